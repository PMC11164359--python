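"""Pairwise Ka/Ks estimation by Nei-Gojobori (1986) pathway counting.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction
of non-stop single-nucleotide neighbors that preserve the amino acid;
*differences* between two codons are averaged over all minimal mutational
pathways that avoid stop codons.  Two distance corrections are offered:

``ng86_jc``
    Jukes-Cantor on the raw proportions, K = -(3/4) ln(1 - (4/3) p).
``kumar_k2p``
    Transition and transversion difference fractions accumulated separately
    within the synonymous and nonsynonymous site classes, each class
    corrected by the Kimura two-parameter formula
    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).

Ka/Ks < 1 signals purifying selection; mitochondrial protein-coding genes
almost universally show ratios well below 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np

from .genetic_code import BASES, GeneticCode, get_code, is_transition

log = logging.getLogger(__name__)

__all__ = [
    "PairwiseRates", "count_sites", "count_differences",
    "kaks_pair", "gene_kaks_summary",
]


@dataclass
class PairwiseRates:
    """Site and difference counts plus corrected rates for one sequence pair.

    ``ratio`` is ``None`` when Ks is zero or either distance is saturated.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    codons_compared: int
    method: str

    @property
    def ratio(self) -> float | None:
        if self.Ka is None or self.Ks is None or self.Ks == 0.0:
            return None
        return self.Ka / self.Ks


def _neighbors(codon: str) -> list[tuple[int, str]]:
    out = []
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                out.append((pos, codon[:pos] + b + codon[pos + 1:]))
    return out


@lru_cache(maxsize=4096)
def _count_sites_cached(codon: str, code_id: str) -> tuple[float, float]:
    code = get_code(code_id)
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            if code.is_stop(nb):
                continue
            valid += 1
            if code.synonymous(codon, nb):
                syn += 1
        if valid:
            s_sites += syn / valid
    return s_sites, 3.0 - s_sites


def count_sites(codon: str, code: GeneticCode | None = None) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Per position: fraction of non-stop single-nucleotide neighbors that are
    synonymous.  s + n = 3 always.
    """
    code = code or get_code()
    if not code.is_sense(codon):
        raise ValueError(f"{codon} is not a sense codon under {code.code_id}")
    return _count_sites_cached(codon, code.code_id)


@lru_cache(maxsize=65536)
def _count_diffs_cached(
    a: str, b: str, code_id: str
) -> tuple[float, float, float, float, float, float]:
    """Pathway-averaged (sd, nd, sd_ts, sd_tv, nd_ts, nd_tv)."""
    code = get_code(code_id)
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return (0.0,) * 6
    path_stats = []
    for order in permutations(diff_pos):
        cur = a
        sd = nd = sd_ts = sd_tv = nd_ts = nd_tv = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            ts = is_transition(cur[pos], b[pos])
            if code.synonymous(cur, nxt):
                sd += 1
                sd_ts += ts
                sd_tv += not ts
            else:
                nd += 1
                nd_ts += ts
                nd_tv += not ts
            cur = nxt
        if ok:
            path_stats.append((sd, nd, sd_ts, sd_tv, nd_ts, nd_tv))
    if not path_stats:
        # no stop-free minimal pathway: count everything nonsynonymous
        log.debug("no stop-free pathway between %s and %s", a, b)
        nd = float(len(diff_pos))
        nd_ts = float(sum(is_transition(a[i], b[i]) for i in diff_pos))
        return 0.0, nd, 0.0, 0.0, nd_ts, nd - nd_ts
    return tuple(float(np.mean([p[i] for p in path_stats])) for i in range(6))


def count_differences(
    codon_a: str, codon_b: str, code: GeneticCode | None = None
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    aligned sense codons.  sd + nd equals the Hamming distance whenever at
    least one stop-free minimal pathway exists."""
    code = code or get_code()
    for c in (codon_a, codon_b):
        if not code.is_sense(c):
            raise ValueError(f"{c} is not a sense codon under {code.code_id}")
    sd, nd, *_ = _count_diffs_cached(codon_a, codon_b, code.code_id)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _k2p_correct(p: float, q: float) -> float | None:
    a1 = 1.0 - 2.0 * p - q
    a2 = 1.0 - 2.0 * q
    if a1 <= 0.0 or a2 <= 0.0:
        return None
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def _usable_codon_pairs(cds_a: str, cds_b: str, code: GeneticCode):
    """Yield aligned codon pairs after pairwise deletion of gapped,
    ambiguous, or stop-containing columns."""
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    for i in range(0, len(a) - len(a) % 3, 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if set(ca) - set(BASES) or set(cb) - set(BASES):
            continue
        if not (code.is_sense(ca) and code.is_sense(cb)):
            continue
        yield ca, cb


def kaks_pair(
    cds_a: str,
    cds_b: str,
    code: GeneticCode | None = None,
    method: str = "ng86_jc",
) -> PairwiseRates:
    """Ka, Ks and their ratio for one aligned codon-sequence pair.

    Sites are averaged over the two sequences; gapped/ambiguous/stop codon
    columns are removed pairwise before counting.
    """
    if method not in ("ng86_jc", "kumar_k2p"):
        raise ValueError(f"unknown method {method!r}")
    code = code or get_code()
    S = N = Sd = Nd = 0.0
    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    n_codons = 0
    for ca, cb in _usable_codon_pairs(cds_a, cds_b, code):
        n_codons += 1
        sa, na = count_sites(ca, code)
        sb, nb = count_sites(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        d = _count_diffs_cached(ca, cb, code.code_id)
        Sd += d[0]
        Nd += d[1]
        sd_ts += d[2]
        sd_tv += d[3]
        nd_ts += d[4]
        nd_tv += d[5]
    if n_codons == 0:
        raise ValueError("no comparable codons after pairwise deletion")
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    if method == "ng86_jc":
        Ks = _jc_correct(pS)
        Ka = _jc_correct(pN)
    else:
        Ks = _k2p_correct(sd_ts / S if S else 0.0, sd_tv / S if S else 0.0)
        Ka = _k2p_correct(nd_ts / N if N else 0.0, nd_tv / N if N else 0.0)
    return PairwiseRates(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        codons_compared=n_codons, method=method,
    )


def gene_kaks_summary(
    alignment: dict[str, str],
    code: GeneticCode | None = None,
    method: str = "ng86_jc",
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> dict:
    """Mean Ka, Ks and Ka/Ks over all unordered sequence pairs of one gene
    alignment, with a bootstrap standard error of the mean ratio.

    Bootstrap resamples codon columns (not nucleotides) with replacement,
    preserving codon structure.
    """
    taxa = sorted(alignment)
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    code = code or get_code()
    lengths = {len(alignment[t]) for t in taxa}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    length = lengths.pop() // 3 * 3

    def _means(seqs: dict[str, str]):
        kas, kss, ratios = [], [], []
        for ta, tb in combinations(taxa, 2):
            r = kaks_pair(seqs[ta], seqs[tb], code=code, method=method)
            if r.Ka is not None:
                kas.append(r.Ka)
            if r.Ks is not None:
                kss.append(r.Ks)
            if r.ratio is not None:
                ratios.append(r.ratio)
        return (
            float(np.mean(kas)) if kas else None,
            float(np.mean(kss)) if kss else None,
            float(np.mean(ratios)) if ratios else None,
        )

    ka, ks, ratio = _means(alignment)
    se = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        n_cols = length // 3
        boot_ratios = []
        for _ in range(bootstrap_reps):
            cols = rng.integers(0, n_cols, size=n_cols)
            seqs = {
                t: "".join(alignment[t][3 * c : 3 * c + 3] for c in cols)
                for t in taxa
            }
            _, _, r = _means(seqs)
            if r is not None:
                boot_ratios.append(r)
        se = float(np.std(boot_ratios, ddof=1)) if len(boot_ratios) > 1 else 0.0
    return {
        "n_taxa": len(taxa),
        "n_codons": length // 3,
        "mean_ka": ka,
        "mean_ks": ks,
        "mean_ratio": ratio,
        "ratio_se": se,
        "method": method,
    }
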