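"""Codon-usage-bias statistics: RSCU, ENC, CBI, positional GC, ENC-plot
null curve and neutrality-plot correlation.

ENC (effective number of codons) is Wright's estimator generalized to an
arbitrary genetic code: synonymous-family degeneracy classes are derived
from the active code table rather than fixed at the standard-code 2/3/4/6
split.  Under the invertebrate mitochondrial code the classes are twelve
2-fold, six 4-fold, one 6-fold (Leu) and one 8-fold (Ser) family, so ENC
ranges from 20 (one codon per amino acid) to 62 (uniform usage over all
sense codons).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .genetic_code import BASES, GeneticCode, get_code

log = logging.getLogger(__name__)

__all__ = [
    "CodonCounts", "count_codons", "rscu", "enc", "cbi",
    "positional_gc", "enc_null_curve", "correlation",
]


@dataclass
class CodonCounts:
    """Aggregated codon counts under one genetic code.

    Codons containing non-ACGT characters are excluded at construction; stop
    codons are excluded when built through :func:`count_codons` with
    ``exclude_stops=True`` (the default 62-codon universe).
    """

    counts: dict[str, int]
    code_id: str
    codon_strings: list[str] = field(default_factory=list, repr=False)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def code(self) -> GeneticCode:
        return get_code(self.code_id)

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def count_codons(
    cds_list: list[str],
    code: GeneticCode | None = None,
    exclude_stops: bool = True,
) -> CodonCounts:
    """Count codons over a set of CDS sequences.

    Trailing partial codons (incomplete stops completed by polyadenylation)
    are dropped; codons containing ambiguity characters are skipped.
    """
    code = code or get_code()
    counts: dict[str, int] = {}
    kept: list[str] = []
    for cds in cds_list:
        s = cds.upper()
        if len(s) < 3:
            warnings.warn(f"CDS shorter than one codon skipped: {s!r}",
                          stacklevel=2)
            continue
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if set(codon) - set(BASES):
                continue
            if exclude_stops and code.is_stop(codon):
                continue
            counts[codon] = counts.get(codon, 0) + 1
            kept.append(codon)
    return CodonCounts(counts=counts, code_id=code.code_id, codon_strings=kept)


def rscu(counts: CodonCounts) -> dict[str, float | None]:
    """Relative synonymous codon usage: k * n_c / sum over the family.

    Families with zero observations report ``None`` for each member (RSCU is
    undefined, not zero, when the amino acid never occurs).
    """
    if counts.total == 0:
        raise ValueError("empty codon counts")
    code = counts.code
    out: dict[str, float | None] = {}
    for aa, codons in code.families.items():
        fam_total = sum(counts[c] for c in codons)
        k = len(codons)
        for c in codons:
            out[c] = k * counts[c] / fam_total if fam_total else None
    return out


def _family_homozygosity(n: int, codon_counts: list[int]) -> float | None:
    """Wright's F-hat = (n * sum p_i^2 - 1)/(n - 1); defined for n >= 2 and
    excluded (None) when it comes out non-positive (1/F undefined)."""
    if n < 2:
        return None
    p2 = sum((c / n) ** 2 for c in codon_counts)
    f = (n * p2 - 1) / (n - 1)
    return f if f > 0 else None


def enc(counts: CodonCounts) -> float:
    """Effective number of codons, degeneracy classes from the active code.

    Per amino acid with n >= 2 codons observed, homozygosity
    F-hat = (n * sum p_i^2 - 1)/(n - 1); per degeneracy class k the mean
    F-bar_k of defined F-hat values; ENC = sum_k m_k / F-bar_k.  A class with
    no defined F-hat is imputed as F-bar = 1/k (uniform usage) with a
    warning.  The result is clamped to [number of amino acids, number of
    sense codons] ([20, 62] for the invertebrate mitochondrial code).
    """
    code = counts.code
    classes = code.degeneracy_classes()
    any_defined = False
    total = 0.0
    n_aa = sum(len(aas) for aas in classes.values())
    for k, aas in sorted(classes.items()):
        if k == 1:
            total += len(aas)  # non-degenerate amino acids contribute 1 each
            continue
        fhats = []
        for aa in aas:
            fam = code.families[aa]
            n = sum(counts[c] for c in fam)
            f = _family_homozygosity(n, [counts[c] for c in fam])
            if f is not None:
                fhats.append(f)
        if fhats:
            any_defined = True
            fbar = float(np.mean(fhats))
        else:
            log.warning(
                "no amino acid in the %d-fold class has >=2 codons; "
                "imputing F-bar = 1/%d", k, k,
            )
            fbar = 1.0 / k
        total += len(aas) / fbar
    if not any_defined:
        raise ValueError("insufficient codons: every family has n < 2")
    return float(np.clip(total, n_aa, len(code.sense_codons)))


def cbi(
    counts: CodonCounts,
    preferred: dict[str, str] | None = None,
) -> float:
    """Codon bias index: (N_pref - N_rand) / (N_tot - N_rand).

    Restricted to amino acids with >= 2 synonyms.  ``preferred`` maps amino
    acid -> preferred codon; by default the modal codon in the dataset
    (ties broken alphabetically).
    """
    code = counts.code
    n_tot = n_pref = n_rand = 0.0
    for aa, fam in code.families.items():
        k = len(fam)
        if k < 2:
            continue
        n_aa = sum(counts[c] for c in fam)
        if n_aa == 0:
            continue
        if preferred is not None:
            pref = preferred[aa]
            if pref not in fam:
                raise ValueError(f"preferred codon {pref} not in {aa} family")
        else:
            pref = max(sorted(fam), key=lambda c: counts[c])
        n_tot += n_aa
        n_pref += counts[pref]
        n_rand += n_aa / k
    if n_tot == n_rand:
        raise ValueError("degenerate codon table: N_tot equals N_rand")
    return (n_pref - n_rand) / (n_tot - n_rand)


def positional_gc(
    cds_list: list[str], code: GeneticCode | None = None
) -> dict[str, float]:
    """GC and AT percent at each codon position over all counted codons.

    Returns gc1, gc2, gc3, gc12 (= mean of gc1 and gc2), gc_all, at1, at2,
    at3, all as percentages.  Codon filtering matches :func:`count_codons`
    (stops and ambiguous codons excluded).
    """
    counted = count_codons(cds_list, code=code)
    if not counted.codon_strings:
        raise ValueError("no codons to analyze")
    gc = []
    at = []
    for pos in range(3):
        bases = [c[pos] for c in counted.codon_strings]
        n = len(bases)
        g = sum(b in "GC" for b in bases)
        gc.append(100.0 * g / n)
        at.append(100.0 - 100.0 * g / n)
    return {
        "gc1": gc[0], "gc2": gc[1], "gc3": gc[2],
        "gc12": (gc[0] + gc[1]) / 2.0,
        "gc_all": sum(gc) / 3.0,
        "at1": at[0], "at2": at[1], "at3": at[2],
    }


def enc_null_curve(s: float) -> float:
    """Expected ENC under mutation pressure alone at GC3 fraction ``s``:
    ENC = 2 + s + 29 / (s^2 + (1 - s)^2).  Points below this curve indicate
    selection shaping codon usage beyond mutation bias."""
    if not 0.0 < s < 1.0:
        raise ValueError(f"GC3 fraction must lie in (0, 1), got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def correlation(x, y) -> tuple[float, float, float]:
    """Pearson correlation: returns (r, r^2, two-sided p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r * r), float(p)
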