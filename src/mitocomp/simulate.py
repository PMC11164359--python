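"""Synthetic annotated mitogenomes and codon-sequence evolution.

The generator emits circular genomes with the full insect mitochondrial
gene complement (13 protein-coding genes, 22 tRNAs, 2 rRNAs, one control
region) in either the ancestral insect order or the Formica order (trnM
translocated in front of trnI-trnQ), with AT-rich, strand-skewed base
composition, AT-biased codon usage, and a control region carrying tandem
repeats, homopolymer runs and TATA motifs.  The coding-sequence simulator
evolves codons along a tree under a dN/dS ratio (omega) and a
transition/transversion rate ratio (kappa), which lets selection and
phylogeny estimators be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_code import BASES, GeneticCode, get_code, is_transition
from .genome import (
    ANCESTRAL_INSECT_ORDER,
    FORMICA_ORDER,
    AnnotatedGenome,
    GeneFeature,
    PCG_NAMES,
    revcomp,
)

__all__ = ["CRSpec", "SyntheticConfig", "generate_genome", "evolve_coding"]

#: Realistic per-gene lengths (nt) for an ant-like mitogenome.  PCG lengths
#: are multiples of 3 and include start and stop codons.
GENE_LENGTHS: dict[str, int] = {
    "cox1": 1536, "cox2": 684, "cox3": 786, "cob": 1140,
    "nad1": 936, "nad2": 1023, "nad3": 351, "nad4": 1338,
    "nad4L": 288, "nad5": 1719, "nad6": 522, "atp6": 678, "atp8": 159,
    "rrnL": 1300, "rrnS": 790,
}
TRNA_LENGTH = 65


@dataclass(frozen=True)
class CRSpec:
    """Structural plan for the control region."""

    length: int = 1000
    repeat_period: int = 24
    repeat_copies: float = 4.0
    poly_a_len: int = 8
    poly_t_len: int = 8
    n_tata: int = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic mitogenome.

    Defaults emulate Formica mitogenomes: ~16.6 kb, A+T fraction 0.835,
    slightly negative AT skew and strongly negative GC skew on the J-strand,
    the Formica gene order, and AT-biased codon usage.
    """

    seed: int = 0
    genome_length: int = 16600
    at_content: float = 0.835
    at_skew: float = -0.02
    gc_skew: float = -0.31
    gene_order: str = "formica"
    codon_bias: float = 1.0
    omega: float = 0.1
    kappa: float = 2.0
    genetic_code: str = "invertebrate_mitochondrial"
    cr_spec: CRSpec = field(default_factory=CRSpec)

    def __post_init__(self):
        for name, v in (("at_content", self.at_content),):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name, v in (("at_skew", self.at_skew), ("gc_skew", self.gc_skew)):
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")
        if self.omega <= 0 or self.kappa <= 0:
            raise ValueError("omega and kappa must be positive")
        if self.gene_order not in ("ancestral", "formica"):
            raise ValueError(f"unknown gene_order {self.gene_order!r}")
        if self.codon_bias < 0:
            raise ValueError("codon_bias must be >= 0")

    def base_probs(self) -> dict[str, float]:
        """Per-base J-strand sampling probabilities implied by the
        content/skew targets."""
        at, gc = self.at_content, 1.0 - self.at_content
        p = {
            "A": at * (1.0 + self.at_skew) / 2.0,
            "T": at * (1.0 - self.at_skew) / 2.0,
            "G": gc * (1.0 + self.gc_skew) / 2.0,
            "C": gc * (1.0 - self.gc_skew) / 2.0,
        }
        if min(p.values()) <= 0.0:
            raise ValueError("infeasible composition targets (a base "
                             "probability is not positive)")
        return p


def _sample_bases(rng: np.random.Generator, probs: dict[str, float],
                  n: int) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([probs[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=n, p=p / p.sum()))


def _codon_distribution(
    code: GeneticCode, probs: dict[str, float], bias: float
) -> tuple[list[str], np.ndarray]:
    """Sense-codon sampling distribution.

    The mutational part is the product of base probabilities (codon usage a
    neutral consequence of composition).  ``bias`` adds a selection-like
    preference decoupled from composition: the most AT-rich codon of every
    synonymous family (tie-break alphabetical) is boosted by exp(bias), so
    bias=0 is pure mutation pressure and increasing bias drives ENC below
    the mutation-only expectation at a given GC3.
    """
    preferred = {
        max(fam, key=lambda c: (c.count("A") + c.count("T"), [-ord(x) for x in c]))
        for fam in code.families.values()
    }
    codons = code.sense_codons
    w = np.array([
        np.prod([probs[b] for b in c]) * (np.exp(bias) if c in preferred else 1.0)
        for c in codons
    ])
    return codons, w / w.sum()


def _sample_pcg(
    rng: np.random.Generator, length: int, code: GeneticCode,
    codons: list[str], p: np.ndarray,
) -> str:
    """ATN-start, TAA-stop coding sequence with no internal stop codons."""
    n_codons = length // 3
    start = "AT" + rng.choice(list("AGCT"), p=[0.5, 0.3, 0.1, 0.1])
    body = rng.choice(codons, size=n_codons - 2, p=p)
    return start + "".join(body) + "TAA"


def _build_cr(rng: np.random.Generator, spec: CRSpec,
              probs: dict[str, float]) -> str:
    """Control region: poly-T run, TATA cluster, tandem repeat array,
    poly-A run, AT-rich filler."""
    unit = _sample_bases(rng, probs, spec.repeat_period)
    whole = int(spec.repeat_copies)
    frac = spec.repeat_copies - whole
    array = unit * whole + unit[: round(frac * spec.repeat_period)]
    parts = [
        "T" * spec.poly_t_len,
        "TATA" * spec.n_tata,
        array,
        "A" * spec.poly_a_len,
    ]
    core = "".join(parts)
    if len(core) > spec.length:
        raise ValueError("control-region components exceed its length")
    pad = spec.length - len(core)
    # split the filler so the array is interior, not flush with the edge
    left = _sample_bases(rng, probs, pad // 2)
    right = _sample_bases(rng, probs, pad - pad // 2)
    return left + core + right


def _adjust_composition(
    seq_parts: list[str],
    adjustable: list[tuple[int, int]],
    targets: dict[str, int],
    rng: np.random.Generator,
) -> str:
    """Steer whole-genome base counts toward targets by flipping bases at
    adjustable (non-functional) positions, in seeded random order."""
    seq = list("".join(seq_parts))
    counts = {b: 0 for b in BASES}
    for ch in seq:
        counts[ch] += 1
    positions = np.array(
        [i for s, e in adjustable for i in range(s, e)], dtype=int
    )
    rng.shuffle(positions)
    for i in positions:
        b = seq[i]
        if counts[b] <= targets[b]:
            continue
        deficits = [c for c in BASES if counts[c] < targets[c]]
        if not deficits:
            break
        c = max(deficits, key=lambda x: targets[x] - counts[x])
        seq[i] = c
        counts[b] -= 1
        counts[c] += 1
    return "".join(seq)


def generate_genome(config: SyntheticConfig) -> AnnotatedGenome:
    """Generate one annotated circular mitogenome per the config.

    The realized whole-genome composition is steered to the content/skew
    targets by a correction pass over rRNA and spacer positions (coding
    genes and the control region's structured elements are left intact), so
    targets are met to sampling tolerance rather than exactly.
    """
    rng = np.random.default_rng(config.seed)
    probs = config.base_probs()
    code = get_code(config.genetic_code)
    codons, codon_p = _codon_distribution(code, probs, config.codon_bias)
    # N-strand genes: weight codons by complemented base probabilities so
    # their reverse complement matches the J-strand composition targets
    probs_n = {"A": probs["T"], "T": probs["A"],
               "G": probs["C"], "C": probs["G"]}
    codons_n, codon_p_n = _codon_distribution(code, probs_n, config.codon_bias)

    order = (FORMICA_ORDER if config.gene_order == "formica"
             else ANCESTRAL_INSECT_ORDER)
    gene_sizes = {}
    for name, _ in order:
        if name in PCG_NAMES or name in ("rrnL", "rrnS"):
            gene_sizes[name] = GENE_LENGTHS[name]
        elif name == "CR":
            gene_sizes[name] = config.cr_spec.length
        else:
            gene_sizes[name] = TRNA_LENGTH
    total_genes = sum(gene_sizes.values())
    slack = config.genome_length - total_genes
    if slack < 0:
        raise ValueError(
            f"genome_length {config.genome_length} too small for gene "
            f"content ({total_genes} nt)"
        )
    # distribute spacer lengths over the gaps (multinomial, seeded)
    n_gaps = len(order)
    gap_lens = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))

    parts: list[str] = []
    features: list[GeneFeature] = []
    adjustable: list[tuple[int, int]] = []
    pos = 0
    for (name, strand), gap in zip(order, gap_lens):
        size = gene_sizes[name]
        if name in PCG_NAMES:
            if strand == "N":
                coding = _sample_pcg(rng, size, code, codons_n, codon_p_n)
                seq = revcomp(coding)
            else:
                coding = _sample_pcg(rng, size, code, codons, codon_p)
                seq = coding
            kind = "PCG"
        elif name in ("rrnL", "rrnS"):
            seq = _sample_bases(rng, probs, size)
            adjustable.append((pos, pos + size))
            kind = "rRNA"
        elif name == "CR":
            seq = _build_cr(rng, config.cr_spec, probs)
            kind = "CR"
        else:
            seq = _sample_bases(rng, probs, size)
            kind = "tRNA"
        features.append(GeneFeature(name=name, kind=kind, strand=strand,
                                    start=pos, end=pos + size))
        parts.append(seq)
        pos += size
        if gap:
            parts.append(_sample_bases(rng, probs, int(gap)))
            adjustable.append((pos, pos + int(gap)))
            pos += int(gap)

    targets = {
        b: round(p * config.genome_length) for b, p in probs.items()
    }
    sequence = _adjust_composition(parts, adjustable, targets, rng)
    return AnnotatedGenome(
        genome_id=f"SYN{config.seed:06d}",
        taxon=f"synthetic Formica-like (seed {config.seed})",
        sequence=sequence,
        is_circular=True,
        genetic_code=config.genetic_code,
        features=features,
    )


# ---------------------------------------------------------------------------
# Codon-sequence evolution along a tree
# ---------------------------------------------------------------------------

def _substitution_table(
    code: GeneticCode, omega: float, kappa: float
) -> dict[str, tuple[list[str], np.ndarray, float]]:
    """Per sense codon: (neighbor codons, cumulative weights, total weight).

    Weight of a single-nucleotide change = kappa (transition) or 1
    (transversion), multiplied by omega if the change is nonsynonymous;
    changes into stop codons are forbidden.
    """
    table = {}
    for codon in code.sense_codons:
        neighbors, weights = [], []
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                nb = codon[:pos] + b + codon[pos + 1:]
                if code.is_stop(nb):
                    continue
                w = kappa if is_transition(codon[pos], b) else 1.0
                if not code.synonymous(codon, nb):
                    w *= omega
                neighbors.append(nb)
                weights.append(w)
        w = np.array(weights)
        table[codon] = (neighbors, np.cumsum(w), float(w.sum()))
    return table


def _evolve_branch(
    codon_list: list[str],
    branch_length: float,
    table: dict,
    rho0: float,
    rng: np.random.Generator,
) -> list[str]:
    """Gillespie simulation of one branch.

    ``branch_length`` is in expected substitutions per nucleotide site at
    the root composition: event rates are normalized by ``rho0``, the root
    mean substitution weight per site.
    """
    codons = list(codon_list)
    # bucket positions by codon identity: event sampling is O(#codon types)
    buckets: dict[str, list[int]] = {}
    for i, c in enumerate(codons):
        buckets.setdefault(c, []).append(i)
    total_w = sum(table[c][2] * len(ix) for c, ix in buckets.items())
    t = 0.0
    while True:
        rate = total_w / rho0  # events per unit time (3L at root composition)
        t += rng.exponential(1.0 / rate)
        if t >= branch_length:
            return codons
        # pick a codon type proportional to count * weight, then a position
        types = list(buckets)
        type_w = np.array([table[c][2] * len(buckets[c]) for c in types])
        ci = types[rng.choice(len(types), p=type_w / type_w.sum())]
        members = buckets[ci]
        slot = int(rng.integers(len(members)))
        idx = members[slot]
        neighbors, cum_w, w_tot = table[ci]
        u = rng.random() * w_tot
        new_codon = neighbors[int(np.searchsorted(cum_w, u, side="right"))]
        members[slot] = members[-1]
        members.pop()
        if not members:
            del buckets[ci]
        buckets.setdefault(new_codon, []).append(idx)
        codons[idx] = new_codon
        total_w += table[new_codon][2] - table[ci][2]


def evolve_coding(
    root_cds: str,
    tree,
    omega: float,
    kappa: float,
    seed: int | None = None,
    code: GeneticCode | None = None,
) -> dict[str, str]:
    """Evolve a codon sequence along a tree; returns taxon -> sequence.

    ``tree`` is a newick string or a :class:`~mitocomp.phylogeny.TreeNode`;
    leaf labels become the output taxa.  Branch lengths are expected
    substitutions per nucleotide site at the root composition.  No indels
    are simulated, so the output is a gap-free alignment.
    """
    from .phylogeny import TreeNode, read_newick

    code = code or get_code()
    if len(root_cds) % 3:
        raise ValueError("root CDS length must be a multiple of 3")
    root_codons = [root_cds[i:i + 3].upper()
                   for i in range(0, len(root_cds), 3)]
    for c in root_codons:
        if not code.is_sense(c):
            raise ValueError(f"root contains non-sense codon {c}")
    if isinstance(tree, str):
        tree = read_newick(tree)
    if not isinstance(tree, TreeNode):
        raise TypeError("tree must be a newick string or TreeNode")
    leaves = tree.leaf_names()
    if len(set(leaves)) != len(leaves) or any(n is None for n in leaves):
        raise ValueError("tree leaves must carry unique labels")

    table = _substitution_table(code, omega, kappa)
    rho0 = sum(table[c][2] for c in root_codons) / (3 * len(root_codons))
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}

    def descend(node, codons: list[str]) -> None:
        if node.length:
            codons = _evolve_branch(codons, node.length, table, rho0, rng)
        if node.is_leaf:
            out[node.name] = "".join(codons)
            return
        for child in node.children:
            descend(child, codons)

    descend(tree, root_codons)
    return out
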