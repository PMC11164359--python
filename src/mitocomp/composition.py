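"""Nucleotide composition and strand-asymmetry skew statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed on the
J-strand as deposited.  Insect mitogenomes are strongly AT-rich; Formica
mitogenomes show a slightly negative AT skew (more T than A on the majority
strand) and a strongly negative GC skew.  N and other ambiguity codes are
excluded from both numerators and denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import AnnotatedGenome, extract_gene

__all__ = ["CompositionStats", "composition", "regional_composition"]


@dataclass(frozen=True)
class CompositionStats:
    """Base counts with derived content percentages and skews.

    ``at_skew``/``gc_skew`` are ``None`` when the corresponding base pair is
    absent (0/0 is undefined, not zero).
    """

    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        """Percent A+T over unambiguous bases."""
        return 100.0 * (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return 100.0 * (self.g + self.c) / self.total

    @property
    def at_skew(self) -> float | None:
        at = self.a + self.t
        return (self.a - self.t) / at if at else None

    @property
    def gc_skew(self) -> float | None:
        gc = self.g + self.c
        return (self.g - self.c) / gc if gc else None


def composition(seq: str) -> CompositionStats:
    """Composition of a DNA string; only unambiguous A/C/G/T bases count."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    stats = CompositionStats(
        a=s.count("A"), c=s.count("C"), g=s.count("G"), t=s.count("T")
    )
    if stats.total == 0:
        raise ValueError("no unambiguous bases in sequence")
    return stats


#: Region keys emitted by :func:`regional_composition`, before per-gene rows.
SUMMARY_REGIONS = ("whole", "PCGs", "tRNAs", "rRNAs", "CR", "IGS_concatenated")


def regional_composition(genome: AnnotatedGenome) -> pd.DataFrame:
    """Composition table over whole genome, gene classes, CR, concatenated
    intergenic spacers, and each gene.

    Class concatenations use J-strand-oriented sequences as deposited (no
    re-orientation), so class counts are consistent with whole-genome strand
    accounting.  Absent regions are omitted.
    """
    from .genome import compute_spacers

    rows: list[dict] = []

    def add(region: str, seq: str) -> None:
        if not seq or not set(seq.upper()) & set("ACGT"):
            return
        st = composition(seq)
        rows.append({
            "region": region,
            "length": len(seq),
            "A": st.a, "C": st.c, "G": st.g, "T": st.t,
            "at_content": st.at_content,
            "gc_content": st.gc_content,
            "at_skew": st.at_skew,
            "gc_skew": st.gc_skew,
        })

    add("whole", genome.sequence)
    by_kind = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs"}
    for kind, region in by_kind.items():
        seqs = [
            genome.region_sequence(f.start, f.end)
            for f in genome.features if f.kind == kind
        ]
        add(region, "".join(seqs))
    cr = [f for f in genome.features if f.kind == "CR"]
    if cr:
        add("CR", genome.region_sequence(cr[0].start, cr[0].end))
    if len(genome.features) >= 2:
        spacers = compute_spacers(genome)
        add("IGS_concatenated", "".join(s.sequence for s in spacers))
    for f in genome.features:
        if f.kind == "CR":
            continue  # already covered by the CR class row
        add(f.name, extract_gene(genome, f.name))
    return pd.DataFrame(rows)
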