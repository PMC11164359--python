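"""Genetic-code tables and synonymous-family (degeneracy) structure.

Codon-usage and substitution statistics all depend on which codons are
synonymous, which differs between the standard nuclear code and the
invertebrate mitochondrial code (NCBI translation table 5): the latter has
62 sense codons, stops {TAA, TAG}, an 8-fold serine family (TCN + AGN) and
no 3-fold class.  Degeneracy classes are therefore derived from the active
table rather than hardcoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

BASES = "ACGT"
CODONS = ["".join(c) for c in product(BASES, repeat=3)]

INVERTEBRATE_MITO = "invertebrate_mitochondrial"

_CODE_IDS = {
    "standard": 1,
    INVERTEBRATE_MITO: 5,
    "vertebrate_mitochondrial": 2,
}


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with derived synonymous-family structure.

    Attributes
    ----------
    code_id : str
        Human-readable identifier (e.g. ``"invertebrate_mitochondrial"``).
    table : dict
        64-entry codon -> one-letter amino acid map; stop codons map to ``"*"``.
    stops : frozenset
        Stop codons.
    """

    code_id: str
    table: dict[str, str]
    stops: frozenset[str]
    families: dict[str, tuple[str, ...]] = field(default=None)  # aa -> codons

    def __post_init__(self):
        fams: dict[str, list[str]] = {}
        for codon in CODONS:
            aa = self.table[codon]
            if aa == "*":
                continue
            fams.setdefault(aa, []).append(codon)
        object.__setattr__(
            self, "families", {aa: tuple(cs) for aa, cs in fams.items()}
        )

    # -- basic queries -----------------------------------------------------

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def is_sense(self, codon: str) -> bool:
        return codon in self.table and codon not in self.stops

    @property
    def sense_codons(self) -> list[str]:
        return [c for c in CODONS if c not in self.stops]

    def family_size(self, codon: str) -> int:
        return len(self.families[self.table[codon]])

    def degeneracy_classes(self) -> dict[int, list[str]]:
        """Map family size k -> list of amino acids with k synonymous codons."""
        classes: dict[int, list[str]] = {}
        for aa, codons in sorted(self.families.items()):
            classes.setdefault(len(codons), []).append(aa)
        return classes

    def synonymous(self, a: str, b: str) -> bool:
        return self.table[a] == self.table[b]


@lru_cache(maxsize=None)
def get_code(code_id: str = INVERTEBRATE_MITO) -> GeneticCode:
    """Load a genetic code by name (Biopython NCBI tables underneath)."""
    if code_id not in _CODE_IDS:
        raise KeyError(
            f"unknown genetic code {code_id!r}; known: {sorted(_CODE_IDS)}"
        )
    ncbi = CodonTable.unambiguous_dna_by_id[_CODE_IDS[code_id]]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = "*"
    return GeneticCode(
        code_id=code_id, table=table, stops=frozenset(ncbi.stop_codons)
    )


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return a != b and {a, b} in ({"A", "G"}, {"C", "T"})
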