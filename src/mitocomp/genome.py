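"""Annotated mitogenome model and GenBank I/O on a circular coordinate system.

Coordinates are 0-based half-open on the J-strand (the majority strand, as
deposited).  Features may wrap the origin, in which case ``end`` exceeds the
sequence length and extraction uses modular indexing.  GenBank flat files use
1-based inclusive coordinates; conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genetic_code import INVERTEBRATE_MITO, get_code

log = logging.getLogger(__name__)

VALID_KINDS = ("PCG", "tRNA", "rRNA", "CR")

#: 37-gene ancestral insect (Drosophila-like) mitochondrial order on the
#: J-strand, with coding strand.  The CR sits between rrnS and trnI.
ANCESTRAL_INSECT_ORDER: tuple[tuple[str, str], ...] = (
    ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"),
    ("trnW", "J"), ("trnC", "N"), ("trnY", "N"), ("cox1", "J"),
    ("trnL2", "J"), ("cox2", "J"), ("trnK", "J"), ("trnD", "J"),
    ("atp8", "J"), ("atp6", "J"), ("cox3", "J"), ("trnG", "J"),
    ("nad3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"), ("nad5", "N"),
    ("trnH", "N"), ("nad4", "N"), ("nad4L", "N"), ("trnT", "J"),
    ("trnP", "N"), ("nad6", "J"), ("cob", "J"), ("trnS2", "J"),
    ("nad1", "N"), ("trnL1", "N"), ("rrnL", "N"), ("trnV", "N"),
    ("rrnS", "N"), ("CR", "J"),
)

#: Formica / Formicidae order: trnM translocated in front of trnI-trnQ
#: (duplication / random loss of the ancestral trnI-trnQ-trnM block).
FORMICA_ORDER: tuple[tuple[str, str], ...] = (
    ("trnM", "J"), ("trnI", "J"), ("trnQ", "N"),
) + ANCESTRAL_INSECT_ORDER[3:]

PCG_NAMES = frozenset(
    n for n, _ in ANCESTRAL_INSECT_ORDER
    if n.startswith(("cox", "nad", "atp")) or n == "cob"
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenBankParseError(ValueError):
    """Raised when a GenBank flat file cannot be interpreted."""


@dataclass
class GeneFeature:
    """One gene on the circular genome.

    ``start``/``end`` are 0-based half-open positions on the J-strand;
    ``end`` may exceed the genome length for origin-wrapping features.
    ``strand`` is "J" (as deposited) or "N" (extraction reverse-complements).
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"{self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.kind not in VALID_KINDS:
            raise ValueError(f"{self.name}: unknown feature kind {self.kind!r}")
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be 'J' or 'N'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SpacerRecord:
    """Intergenic spacer (or overlap, with negative length) between two
    consecutive features in circular J-strand order."""

    upstream_gene: str
    downstream_gene: str
    sequence: str
    length: int

    def __post_init__(self):
        if self.length >= 0 and self.length != len(self.sequence):
            raise ValueError("spacer length must equal sequence length")
        if self.length < 0 and self.sequence:
            raise ValueError("overlap records carry an empty sequence")

    @property
    def is_overlap(self) -> bool:
        return self.length < 0


@dataclass
class AnnotatedGenome:
    genome_id: str
    taxon: str
    sequence: str
    is_circular: bool = True
    genetic_code: str = INVERTEBRATE_MITO
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty genome sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains invalid characters {bad}")
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        names = [f.name for f in self.features]
        dupes = {x for x in names if names.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        for f in self.features:
            if not (0 <= f.start < n):
                raise ValueError(f"{f.name}: start {f.start} outside [0, {n})")
            if not self.is_circular and f.end > n:
                raise ValueError(f"{f.name}: wraps origin of a linear genome")
            if f.end - f.start > n:
                raise ValueError(f"{f.name}: longer than the genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"gene {name!r} not annotated in {self.genome_id}")

    def region_sequence(self, start: int, end: int) -> str:
        """J-strand sequence of [start, end); modular for wrapping intervals."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        return (self.sequence + self.sequence)[start:end]


def extract_gene(genome: AnnotatedGenome, name: str) -> str:
    """Coding-strand sequence of a gene (reverse complement for strand N)."""
    f = genome.feature(name)
    seq = genome.region_sequence(f.start, f.end)
    return revcomp(seq) if f.strand == "N" else seq


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

def _load_synonyms() -> dict[str, str]:
    table = {}
    src = resources.files("mitocomp.data").joinpath("gene_synonyms.tsv")
    for line in src.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        raw, canonical = line.split("\t")
        table[raw] = canonical
    return table


_SYNONYMS: dict[str, str] | None = None


def canonical_gene_name(raw: str) -> str | None:
    """Map a raw GenBank/MITOS gene label to the canonical symbol, or None."""
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    return _SYNONYMS.get(raw.strip().upper())


_LEU_SER_BY_ANTICODON = {
    "TAG": "trnL1", "CAA": "trnL1",   # CUN leucine
    "TAA": "trnL2",                    # UUR leucine
    "TCT": "trnS1", "GCT": "trnS1",   # AGN serine
    "TGA": "trnS2",                    # UCN serine
}


def _feature_raw_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def _location_to_interval(loc, seq_len: int) -> tuple[int, int, str]:
    """Biopython location -> (start, end, strand) with origin wrap folded into
    end > seq_len."""
    strand = "N" if loc.strand == -1 else "J"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning join(x..len, 1..y)
        if (
            len(parts) == 2
            and int(parts[1].end) == seq_len
            and int(parts[0].start) == 0
        ):
            return int(parts[1].start), seq_len + int(parts[0].end), strand
        return int(loc.start), int(loc.end), strand
    return int(loc.start), int(loc.end), strand


def parse_genbank(path) -> list[AnnotatedGenome]:
    """Parse a GenBank flat file into annotated genomes.

    GenBank 1-based inclusive coordinates become 0-based half-open; gene
    names are normalized through the synonym table; unmappable names are
    retained raw with a warning, with the kind inferred from the feature key.
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenBankParseError(f"malformed GenBank record in {path}: {exc}")
    if not records:
        raise GenBankParseError(f"no GenBank records found in {path}")
    return [_record_to_genome(rec) for rec in records]


def _record_to_genome(rec: SeqRecord) -> AnnotatedGenome:
    seq = str(rec.seq).upper()
    circular = rec.annotations.get("topology", "circular") == "circular"
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in rec.features:
        kind = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}.get(feat.type)
        if kind is None:
            if feat.type in ("D-loop", "misc_feature"):
                kind = "CR"
            else:
                continue
        raw = _feature_raw_name(feat) or (
            "CR" if kind == "CR" else feat.type
        )
        name = canonical_gene_name(raw)
        if name is None and kind == "tRNA" and raw.upper().rstrip("12- ") in (
            "TRNA-LEU", "TRNL", "TRNA-SER", "TRNS"
        ):
            # disambiguate tRNA-Leu / tRNA-Ser via the anticodon qualifier
            anticodon = "".join(
                feat.qualifiers.get("anticodon", [""])
            ).upper().replace("U", "T")
            for ac, trn in _LEU_SER_BY_ANTICODON.items():
                if ac in anticodon:
                    if ("LEU" in raw.upper() or "TRNL" in raw.upper()) == (
                        trn.startswith("trnL")
                    ):
                        name = trn
                        break
        if kind == "CR" and name is None:
            name = "CR" if "CR" not in seen else None
        if name is None:
            warnings.warn(
                f"{rec.id}: gene name {raw!r} not in synonym table; kept raw",
                stacklevel=2,
            )
            name = raw
        if name in seen:  # duplicated annotations (gene + CDS pairs)
            continue
        seen.add(name)
        start, end, strand = _location_to_interval(feat.location, len(seq))
        feats.append(GeneFeature(name=name, kind=kind, strand=strand,
                                 start=start, end=end))
    feats.sort(key=lambda f: f.start)
    taxon = rec.annotations.get("organism", rec.description or rec.id)
    return AnnotatedGenome(
        genome_id=rec.id or rec.name,
        taxon=taxon,
        sequence=seq,
        is_circular=circular,
        features=feats,
    )


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Write a genome back to GenBank, preserving coordinates and strands."""
    n = len(genome.sequence)
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id.split(".")[0][:16],
        description=f"{genome.taxon} mitochondrion, complete genome",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.is_circular else "linear"
    rec.annotations["organism"] = genome.taxon
    keymap = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature"}
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        if f.end <= n:
            loc = SimpleLocation(f.start, f.end, strand=strand)
        else:
            parts = [SimpleLocation(f.start, n, strand=strand),
                     SimpleLocation(0, f.end - n, strand=strand)]
            if strand == -1:
                parts = parts[::-1]
            loc = CompoundLocation(parts)
        rec.features.append(
            SeqFeature(loc, type=keymap[f.kind], qualifiers={"gene": [f.name]})
        )
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "genbank")


# ---------------------------------------------------------------------------
# Spacers, gene order, start/stop codons
# ---------------------------------------------------------------------------

def compute_spacers(genome: AnnotatedGenome) -> list[SpacerRecord]:
    """Spacer (gap) or overlap between every consecutive feature pair in
    circular J-strand order, including the pair spanning the origin."""
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    if len(feats) < 2:
        raise ValueError("need at least two features to compute spacers")
    n = len(genome.sequence)
    out: list[SpacerRecord] = []
    for i, cur in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        nxt_start = nxt.start + (n if i == len(feats) - 1 else 0)
        gap = nxt_start - cur.end
        if gap >= 0:
            seq = genome.region_sequence(cur.end % n, cur.end % n + gap)
            out.append(SpacerRecord(cur.name, nxt.name, seq, gap))
        else:
            out.append(SpacerRecord(cur.name, nxt.name, "", gap))
    return out


def gene_order_signature(
    genome: AnnotatedGenome,
) -> tuple[list[tuple[str, str]], str, list[str]]:
    """Circularly normalized gene order anchored at cox1, plus a
    rearrangement label.

    Returns ``(order, label, missing)`` with label in
    {"ancestral", "trnM_translocation", "other"}.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    order = [(f.name, f.strand) for f in feats]
    names = [n for n, _ in order]
    expected = {n for n, _ in ANCESTRAL_INSECT_ORDER}
    missing = sorted(expected - set(names))
    if "cox1" in names:
        i = names.index("cox1")
        order = order[i:] + order[:i]
    if missing:
        return order, "other", missing

    def _anchor(ref: tuple[tuple[str, str], ...]) -> list[tuple[str, str]]:
        ref = list(ref)
        i = [n for n, _ in ref].index("cox1")
        return ref[i:] + ref[:i]

    if order == _anchor(ANCESTRAL_INSECT_ORDER):
        return order, "ancestral", []
    if order == _anchor(FORMICA_ORDER):
        return order, "trnM_translocation", []
    return order, "other", []


STOP_CLASSES = ("TAA", "TAG", "incomplete_TA", "incomplete_T")


def survey_start_stop(genome: AnnotatedGenome):
    """Start codon and stop-codon class for every protein-coding gene.

    A CDS length of 3k+1 implies an incomplete T stop, 3k+2 an incomplete TA
    (completed by post-transcriptional polyadenylation).  Internal stop
    codons are flagged but do not abort the survey.
    """
    import pandas as pd

    code = get_code(genome.genetic_code)
    rows = []
    for f in genome.features:
        if f.kind != "PCG":
            continue
        cds = extract_gene(genome, f.name)
        start = cds[:3]
        rem = len(cds) % 3
        if rem == 1:
            stop_class = "incomplete_T"
        elif rem == 2:
            stop_class = "incomplete_TA"
        else:
            stop_class = cds[-3:] if cds[-3:] in code.stops else "none"
        n_codons = len(cds) // 3
        internal = []
        for i in range(1, n_codons - (1 if rem == 0 else 0)):
            codon = cds[3 * i : 3 * i + 3]
            if codon in code.stops:
                internal.append(i)
        if internal:
            log.warning("%s/%s: internal stop codon(s) at codon %s",
                        genome.genome_id, f.name, internal)
        rows.append({
            "gene": f.name,
            "start_codon": start,
            "stop_class": stop_class,
            "length_nt": len(cds),
            "internal_stops": len(internal),
        })
    return pd.DataFrame(rows)
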