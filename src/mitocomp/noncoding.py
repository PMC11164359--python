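"""Control-region and intergenic-spacer characterization.

Mitochondrial control regions are AT-rich and structurally variable: length
differences between species largely trace to tandem-repeat copy number.
This module provides self-contained detectors for tandem repeat arrays,
homopolymer runs, short motifs (e.g. TATA), IUPAC consensus motifs over
aligned spacer blocks, and exact-complementarity stem-loops (hairpins).
Detection is purely sequence-based; no thermodynamic folding is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import revcomp

__all__ = [
    "RepeatArray", "ConsensusMotif", "Hairpin",
    "find_tandem_repeats", "find_runs", "count_motif",
    "consensus_motif", "find_hairpins",
]


@dataclass
class RepeatArray:
    """A tandem repeat array: ``copies`` approximate copies of a ``period``-
    length unit starting at ``start`` (0-based within the searched region).
    ``identity`` is the fraction of positions matching the position one
    period earlier; a fractional final copy is allowed."""

    start: int
    period: int
    copies: float
    consensus: str
    identity: float

    @property
    def span(self) -> int:
        return round(self.copies * self.period)

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass
class ConsensusMotif:
    """IUPAC consensus over an aligned block of equal-length rows."""

    consensus: str
    conservation: list[float]
    n_rows: int
    block_length: int


@dataclass
class Hairpin:
    """An exact Watson-Crick inverted repeat: 5' stem arm at
    ``stem_start_5p``, loop of ``loop_len``, 3' arm at ``stem_start_3p``."""

    stem_start_5p: int
    stem_start_3p: int
    stem_len: int
    loop_len: int

    @property
    def end(self) -> int:
        return self.stem_start_3p + self.stem_len


IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def _array_at(seq: str, start: int, period: int,
              identity_threshold: float) -> tuple[int, float] | None:
    """Greedy extension of a candidate array seeded at ``start`` with exact
    first two copies; returns (span, identity) or None.

    Identity is measured as matches to the position one period earlier; the
    extension stops one position before overall identity would fall below
    the threshold.
    """
    n = len(seq)
    if start + 2 * period > n:
        return None
    if seq[start:start + period] != seq[start + period:start + 2 * period]:
        return None
    matches = period
    compared = period
    end = start + 2 * period
    best_end, best_id = end, 1.0
    while end < n:
        compared += 1
        matches += seq[end] == seq[end - period]
        ident = matches / compared
        if ident < identity_threshold:
            break
        end += 1
        if seq[end - 1] == seq[end - 1 - period]:
            best_end, best_id = end, ident
    return best_end - start, best_id


def find_tandem_repeats(
    seq: str,
    min_period: int = 5,
    max_period: int = 200,
    min_copies: float = 2.0,
    identity_threshold: float = 0.85,
) -> list[RepeatArray]:
    """Detect maximal tandem repeat arrays by greedy extension from exact
    two-copy seeds.

    Candidates at every (start, period) whose first two copies match exactly
    are extended while running identity stays above ``identity_threshold``.
    Overlapping candidates are resolved by longer array, then higher
    identity, then smaller period; arrays nested inside an accepted one are
    dropped.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n = len(s)
    candidates: list[RepeatArray] = []
    for period in range(max(1, min_period), min(max_period, n // 2) + 1):
        start = 0
        while start + 2 * period <= n:
            hit = _array_at(s, start, period, identity_threshold)
            if hit is None:
                start += 1
                continue
            span, ident = hit
            copies = span / period
            if copies >= min_copies:
                candidates.append(RepeatArray(
                    start=start, period=period, copies=copies,
                    consensus=s[start:start + period], identity=ident,
                ))
            start += max(span - 2 * period + 1, 1)
    candidates.sort(key=lambda r: (-r.span, -r.identity, r.period, r.start))
    accepted: list[RepeatArray] = []
    for cand in candidates:
        if all(cand.end <= a.start or cand.start >= a.end for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda r: r.start)
    return accepted


def find_runs(seq: str, base: str, min_len: int = 6) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` with length >= ``min_len`` as (start, length)."""
    if not seq:
        raise ValueError("empty sequence")
    if base not in "ACGT":
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    s = seq.upper()
    runs = []
    i = 0
    n = len(s)
    while i < n:
        if s[i] == base:
            j = i
            while j < n and s[j] == base:
                j += 1
            if j - i >= min_len:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def count_motif(seq: str, motif: str = "TATA") -> int:
    """Count (overlapping) occurrences of a motif."""
    if set(motif.upper()) - set("ACGT"):
        raise ValueError("motif must be over A/C/G/T")
    s, m = seq.upper(), motif.upper()
    count = start = 0
    while True:
        idx = s.find(m, start)
        if idx == -1:
            return count
        count += 1
        start = idx + 1


def consensus_motif(
    aligned_block: list[str], min_freq: float = 0.0
) -> ConsensusMotif:
    """IUPAC consensus of an aligned block.

    Per column, the minimal IUPAC code covering every base whose frequency
    exceeds ``min_freq``; columns containing a gap character are excluded
    from the consensus string (their conservation is recorded as 0).
    """
    if len(aligned_block) < 2:
        raise ValueError("need at least two rows")
    rows = [r.upper() for r in aligned_block]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    length = lengths.pop()
    consensus = []
    conservation = []
    for col in range(length):
        column = [r[col] for r in rows]
        if any(b in "-." for b in column):
            conservation.append(0.0)
            continue
        freqs: dict[str, float] = {}
        for b in column:
            if b in "ACGT":
                freqs[b] = freqs.get(b, 0.0) + 1.0 / len(column)
        observed = frozenset(b for b, f in freqs.items() if f > min_freq)
        if not observed:
            observed = frozenset("ACGT")
        consensus.append(IUPAC_CODES[observed])
        conservation.append(max(freqs.values()) if freqs else 0.0)
    return ConsensusMotif(
        consensus="".join(consensus),
        conservation=conservation,
        n_rows=len(rows),
        block_length=length,
    )


def find_hairpins(
    seq: str,
    min_stem: int = 6,
    loop_range: tuple[int, int] = (3, 20),
) -> list[Hairpin]:
    """Exact Watson-Crick inverted repeats within loop-length bounds.

    All maximal stems are enumerated, then selected greedily longest-stem-
    first (ties: leftmost) without reuse of sequence positions.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n = len(s)
    lo, hi = loop_range
    candidates: list[Hairpin] = []
    for i in range(n):
        for loop in range(lo, hi + 1):
            # stem arm [i-k, i), loop [i, i+loop), arm [i+loop, i+loop+k)
            k = 0
            while (
                i - k - 1 >= 0
                and i + loop + k < n
                and s[i + loop + k] == revcomp(s[i - k - 1])
            ):
                k += 1
            if k >= min_stem:
                candidates.append(Hairpin(
                    stem_start_5p=i - k, stem_start_3p=i + loop,
                    stem_len=k, loop_len=loop,
                ))
    candidates.sort(key=lambda h: (-h.stem_len, h.stem_start_5p, h.loop_len))
    accepted: list[Hairpin] = []
    for cand in candidates:
        if all(
            cand.end <= a.stem_start_5p or cand.stem_start_5p >= a.end
            for a in accepted
        ):
            accepted.append(cand)
    accepted.sort(key=lambda h: h.stem_start_5p)
    return accepted
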