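"""Mismatch-tolerant protospacer mapping.

Acquired spacers are placed on a target genome by an exhaustive sliding
Hamming scan of both strands: every placement within the substitution
budget is reported, together with the 10 bp flanking the protospacer on
each side (in spacer orientation), which downstream PAM inference consumes.

Coordinates are 1-based inclusive; a hit on the minus strand is encoded
with start > end (e.g. 25547-25518 for a 30-mer), the convention used when
reporting targeted phage-genome positions.  Matching is substitution-only:
observed imperfect protospacers carry one or two mismatches, never indels,
and Hamming matching keeps an independent brute-force oracle trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import revcomp

PERFECT = "perfect"
MISMATCHED = "mismatched"
UNMAPPED = "unmapped"

DEFAULT_FLANK_LEN = 10


@dataclass(frozen=True)
class ProtospacerHit:
    """A spacer placement on a genome, with PAM-ready flanks.

    ``upstream_flank`` / ``downstream_flank`` are read in spacer orientation
    (upstream = 5' of the protospacer), so for a minus-strand hit they are
    reverse complements of forward-strand genome sequence.  Flanks are 10 bp
    unless the protospacer sits near a genome end, in which case they are
    shorter and ``flank_truncated`` is set.
    """

    spacer_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    upstream_flank: str
    downstream_flank: str
    flank_truncated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if (self.strand == "+") != (self.start <= self.end):
            raise ValueError(
                f"strand {self.strand} inconsistent with coordinates "
                f"{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return abs(self.start - self.end) + 1


def _encode(seq: str, fill: int) -> np.ndarray:
    """Bytes of the uppercased sequence; non-ACGT positions replaced by ``fill``.

    Distinct fill values for query and text make ambiguity codes mismatch
    everything, including each other.
    """
    a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    a[~np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8))] = fill
    return a


def _scan(query: np.ndarray, text: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """(offset, mismatches) for every window of ``text`` within ``max_mm`` of ``query``."""
    m = len(query)
    if len(text) < m:
        return []
    windows = sliding_window_view(text, m)
    mm = (windows != query).sum(axis=1)
    idx = np.nonzero(mm <= max_mm)[0]
    return [(int(i), int(mm[i])) for i in idx]


def _flank(genome: str, lo: int, hi: int, circular: bool) -> tuple[str, bool]:
    """genome[lo:hi] with truncation at linear ends or modular wrap when circular."""
    L = len(genome)
    if circular:
        return "".join(genome[i % L] for i in range(lo, hi)), False
    clo, chi = max(lo, 0), min(hi, L)
    return genome[clo:chi], (clo != lo or chi != hi)


def find_hits(
    spacer: str,
    genome: str,
    max_mismatches: int = 2,
    *,
    spacer_id: str = "",
    genome_id: str = "",
    flank_len: int = DEFAULT_FLANK_LEN,
    circular: bool = False,
) -> list[ProtospacerHit]:
    """All placements of ``spacer`` on either strand of ``genome``.

    Returns every placement with Hamming distance <= ``max_mismatches``,
    sorted by (mismatches asc, min(start, end) asc, '+' before '-').  With
    ``circular`` the genome is scanned as a circle (doubled-sequence trick,
    wrapped duplicates removed) and flanks wrap instead of truncating.
    """
    spacer = spacer.upper()
    genome = genome.upper()
    m, L = len(spacer), len(genome)
    if m < 1:
        raise ValueError("empty spacer")
    if m > L:
        raise ValueError(f"spacer ({m} nt) longer than genome ({L} nt)")

    text = _encode(genome * 2 if circular else genome, fill=ord("!"))
    fwd = _encode(spacer, fill=ord("?"))
    rev = _encode(revcomp(spacer), fill=ord("?"))

    hits: list[ProtospacerHit] = []
    for strand, query in (("+", fwd), ("-", rev)):
        for i, mm in _scan(query, text, max_mismatches):
            if circular and i >= L:
                continue  # wrapped duplicate of a first-copy hit
            if strand == "+":
                start, end = i + 1, i + m
                up, up_trunc = _flank(genome, i - flank_len, i, circular)
                down, down_trunc = _flank(genome, i + m, i + m + flank_len, circular)
            else:
                start, end = i + m, i + 1
                up, up_trunc = _flank(genome, i + m, i + m + flank_len, circular)
                down, down_trunc = _flank(genome, i - flank_len, i, circular)
                up, down = revcomp(up), revcomp(down)
            # circular hits crossing the origin keep coordinates extending
            # past L (start stays in 1..L) so start/end still encode strand
            hits.append(
                ProtospacerHit(
                    spacer_id=spacer_id,
                    genome_id=genome_id,
                    start=start,
                    end=end,
                    strand=strand,
                    mismatches=mm,
                    upstream_flank=up,
                    downstream_flank=down,
                    flank_truncated=up_trunc or down_trunc,
                )
            )
    hits.sort(key=lambda h: (h.mismatches, min(h.start, h.end), h.strand))
    return hits


def best_hit(hits: list[ProtospacerHit]) -> tuple[ProtospacerHit | None, bool]:
    """First hit under the canonical sort order, plus an ambiguity flag.

    The flag is set when two or more hits share the minimal mismatch count
    (the spacer has several equally good placements).
    """
    if not hits:
        return None, False
    ordered = sorted(hits, key=lambda h: (h.mismatches, min(h.start, h.end), h.strand))
    ambiguous = len(ordered) > 1 and ordered[1].mismatches == ordered[0].mismatches
    return ordered[0], ambiguous


@dataclass
class MappingReport:
    """Per-spacer best placements and perfect/mismatched/unmapped tallies."""

    best_hits: dict[str, ProtospacerHit | None]
    ambiguous: dict[str, bool]
    categories: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {PERFECT: 0, MISMATCHED: 0, UNMAPPED: 0}
            for cat in self.categories.values():
                self.counts[cat] += 1

    @property
    def n(self) -> int:
        return len(self.categories)

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n
        return {k: (v / n if n else 0.0) for k, v in self.counts.items()}

    def mapped_hits(self) -> list[ProtospacerHit]:
        """Best hits of all mapped (perfect or mismatched) spacers."""
        return [h for h in self.best_hits.values() if h is not None]


def classify_spacers(
    spacers: dict[str, str],
    genome: str,
    max_mismatches: int = 2,
    *,
    genome_id: str = "",
    flank_len: int = DEFAULT_FLANK_LEN,
) -> MappingReport:
    """Map every spacer and categorize it by its best placement.

    Categories are exhaustive and mutually exclusive: ``perfect`` (best hit
    with 0 mismatches), ``mismatched`` (best hit with 1..max_mismatches),
    ``unmapped`` (no placement within budget).
    """
    best: dict[str, ProtospacerHit | None] = {}
    amb: dict[str, bool] = {}
    cats: dict[str, str] = {}
    for sid, seq in spacers.items():
        hits = find_hits(
            seq,
            genome,
            max_mismatches,
            spacer_id=sid,
            genome_id=genome_id,
            flank_len=flank_len,
        )
        hit, ambiguous = best_hit(hits)
        best[sid], amb[sid] = hit, ambiguous
        if hit is None:
            cats[sid] = UNMAPPED
        elif hit.mismatches == 0:
            cats[sid] = PERFECT
        else:
            cats[sid] = MISMATCHED
    return MappingReport(best_hits=best, ambiguous=amb, categories=cats)
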