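"""PAM inference from protospacer flanks.

The protospacer adjacent motif (PAM) is read off the sequences flanking
mapped protospacers: k-mers at a fixed offset from the protospacer boundary
are tabulated, wildcard-motif fractions are computed over the table, and a
positional frequency matrix with per-position information content yields a
consensus call.  For the type II-A system analysed here the signal sits
immediately 3' of the protospacer (5'-NAA/NAAA-3' on the downstream side);
upstream tables serve as the built-in negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import IUPAC, check_dna

from .mapping import ProtospacerHit

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"

BASES = "ACGT"

# Downstream 5-mer counts observed across the 165 protospacers mapped on the
# phage M102AD genome after spacer acquisition by S. mutans P42S (the
# published acquired-PAM frequency table); usable as a reference input for
# motif-fraction computations without re-running the mapping.
P42S_ACQUIRED_PAM_COUNTS: dict[str, int] = {
    "TAAAT": 35, "TAAAA": 23, "CAAAT": 19, "AAAAT": 18, "CAAAA": 11,
    "TAAGT": 10, "AAAAA": 7, "TAAAG": 7, "AAAAG": 3, "AAAGT": 3,
    "TTAAA": 3, "TAAAC": 2, "GAAAT": 2, "AAAAC": 1, "AAATT": 1,
    "AAATC": 1, "AAACC": 1, "AAAGG": 1, "AAATG": 1, "AAGTG": 1,
    "AAGCT": 1, "ATAAA": 1, "TAATA": 1, "TAACA": 1, "TAAGA": 1,
    "TAAGC": 1, "TACAG": 1, "TCAAA": 1, "TCGCC": 1, "TGAAA": 1,
    "CAAAC": 1, "CAAAG": 1, "CAAGT": 1, "CAAGG": 1, "GAAAC": 1,
}


@dataclass
class PamTable:
    """k-mer counts at a fixed offset into the protospacer flanks.

    ``offset`` counts away from the protospacer boundary: offset 1 is the
    first base beyond the protospacer on the chosen side.  ``counts`` is
    ordered by count descending, then lexicographically.  Hits whose flank
    was too short for the window are excluded and tallied in ``n_excluded``.
    """

    side: str
    k: int
    offset: int
    counts: dict[str, int]
    total: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.side not in (UPSTREAM, DOWNSTREAM):
            raise ValueError(f"bad side {self.side!r}")
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts do not sum to total")
        self.counts = dict(
            sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], side: str = DOWNSTREAM, offset: int = 1
    ) -> "PamTable":
        """Build a table directly from a k-mer -> count mapping."""
        if not counts:
            raise ValueError("empty count table")
        ks = {len(k) for k in counts}
        if len(ks) != 1:
            raise ValueError(f"inconsistent k-mer lengths: {sorted(ks)}")
        return cls(
            side=side,
            k=ks.pop(),
            offset=offset,
            counts={check_dna(k, "k-mer"): int(v) for k, v in counts.items()},
            total=int(sum(counts.values())),
        )

    def frequencies(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kmer": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [100.0 * v / self.total for v in self.counts.values()],
            }
        )


def _flank_window(hit: ProtospacerHit, side: str, k: int, offset: int) -> str | None:
    """The k-mer at ``offset`` on ``side`` of the hit, or None if the flank is short.

    Flanks are stored 5'->3' in spacer orientation, so on the downstream side
    offset counts from the left end of the flank and on the upstream side
    from its right end (the base abutting the protospacer).
    """
    if side == DOWNSTREAM:
        flank = hit.downstream_flank
        lo = offset - 1
        hi = lo + k
        if hi > len(flank):
            return None
        return flank[lo:hi]
    flank = hit.upstream_flank
    hi = len(flank) - (offset - 1)
    lo = hi - k
    if lo < 0:
        return None
    return flank[lo:hi]


def build_pam_table(
    hits: list[ProtospacerHit],
    side: str = DOWNSTREAM,
    k: int = 5,
    offset: int = 1,
    flank_len: int = 10,
) -> PamTable:
    """Tabulate the k-mers at a fixed offset in the flanks of mapped hits."""
    if side not in (UPSTREAM, DOWNSTREAM):
        raise ValueError(f"bad side {side!r}")
    if k < 1 or offset < 1:
        raise ValueError("k and offset must be >= 1")
    if k + offset - 1 > flank_len:
        raise ValueError(
            f"window k={k} at offset={offset} exceeds flank length {flank_len}"
        )
    counts: dict[str, int] = {}
    excluded = 0
    for hit in hits:
        kmer = _flank_window(hit, side, k, offset)
        if kmer is None:
            excluded += 1
            continue
        counts[kmer] = counts.get(kmer, 0) + 1
    return PamTable(
        side=side,
        k=k,
        offset=offset,
        counts=counts,
        total=len(hits) - excluded,
        n_excluded=excluded,
    )


def motif_fraction(
    table: PamTable, pattern: str, anchor: int = 1
) -> tuple[int, float]:
    """Count table k-mers matching an IUPAC pattern anchored inside the k-mer.

    ``anchor`` is the 1-based k-mer position where the pattern starts
    (default 1).  N matches any base.  Returns (count, count/total).
    """
    pattern = pattern.upper()
    for c in pattern:
        if c not in IUPAC:
            raise ValueError(f"non-IUPAC symbol {c!r} in pattern")
    if anchor < 1 or anchor - 1 + len(pattern) > table.k:
        raise ValueError(
            f"pattern {pattern!r} at anchor {anchor} does not fit in {table.k}-mers"
        )
    count = 0
    for kmer, n in table.counts.items():
        window = kmer[anchor - 1 : anchor - 1 + len(pattern)]
        if all(b in IUPAC[p] for b, p in zip(window, pattern)):
            count += n
    return count, count / table.total


@dataclass
class PositionalFrequencyMatrix:
    """Per-position base frequencies and information content in a flank.

    Position 1 is the base nearest the protospacer on the given side,
    counting outward.  Information content per position is
    ``2 + sum_b f_b log2 f_b`` bits (0 log 0 := 0), i.e. 2 bits for a fully
    conserved position and 0 for a uniform one.
    """

    side: str
    counts: np.ndarray  # shape (width, 4), base order ACGT
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (width, 4)")
        totals = self.counts.sum(axis=1)
        if len(set(totals.tolist())) > 1:
            raise ValueError("unequal column totals")
        self.n = int(totals[0]) if len(totals) else 0

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        if self.n == 0:
            return np.zeros_like(self.counts)
        return self.counts / self.n

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits, in [0, 2]."""
        f = self.frequencies()
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(f > 0, f * np.log2(f), 0.0)
        return np.clip(2.0 + term.sum(axis=1), 0.0, 2.0)

    def consensus(self, threshold: float = 0.75) -> str:
        """Consensus string: the base whose frequency >= threshold, else N."""
        f = self.frequencies()
        out = []
        for p in range(self.width):
            j = int(np.argmax(f[p]))
            out.append(BASES[j] if f[p, j] >= threshold else "N")
        return "".join(out)

    def to_frame(self) -> pd.DataFrame:
        f = self.frequencies()
        ic = self.information_content()
        return pd.DataFrame(
            {
                "position": np.arange(1, self.width + 1),
                **{b: f[:, i] for i, b in enumerate(BASES)},
                "IC_bits": ic,
            }
        )


def build_pfm(
    hits: list[ProtospacerHit],
    side: str = DOWNSTREAM,
    width: int = 10,
) -> PositionalFrequencyMatrix:
    """Positional frequency matrix over flank positions 1..width.

    Only hits whose flank covers the full width contribute, so all positions
    share one column total.
    """
    if side not in (UPSTREAM, DOWNSTREAM):
        raise ValueError(f"bad side {side!r}")
    counts = np.zeros((width, 4), dtype=float)
    index = {b: i for i, b in enumerate(BASES)}
    for hit in hits:
        flank = hit.downstream_flank if side == DOWNSTREAM else hit.upstream_flank
        if len(flank) < width:
            continue
        # orient so position 1 abuts the protospacer
        oriented = flank[:width] if side == DOWNSTREAM else flank[::-1][:width]
        if any(b not in index for b in oriented):
            continue
        for p, b in enumerate(oriented):
            counts[p, index[b]] += 1
    return PositionalFrequencyMatrix(side=side, counts=counts)


def count_genome_motif(genome: str, motif: str) -> int:
    """Occurrences of ``motif`` on the forward strand, overlaps included.

    Counting is overlapping by convention ('AAAA' contains 'AA' three
    times) and single-stranded; genome background motif abundances (e.g.
    AA vs GAA in an AT-rich phage genome) are compared on this basis.
    """
    motif = check_dna(motif, "motif")
    genome = genome.upper()
    count = 0
    i = genome.find(motif)
    while i != -1:
        count += 1
        i = genome.find(motif, i + 1)
    return count
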