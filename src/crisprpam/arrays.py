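"""CRISPR array parsing and spacer-acquisition event calling.

A type II-A CRISPR array is a run of near-identical direct repeats (here a
36-bp consensus) separated by variable spacers of roughly 28-32 bp.  New
spacers are integrated during adaptation, canonically at the leader-proximal
(5') end of the array ("polar" acquisition) but occasionally between
pre-existing spacers ("ectopic" acquisition).  This module locates repeat
occurrences in raw amplicon or locus sequence, extracts the spacers between
them, and calls acquisition events by aligning a mutant (BIM) array against
the wild-type array.

Repeat matching is Hamming-only (no indels): the only repeat variant seen in
these loci is a terminal substitution, and substitution-only matching keeps
the parser exactly invertible against the simulator.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field

from ._seq import check_dna, hamming, revcomp

# Direct repeat of the S. mutans P42S type II-A array (5'->3') and the
# degenerate terminal repeat, which differs at the final base (C->T).
P42S_REPEAT = "GTTTTAGAGCTGTGTTGTTTCGAATGGTTCCAAAAC"
P42S_TERMINAL_REPEAT = "GTTTTAGAGCTGTGTTGTTTCGAATGGTTCCAAAAT"

DEFAULT_SPACER_LEN_WINDOW = (20, 45)

POLAR = "polar"
ECTOPIC = "ectopic"


@dataclass(frozen=True)
class RepeatSpec:
    """Canonical direct repeat plus per-repeat mismatch budgets.

    Terminal repeats of an array degenerate faster than internal ones, so
    they get their own (never smaller) budget.
    """

    consensus: str
    max_mismatches_internal: int = 2
    max_mismatches_terminal: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "consensus", check_dna(self.consensus, "repeat consensus"))
        if not self.consensus:
            raise ValueError("repeat consensus must be non-empty")
        if self.max_mismatches_internal < 0 or self.max_mismatches_terminal < 0:
            raise ValueError("mismatch budgets must be >= 0")
        if self.max_mismatches_terminal < self.max_mismatches_internal:
            raise ValueError(
                "terminal mismatch budget must be >= internal budget "
                f"({self.max_mismatches_terminal} < {self.max_mismatches_internal})"
            )

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class CrisprArray:
    """An ordered CRISPR array; spacer index 1 is leader-proximal (5').

    ``repeats`` holds the observed repeat sequences flanking the spacers
    (one more repeat than spacers); it may be None for arrays reconstructed
    from a spacer table where the repeats were not recorded.  Duplicated
    spacer sequences are permitted: arrays that acquired the same spacer
    twice occur in real BIMs.
    """

    array_id: str
    spacers: list[str]
    repeats: list[str] | None = None
    source_span: tuple[int, int] | None = None
    is_reverse: bool = False

    def __post_init__(self) -> None:
        self.spacers = [check_dna(s, "spacer") for s in self.spacers]
        if self.repeats is not None:
            self.repeats = [check_dna(r, "repeat") for r in self.repeats]
            if self.spacers or self.repeats:
                if len(self.repeats) != len(self.spacers) + 1:
                    raise ValueError(
                        f"array {self.array_id!r}: expected {len(self.spacers) + 1} "
                        f"repeats for {len(self.spacers)} spacers, got {len(self.repeats)}"
                    )

    def __len__(self) -> int:
        return len(self.spacers)

    def validate(
        self,
        repeat_spec: RepeatSpec,
        spacer_len_window: tuple[int, int] = DEFAULT_SPACER_LEN_WINDOW,
    ) -> None:
        """Check repeat budgets and spacer lengths; raise ValueError on violation."""
        lo, hi = spacer_len_window
        for i, s in enumerate(self.spacers, 1):
            if not lo <= len(s) <= hi:
                raise ValueError(
                    f"array {self.array_id!r}: spacer {i} length {len(s)} "
                    f"outside window [{lo}, {hi}]"
                )
        if self.repeats is None:
            return
        n = len(self.repeats)
        for i, r in enumerate(self.repeats):
            budget = (
                repeat_spec.max_mismatches_terminal
                if i in (0, n - 1)
                else repeat_spec.max_mismatches_internal
            )
            d = hamming(r, repeat_spec.consensus)
            if d > budget:
                raise ValueError(
                    f"array {self.array_id!r}: repeat {i + 1} at Hamming distance "
                    f"{d} from consensus (budget {budget})"
                )


@dataclass(frozen=True)
class AcquisitionEvent:
    """One newly acquired spacer relative to the native array.

    ``insertion_index`` is relative to native spacer numbering: 0 means the
    5'/leader end (polar); i >= 1 means between native spacers i and i+1
    (ectopic).  ``ambiguous`` flags a new spacer whose sequence equals a
    native spacer, where the backbone alignment had a choice (resolved
    leftmost).
    """

    spacer: str
    insertion_index: int
    classification: str
    bim_id: str = ""
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.classification not in (POLAR, ECTOPIC):
            raise ValueError(f"bad classification {self.classification!r}")
        if (self.insertion_index == 0) != (self.classification == POLAR):
            raise ValueError(
                f"insertion_index {self.insertion_index} inconsistent with "
                f"classification {self.classification!r}"
            )


# ---------------------------------------------------------------------------
# Repeat detection and array parsing
# ---------------------------------------------------------------------------

def _repeat_candidates(sequence: str, consensus: str, budget: int) -> list[tuple[int, int]]:
    """All 0-based offsets where the window is within ``budget`` of ``consensus``."""
    L = len(consensus)
    out = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        # early-exit Hamming
        d = 0
        for x, y in zip(window, consensus):
            if x != y:
                d += 1
                if d > budget:
                    break
        else:
            out.append((i, d))
    return out


def _chain_candidates(
    cands: list[tuple[int, int]], repeat_len: int, spacer_len_window: tuple[int, int]
) -> list[list[tuple[int, int]]]:
    """Split candidates into maximal runs whose inter-repeat gaps are valid spacers."""
    lo, hi = spacer_len_window
    runs: list[list[tuple[int, int]]] = []
    for cand in cands:
        if runs:
            prev = runs[-1][-1]
            gap = cand[0] - (prev[0] + repeat_len)
            if lo <= gap <= hi:
                runs[-1].append(cand)
                continue
        runs.append([cand])
    return runs


def parse_array(
    sequence: str,
    repeat_spec: RepeatSpec,
    spacer_len_window: tuple[int, int] = DEFAULT_SPACER_LEN_WINDOW,
    array_id: str = "",
) -> CrisprArray:
    """Parse a CRISPR array out of raw sequence using the repeat consensus.

    Finds the maximal chain of repeat occurrences (each within its mismatch
    budget) whose inter-repeat gaps fall inside ``spacer_len_window``, and
    reports the gaps as spacers, 5'->3' in the orientation in which the
    repeats match the consensus.  If the repeats only match the reverse
    complement, the input is reverse-complemented before parsing and the
    result is flagged ``is_reverse``.

    A sequence with no repeat occurrence yields an empty array with a
    warning, not an exception.  Overlapping repeat candidates (which would
    make spacer extraction ambiguous) raise ValueError naming the offending
    coordinates.
    """
    seq = check_dna(sequence, "array sequence")
    consensus = repeat_spec.consensus
    L = len(consensus)
    min_len = 2 * L + spacer_len_window[0]
    if len(seq) < min_len:
        raise ValueError(
            f"sequence too short to hold an array: {len(seq)} < {min_len}"
        )

    budget = repeat_spec.max_mismatches_terminal
    cands = _repeat_candidates(seq, consensus, budget)
    is_reverse = False
    if not cands:
        rc = revcomp(seq)
        rc_cands = _repeat_candidates(rc, consensus, budget)
        if rc_cands:
            seq, cands, is_reverse = rc, rc_cands, True
    if not cands:
        warnings.warn(
            f"no repeat occurrence found in {array_id or 'sequence'}; returning empty array",
            stacklevel=2,
        )
        return CrisprArray(array_id=array_id, spacers=[], repeats=[], is_reverse=False)

    for (i, _), (j, _) in zip(cands, cands[1:]):
        if j < i + L:
            raise ValueError(
                f"overlapping repeat candidates at offsets {i} and {j} "
                f"(repeat length {L})"
            )

    runs = _chain_candidates(cands, L, spacer_len_window)
    best = max(runs, key=lambda r: (len(r), -r[0][0]))

    repeats = [seq[i : i + L] for i, _ in best]
    spacers = [
        seq[i + L : j] for (i, _), (j, _) in zip(best, best[1:])
    ]
    first, last = best[0][0], best[-1][0] + L
    arr = CrisprArray(
        array_id=array_id,
        spacers=spacers,
        repeats=repeats,
        source_span=(first + 1, last),
        is_reverse=is_reverse,
    )
    arr.validate(repeat_spec, spacer_len_window)
    return arr


# ---------------------------------------------------------------------------
# Acquisition-event calling
# ---------------------------------------------------------------------------

def diff_arrays(native: CrisprArray, bim: CrisprArray) -> list[AcquisitionEvent]:
    """Call acquisition events by diffing a BIM array against the native array.

    The native spacer list must be an ordered subsequence of the BIM spacer
    list (adaptation only inserts spacers).  Every BIM spacer absent from the
    aligned native backbone becomes an event with its insertion index in
    native numbering; a contiguous run of new spacers upstream of native
    spacer 1 is polar (each event labelled polar), anything deeper is
    ectopic.  Events are reported 5'->3'.  Where a new spacer duplicates a
    native spacer the backbone takes the leftmost placement and the event is
    flagged ambiguous.
    """
    backbone: list[int] = []  # BIM position of each native spacer
    j = 0
    for i, s in enumerate(native.spacers):
        while j < len(bim.spacers) and bim.spacers[j] != s:
            j += 1
        if j == len(bim.spacers):
            raise ValueError(
                f"native array is not a subsequence of BIM array "
                f"{bim.array_id!r}: native spacer {i + 1} ({s}) not found in order "
                "(deletion or rearrangement?)"
            )
        backbone.append(j)
        j += 1

    matched = set(backbone)
    native_set = set(native.spacers)
    events: list[AcquisitionEvent] = []
    for pos, s in enumerate(bim.spacers):
        if pos in matched:
            continue
        # number of native spacers 5' of this insertion
        insertion_index = bisect_left(backbone, pos)
        events.append(
            AcquisitionEvent(
                spacer=s,
                insertion_index=insertion_index,
                classification=POLAR if insertion_index == 0 else ECTOPIC,
                bim_id=bim.array_id,
                ambiguous=s in native_set,
            )
        )
    return events


# ---------------------------------------------------------------------------
# tracrRNA anti-repeat search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AntiRepeatMatch:
    """Best local repeat/anti-repeat match inside a candidate region.

    ``offset`` is 0-based on the reported strand of the candidate region
    ('+' = region as given, '-' = its reverse complement); ``repeat_offset``
    is the 0-based start of the matched sub-window within the repeat.
    """

    offset: int
    length: int
    matches: int
    strand: str
    repeat_offset: int


def find_anti_repeat(
    candidate_region: str,
    repeat: str,
    min_window: int = 20,
    max_mismatches: int = 2,
) -> AntiRepeatMatch | None:
    """Locate the anti-repeat of a tracrRNA candidate against the crRNA repeat.

    Scans both strands of ``candidate_region`` for the window of length >=
    ``min_window`` maximizing identities to a same-length sub-window of the
    repeat, keeping only windows with at most ``max_mismatches`` mismatches.
    (Scanning both strands of the region also covers matches to the reverse
    complement of the repeat.)  Ties are broken by longer window, then
    smaller offset, then '+' strand.  Returns None when no window qualifies.
    """
    region = check_dna(candidate_region, "candidate region")
    rep = check_dna(repeat, "repeat")
    if len(region) <= min_window:
        raise ValueError(
            f"candidate region ({len(region)} nt) must be longer than min_window ({min_window})"
        )

    best: AntiRepeatMatch | None = None
    best_key: tuple[int, int, int, int] | None = None
    max_len = min(len(rep), len(region))
    for strand, seq in (("+", region), ("-", revcomp(region))):
        for w in range(min_window, max_len + 1):
            for ro in range(len(rep) - w + 1):
                sub = rep[ro : ro + w]
                for off in range(len(seq) - w + 1):
                    window = seq[off : off + w]
                    m = sum(x == y for x, y in zip(window, sub))
                    if w - m > max_mismatches:
                        continue
                    key = (m, w, -off, 0 if strand == "+" else -1)
                    if best_key is None or key > best_key:
                        best_key = key
                        best = AntiRepeatMatch(
                            offset=off, length=w, matches=m, strand=strand, repeat_offset=ro
                        )
    return best
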