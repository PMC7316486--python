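"""PAM-acceptance rules and interference target prediction.

Plasmid interference assays pin down which 3'-flanking 5-mers license Cas9
cleavage.  For the S. mutans P42S system the experimentally determined rule
is: position 3 must be adenine, and position 2 must be adenine — unless it
is guanine, which is tolerated only when position 4 is adenine.  That is
exactly the union of the patterns NAANN and NGAAN (80 of the 1024 possible
5-mers); positions 1 and 5, and position 4 when position 2 is A, never
affect acceptance.

``scan_construct`` applies a rule to predict whether a plasmid or genome
sequence is targeted by a CRISPR array: targeted means at least one spacer
has a full placement within the mismatch budget whose downstream 5-mer the
rule accepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from ._seq import DNA_ALPHABET
from .arrays import CrisprArray
from .mapping import ProtospacerHit, find_hits

PAM_WIDTH = 5


@dataclass(frozen=True)
class PamRule:
    """A named, total, deterministic predicate over PAM 5-mers."""

    name: str
    predicate: Callable[[str], bool]

    def __call__(self, pam: str) -> bool:
        return pam_accepted(pam, self)


#: Acceptance rule of the S. mutans P42S type II-A system: NAA or NGAA at
#: the protospacer 3' end.
P42S_RULE = PamRule(
    "P42S",
    lambda p: p[2] == "A" and (p[1] == "A" or (p[1] == "G" and p[3] == "A")),
)

#: The canonical S. pyogenes-style rule (NGG immediately 3'), for swapping in.
NGG_RULE = PamRule("NGG", lambda p: p[1] == "G" and p[2] == "G")

RULES: dict[str, PamRule] = {r.name: r for r in (P42S_RULE, NGG_RULE)}


def pam_accepted(pam: str, rule: PamRule = P42S_RULE) -> bool:
    """Evaluate a 5-mer under a PAM rule.

    Raises ValueError unless ``pam`` is exactly 5 bases of A/C/G/T.
    """
    pam = pam.upper()
    if len(pam) != PAM_WIDTH:
        raise ValueError(f"PAM must be {PAM_WIDTH} nt, got {len(pam)}")
    if set(pam) - DNA_ALPHABET:
        raise ValueError(f"PAM contains non-ACGT symbols: {pam!r}")
    return bool(rule.predicate(pam))


@dataclass(frozen=True)
class SupportingMatch:
    """One spacer placement on a construct with its PAM evaluation."""

    spacer_index: int  # 1-based index in the array
    hit: ProtospacerHit
    pam: str
    pam_accepted: bool


@dataclass
class TargetPrediction:
    """Predicted interference outcome for one construct.

    ``targeted`` is True iff at least one supporting match is within the
    mismatch budget and carries an accepted PAM.
    """

    construct_id: str
    targeted: bool
    matches: list[SupportingMatch] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "construct_id": self.construct_id,
            "targeted": self.targeted,
            "matches": [
                {
                    "spacer_index": m.spacer_index,
                    "start": m.hit.start,
                    "end": m.hit.end,
                    "strand": m.hit.strand,
                    "mismatches": m.hit.mismatches,
                    "pam": m.pam,
                    "pam_accepted": m.pam_accepted,
                }
                for m in self.matches
            ],
        }


def scan_construct(
    array: CrisprArray,
    construct: str,
    circular: bool = True,
    rule: PamRule = P42S_RULE,
    max_mismatches: int = 0,
    construct_id: str = "",
) -> TargetPrediction:
    """Predict whether a construct is targeted by any spacer of an array.

    Every spacer is mapped onto the construct (as a circle by default, the
    usual plasmid case); each placement's downstream 5-mer is evaluated
    under ``rule``.  Interference requires a full-length spacer match within
    ``max_mismatches`` (default 0, the stringency probed by plasmid assays)
    plus an accepted PAM.
    """
    if not construct:
        raise ValueError("empty construct sequence")
    matches: list[SupportingMatch] = []
    targeted = False
    for idx, spacer in enumerate(array.spacers, 1):
        if len(spacer) > len(construct):
            continue
        hits = find_hits(
            spacer,
            construct,
            max_mismatches,
            spacer_id=f"spacer{idx}",
            genome_id=construct_id,
            circular=circular,
        )
        for hit in hits:
            pam = hit.downstream_flank[:PAM_WIDTH]
            ok = len(pam) == PAM_WIDTH and not (set(pam) - DNA_ALPHABET)
            accepted = pam_accepted(pam, rule) if ok else False
            matches.append(SupportingMatch(idx, hit, pam, accepted))
            targeted = targeted or accepted
    return TargetPrediction(construct_id=construct_id, targeted=targeted, matches=matches)
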