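"""Synthetic phage genomes and BIM cohorts with ground-truth labels.

The generator emulates the study system end to end: an AT-rich ~30 kb phage
genome; a native five-spacer CRISPR array; and a cohort of
bacteriophage-insensitive mutants (BIMs) whose arrays carry newly acquired
spacers drawn from the genome.  Acquisition follows the observed statistics:
spacer lengths 28-32 bp with mode 30, ~88% perfect protospacer matches and
~10% carrying 1-2 substitutions, a small fraction of non-phage (host-like)
spacers, mostly polar (5'-end) insertions with occasional ectopic ones, and
a configurable preference for PAM-rule-satisfying 3' flanks.

Every sampled event is recorded in a truth table so each pipeline stage can
be validated by parameter recovery.  Protospacer positions are drawn
uniformly along the genome (rejection-sampled against the PAM predicate);
no positional hotspots are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp
from .arrays import (
    ECTOPIC,
    P42S_REPEAT,
    P42S_TERMINAL_REPEAT,
    POLAR,
    CrisprArray,
)
from .interference import P42S_RULE, RULES, PamRule

BASES = "ACGT"

DEFAULT_SPACER_LEN_DIST = {30: 0.68, 31: 0.27, 32: 0.03, 29: 0.01, 28: 0.01}
# most BIMs pick up one or two spacers; up to seven has been seen once
DEFAULT_SPACERS_PER_BIM = {1: 0.45, 2: 0.25, 3: 0.12, 4: 0.08, 5: 0.05, 6: 0.03, 7: 0.02}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the characterized system: a 30,664-bp genome at 35% GC,
    spacer length spectrum peaked at 30 bp, 10% mismatched spacers, 2%
    non-phage spacers, 93% of acquisitions obeying the PAM rule, and roughly
    one in seven events ectopic.
    """

    seed: int = 0
    genome_length: int = 30664
    gc_fraction: float = 0.35
    n_bims: int = 100
    spacers_per_bim_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SPACERS_PER_BIM)
    )
    spacer_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SPACER_LEN_DIST)
    )
    pam_rule: PamRule = P42S_RULE
    acquisition_pam_obedience: float = 0.93
    mismatch_rate: float = 0.10
    non_phage_rate: float = 0.02
    ectopic_rate: float = 0.14
    n_native_spacers: int = 5

    def __post_init__(self) -> None:
        for name in ("spacers_per_bim_distribution", "spacer_length_distribution"):
            dist = getattr(self, name)
            if not dist or abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probabilities")
        for name in (
            "gc_fraction",
            "acquisition_pam_obedience",
            "mismatch_rate",
            "non_phage_rate",
            "ectopic_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if isinstance(d.get("pam_rule"), str):
            d["pam_rule"] = RULES[d["pam_rule"]]
        for key in ("spacers_per_bim_distribution", "spacer_length_distribution"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass(frozen=True)
class TruthEvent:
    """Ground truth for one acquisition event.

    Coordinates follow the mapping convention (1-based inclusive, start >
    end on the minus strand); they are None for non-phage spacers.  ``pam``
    is the downstream 5-mer at the sampled site, in spacer orientation.
    """

    spacer: str
    start: int | None
    end: int | None
    strand: str | None
    mismatches: int
    insertion_index: int
    classification: str
    pam: str | None


@dataclass
class BimTruth:
    bim_id: str
    events: list[TruthEvent]


TruthTable = list[BimTruth]


def _sample_dist(rng: np.random.Generator, dist: dict[int, float]) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def _random_dna(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=p))


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def gen_genome(config: SimulationConfig) -> SeqRecord:
    """An i.i.d. random genome at the configured length and GC fraction."""
    if config.genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    rng = np.random.default_rng([config.seed, 11])
    seq = _random_dna(rng, config.genome_length, _base_probs(config.gc_fraction))
    return SeqRecord(
        Seq(seq), id="sim_phage", description="synthetic AT-rich phage genome"
    )


def gen_native_array(config: SimulationConfig, array_id: str = "WT") -> CrisprArray:
    """A native array of random spacers between consensus repeats.

    Native spacers are drawn independently of the phage genome (the real
    native spacers showed essentially no identity to the challenging phage).
    """
    rng = np.random.default_rng([config.seed, 13])
    p = _base_probs(0.40)
    spacers = [
        _random_dna(rng, int(rng.integers(29, 32)), p)
        for _ in range(config.n_native_spacers)
    ]
    repeats = [P42S_REPEAT] * len(spacers) + [P42S_TERMINAL_REPEAT]
    return CrisprArray(array_id=array_id, spacers=spacers, repeats=repeats)


def _sample_protospacer(
    rng: np.random.Generator,
    genome: str,
    length: int,
    rule: PamRule,
    want_obedient: bool,
    max_tries: int = 20000,
) -> tuple[str, int, int, str, str]:
    """One uniform protospacer whose downstream 5-mer does/doesn't satisfy the rule.

    Returns (spacer, start, end, strand, pam) in mapping coordinates.
    """
    L = len(genome)
    for _ in range(max_tries):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            if L - length - 5 < 0:
                break
            i = int(rng.integers(0, L - length - 5 + 1))
            proto = genome[i : i + length]
            pam = genome[i + length : i + length + 5]
            start, end = i + 1, i + length
            spacer = proto
        else:
            i = int(rng.integers(5, L - length + 1))
            proto = genome[i : i + length]
            pam = revcomp(genome[i - 5 : i])
            start, end = i + length, i + 1
            spacer = revcomp(proto)
        if rule(pam) == want_obedient:
            return spacer, start, end, strand, pam
    raise RuntimeError(
        "no protospacer site with the requested PAM status found in the genome"
    )


def _mutate(rng: np.random.Generator, spacer: str, n_mut: int) -> str:
    positions = rng.choice(len(spacer), size=n_mut, replace=False)
    chars = list(spacer)
    for p in positions:
        chars[p] = rng.choice([b for b in BASES if b != chars[p]])
    return "".join(chars)


def _random_non_phage(
    rng: np.random.Generator, genome: str, length: int, gc: float
) -> str:
    """A random spacer guaranteed absent from either strand of the genome."""
    rc = revcomp(genome)
    for _ in range(100):
        s = _random_dna(rng, length, _base_probs(gc))
        if s not in genome and s not in rc:
            return s
    raise RuntimeError("could not draw a genome-absent spacer")


def simulate_bims(
    genome: SeqRecord | str,
    native_array: CrisprArray,
    config: SimulationConfig,
) -> tuple[list[SeqRecord], TruthTable]:
    """Sample a BIM cohort and emit amplicon sequences plus a truth table.

    Every BIM acquires >= 1 spacer (the cohort models the screened,
    spacer-positive colonies).  Each event samples, in order: whether the
    spacer is non-phage; its length; whether the site obeys the PAM rule;
    whether 1-2 substitutions are applied; and whether insertion is polar
    (index 0) or ectopic (uniform between native spacers).  The amplicon is
    rebuilt as repeat-spacer-...-terminal-repeat with short random pads.
    """
    if len(native_array) < 2:
        raise ValueError("native array needs >= 2 spacers to express ectopic insertions")
    g = str(genome.seq) if isinstance(genome, SeqRecord) else genome
    g = g.upper()
    rng = np.random.default_rng([config.seed, 17])
    pads = _base_probs(0.40)

    records: list[SeqRecord] = []
    truth: TruthTable = []
    for b in range(config.n_bims):
        bim_id = f"BIM{b + 1}"
        n_events = _sample_dist(rng, config.spacers_per_bim_distribution)
        events: list[TruthEvent] = []
        for _ in range(n_events):
            length = _sample_dist(rng, config.spacer_length_distribution)
            if rng.random() < config.non_phage_rate:
                spacer = _random_non_phage(rng, g, length, config.gc_fraction)
                start = end = strand = pam = None
                mismatches = 0
            else:
                want = rng.random() < config.acquisition_pam_obedience
                spacer, start, end, strand, pam = _sample_protospacer(
                    rng, g, length, config.pam_rule, want
                )
                mismatches = 0
                if rng.random() < config.mismatch_rate:
                    mismatches = int(rng.integers(1, 3))
                    spacer = _mutate(rng, spacer, mismatches)
            if rng.random() < config.ectopic_rate:
                idx = int(rng.integers(1, len(native_array)))
                cls = ECTOPIC
            else:
                idx, cls = 0, POLAR
            events.append(
                TruthEvent(spacer, start, end, strand, mismatches, idx, cls, pam)
            )

        spacers = list(native_array.spacers)
        for ev in sorted(
            (e for e in events if e.classification == ECTOPIC),
            key=lambda e: -e.insertion_index,
        ):
            spacers.insert(ev.insertion_index, ev.spacer)
        polar_run = [e.spacer for e in events if e.classification == POLAR]
        spacers = polar_run + spacers

        repeat = (native_array.repeats or [P42S_REPEAT])[0]
        terminal = (native_array.repeats or [None, P42S_TERMINAL_REPEAT])[-1]
        body = "".join(repeat + s for s in spacers) + terminal
        amplicon = (
            _random_dna(rng, 25, pads) + body + _random_dna(rng, 25, pads)
        )
        records.append(
            SeqRecord(Seq(amplicon), id=bim_id, description="synthetic BIM amplicon")
        )
        truth.append(BimTruth(bim_id=bim_id, events=events))
    return records, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[SeqRecord, CrisprArray, list[SeqRecord], TruthTable]:
    """Convenience wrapper: genome, native array, BIM amplicons, truth table."""
    genome = gen_genome(config)
    native = gen_native_array(config)
    bims, truth = simulate_bims(genome, native, config)
    return genome, native, bims, truth


def truth_to_frame(truth: TruthTable) -> pd.DataFrame:
    """Flatten a truth table to one row per event."""
    rows = []
    for bt in truth:
        for ev in bt.events:
            rows.append(
                {
                    "bim_id": bt.bim_id,
                    "spacer": ev.spacer,
                    "start": ev.start,
                    "end": ev.end,
                    "strand": ev.strand,
                    "mismatches": ev.mismatches,
                    "insertion_index": ev.insertion_index,
                    "classification": ev.classification,
                    "pam": ev.pam,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "bim_id",
            "spacer",
            "start",
            "end",
            "strand",
            "mismatches",
            "insertion_index",
            "classification",
            "pam",
        ],
    )
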