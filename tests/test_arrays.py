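"""Array parsing, acquisition-event calling, and anti-repeat search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprpam import (
    P42S_REPEAT,
    P42S_TERMINAL_REPEAT,
    CrisprArray,
    RepeatSpec,
    diff_arrays,
    find_anti_repeat,
    parse_array,
    revcomp,
)

from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=28, max_size=32)


def build_amplicon(spacers, repeat=P42S_REPEAT, terminal=P42S_TERMINAL_REPEAT):
    return "".join(repeat + s for s in spacers) + terminal


class TestParseArray:
    def test_printed_repeat_and_terminal_variant(self, repeat_spec):
        """The canonical 36-mer chains with the 1-mismatch terminal variant."""
        rng = np.random.default_rng(0)
        s1, s2 = random_dna(rng, 30), random_dna(rng, 30)
        seq = P42S_REPEAT + s1 + P42S_REPEAT + s2 + P42S_TERMINAL_REPEAT
        arr = parse_array(seq, repeat_spec)
        assert arr.spacers == [s1, s2]
        assert arr.repeats == [P42S_REPEAT, P42S_REPEAT, P42S_TERMINAL_REPEAT]
        assert not arr.is_reverse

    def test_no_repeat_yields_empty_array_with_warning(self, repeat_spec):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 300)
        assert P42S_REPEAT not in seq
        with pytest.warns(UserWarning, match="no repeat"):
            arr = parse_array(seq, repeat_spec)
        assert arr.spacers == [] and arr.repeats == []

    def test_too_short_sequence_raises(self, repeat_spec):
        with pytest.raises(ValueError, match="too short"):
            parse_array("ACGT" * 10, repeat_spec)

    def test_orientation_invariance(self, repeat_spec):
        """Reverse-complemented input yields the same spacers, flagged reverse."""
        rng = np.random.default_rng(2)
        spacers = [random_dna(rng, 30) for _ in range(3)]
        seq = random_dna(rng, 40) + build_amplicon(spacers) + random_dna(rng, 40)
        fwd = parse_array(seq, repeat_spec)
        rev = parse_array(revcomp(seq), repeat_spec)
        assert fwd.spacers == rev.spacers == spacers
        assert not fwd.is_reverse and rev.is_reverse

    def test_overlapping_repeat_candidates_raise_with_coordinates(self):
        """A periodic consensus creates overlapping matches, which is an error."""
        spec = RepeatSpec("AT" * 18, 0, 0)
        seq = "G" * 30 + "AT" * 40 + "G" * 60
        with pytest.raises(ValueError, match="overlapping repeat candidates at offsets"):
            parse_array(seq, spec)

    def test_round_trip_of_synthetic_arrays(self, repeat_spec):
        """Serialize -> parse recovers spacer lists exactly (50 random arrays)."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 11))
            spacers = [random_dna(rng, int(rng.integers(28, 33))) for _ in range(n)]
            arr = parse_array(build_amplicon(spacers), repeat_spec)
            assert arr.spacers == spacers
            assert len(arr.repeats) == len(arr.spacers) + 1

    def test_repeat_budget_enforced(self):
        """An internal repeat beyond its mismatch budget is rejected."""
        rng = np.random.default_rng(4)
        bad = "AAA" + P42S_REPEAT[3:]  # 3 mismatches, internal budget is 2
        spacers = [random_dna(rng, 30) for _ in range(3)]
        seq = (
            P42S_REPEAT + spacers[0] + bad + spacers[1] + P42S_REPEAT
            + spacers[2] + P42S_TERMINAL_REPEAT
        )
        with pytest.raises(ValueError, match="Hamming distance"):
            parse_array(seq, RepeatSpec(P42S_REPEAT, 2, 3))


class TestRepeatSpec:
    def test_terminal_budget_must_cover_internal(self):
        with pytest.raises(ValueError, match="terminal"):
            RepeatSpec(P42S_REPEAT, max_mismatches_internal=3, max_mismatches_terminal=1)

    def test_non_dna_consensus_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            RepeatSpec("ACGTN")


class TestDiffArrays:
    @staticmethod
    def arr(spacers, array_id="A"):
        return CrisprArray(array_id=array_id, spacers=list(spacers))

    def test_identity_yields_no_events(self):
        rng = np.random.default_rng(5)
        a = self.arr([random_dna(rng, 30) for _ in range(5)])
        assert diff_arrays(a, a) == []

    def test_single_polar_insertion(self):
        rng = np.random.default_rng(6)
        native = [random_dna(rng, 30) for _ in range(5)]
        new = random_dna(rng, 30)
        events = diff_arrays(self.arr(native), self.arr([new] + native, "B"))
        assert len(events) == 1
        ev = events[0]
        assert (ev.spacer, ev.insertion_index, ev.classification) == (new, 0, "polar")

    def test_polar_run_all_labelled_polar(self):
        rng = np.random.default_rng(7)
        native = [random_dna(rng, 30) for _ in range(5)]
        run = [random_dna(rng, 30) for _ in range(3)]
        events = diff_arrays(self.arr(native), self.arr(run + native, "B"))
        assert [e.spacer for e in events] == run
        assert all(e.insertion_index == 0 and e.classification == "polar" for e in events)

    def test_ectopic_between_spacers_4_and_5(self):
        rng = np.random.default_rng(8)
        native = [random_dna(rng, 30) for _ in range(5)]
        new = random_dna(rng, 30)
        bim = native[:4] + [new] + native[4:]
        events = diff_arrays(self.arr(native), self.arr(bim, "B"))
        assert len(events) == 1
        ev = events[0]
        assert (ev.spacer, ev.insertion_index, ev.classification) == (new, 4, "ectopic")

    def test_deletion_raises_naming_first_mismatch(self):
        rng = np.random.default_rng(9)
        native = [random_dna(rng, 30) for _ in range(5)]
        with pytest.raises(ValueError, match="native spacer 3"):
            diff_arrays(self.arr(native), self.arr(native[:2] + native[3:], "B"))

    def test_duplicate_of_native_spacer_flagged_ambiguous(self):
        rng = np.random.default_rng(10)
        native = [random_dna(rng, 30) for _ in range(5)]
        bim = [native[0]] + native  # re-acquired copy of native spacer 1
        events = diff_arrays(self.arr(native), self.arr(bim, "B"))
        assert len(events) == 1
        assert events[0].ambiguous
        # leftmost backbone placement puts the new copy at the deepest index
        assert events[0].classification == "ectopic"

    def test_simulated_bims_fully_recovered(self, clean_cohort):
        """Every truth event (sequence, index, label) is called on 60 clean BIMs."""
        config, (genome, native, bims, truth) = clean_cohort
        spec = RepeatSpec(P42S_REPEAT)
        by_id = {bt.bim_id: bt for bt in truth}
        n_events = 0
        for rec in bims:
            arr = parse_array(str(rec.seq), spec, array_id=rec.id)
            events = diff_arrays(native, arr)
            want = {
                (ev.spacer, ev.insertion_index, ev.classification)
                for ev in by_id[rec.id].events
            }
            got = {(e.spacer, e.insertion_index, e.classification) for e in events}
            assert got == want
            n_events += len(events)
        assert n_events == sum(len(bt.events) for bt in truth) > 0

    @settings(derandomize=True, max_examples=50)
    @given(
        native=st.lists(dna, min_size=2, max_size=6, unique=True),
        inserts=st.lists(dna, min_size=1, max_size=4, unique=True),
        data=st.data(),
    )
    def test_insertion_recovery_property(self, native, inserts, data):
        """diff_arrays recovers an arbitrary unique insertion set exactly."""
        inserts = [s for s in inserts if s not in native]
        bim = list(native)
        truth = []
        for s in inserts:
            idx = data.draw(st.integers(min_value=0, max_value=len(native)))
            # translate native insertion index to current list position
            pos = 0 if idx == 0 else bim.index(native[idx - 1]) + 1
            bim.insert(pos, s)
            truth.append((s, idx))
        events = diff_arrays(self.arr(native), self.arr(bim, "B"))
        assert {(e.spacer, e.insertion_index) for e in events} == set(truth)
        for e in events:
            assert (e.classification == "polar") == (e.insertion_index == 0)


class TestFindAntiRepeat:
    def test_planted_exact_reverse_complement(self):
        """A planted RC 25-mer of the repeat scores 25/25 at the right offset."""
        rng = np.random.default_rng(11)
        sub = P42S_REPEAT[5:30]
        region = random_dna(rng, 80) + revcomp(sub) + random_dna(rng, 80)
        m = find_anti_repeat(region, P42S_REPEAT, min_window=25, max_mismatches=0)
        assert m is not None
        assert m.matches == m.length >= 25  # the planted 25/25 stretch
        scanned = region if m.strand == "+" else revcomp(region)
        window = scanned[m.offset : m.offset + m.length]
        assert sub in window or revcomp(sub) in window

    def test_single_substitution_scores_24_of_25(self):
        rng = np.random.default_rng(12)
        sub = list(revcomp(P42S_REPEAT[5:30]))
        sub[10] = {"A": "C"}.get(sub[10], "A")
        region = random_dna(rng, 60) + "".join(sub) + random_dna(rng, 60)
        m = find_anti_repeat(region, P42S_REPEAT, min_window=25, max_mismatches=1)
        assert m is not None
        assert m.matches >= 24 and m.length - m.matches <= 1

    def test_absent_signal_returns_none(self):
        region = "AC" * 60  # max 50% identity to the repeat anywhere
        assert find_anti_repeat(region, P42S_REPEAT, min_window=25, max_mismatches=2) is None

    def test_matches_exhaustive_enumeration(self):
        """Best score equals an independently coded all-offsets enumeration."""
        rng = np.random.default_rng(13)

        def brute(region, repeat, min_w, max_mm):
            best = None
            for strand in ("+", "-"):
                seq = region if strand == "+" else revcomp(region)
                for w in range(min_w, min(len(repeat), len(seq)) + 1):
                    for ro in range(len(repeat) - w + 1):
                        for off in range(len(seq) - w + 1):
                            m = sum(
                                a == b
                                for a, b in zip(seq[off : off + w], repeat[ro : ro + w])
                            )
                            if w - m <= max_mm and (best is None or m > best):
                                best = m
            return best

        for _ in range(10):
            region = random_dna(rng, 200)
            got = find_anti_repeat(region, P42S_REPEAT, min_window=18, max_mismatches=3)
            want = brute(region, P42S_REPEAT, 18, 3)
            assert (got.matches if got else None) == want
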