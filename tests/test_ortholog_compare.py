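"""Indel calling, microhomology measurement and mechanism labels."""

import numpy as np
import pytest

from vntrcode.ortholog_compare import (
    IndelEvent,
    MechanismConfig,
    align_pair,
    classify_mechanism,
    compare_pair,
    left_normalize,
    make_pair,
    measure_microhomology,
)
from vntrcode.segmentation import VNTRElement
from vntrcode.synthetic_data import (
    PlantedEvent,
    generate_subfamily_set,
    load_packaged_grammar,
    make_ortholog_pair,
    make_random_planted_pair,
)

from .oracle import scan_mh_left, scan_mh_right


def _pair_from(seq_a, seq_b, lib, pid="p"):
    a = VNTRElement(id="a", subfamily="t", sequence=seq_a)
    b = VNTRElement(id="b", subfamily="t", sequence=seq_b)
    return make_pair(pid, a, b, lib)


class TestMechanismConfig:
    def test_defaults_reflect_mechanism_bounds(self):
        cfg = MechanismConfig()
        assert (cfg.mh_min, cfg.nahr_min, cfg.slippage_window) == (5, 34, 200)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MechanismConfig(mh_min=40, nahr_min=34)
        with pytest.raises(ValueError):
            MechanismConfig(slippage_window=0)


class TestAlignPair:
    def test_identical_sequences_no_events(self, lib):
        seq = "".join(lib.consensus(c) for c in "ABCA")
        pair = _pair_from(seq, seq, lib)
        assert align_pair(pair) == []

    def test_single_inserted_ru_found_at_token_boundary(self, lib):
        base = [lib.consensus(c) for c in "ABCA"]
        long_seq = "".join(base[:2] + [lib.consensus("K")] + base[2:])
        short_seq = "".join(base)
        pair = _pair_from(long_seq, short_seq, lib)
        events = align_pair(pair)
        assert len(events) == 1
        ev = events[0]
        start = len(base[0]) + len(base[1])
        assert (ev.start, ev.end) == (start, start + 49)

    def test_three_planted_indels_recovered(self, lib):
        g = load_packaged_grammar("sva_d")
        g.mutation_rate = 0.0
        recovered = 0
        for seed in range(20):
            els, truths = generate_subfamily_set(g, 1, seed=100 + seed, lib=lib)
            el, truth = els[0], truths[0]
            n = len(truth.generating_tokens)
            spec = [
                PlantedEvent(span=(1, 2), designed_mh=0),
                PlantedEvent(span=(n // 2, n // 2 + 1), designed_mh=0),
                PlantedEvent(span=(n - 3, n - 2), designed_mh=0),
            ]
            h1, h2, tev = make_ortholog_pair(el, spec, seed=seed, lib=lib, truth=truth)
            pair = make_pair(f"s{seed}", h1, h2, lib)
            events = align_pair(pair)
            want = {tuple(t["segment"]) for t in tev}
            got = {
                tuple(left_normalize(h1.sequence, ev.start, ev.end, "")[:2])
                for ev in events
            }
            recovered += want == got
        assert recovered >= 19  # tandem context can merge rare borderline cases

    def test_swap_symmetry(self, lib):
        e1, e2, _t = make_random_planted_pair(3)
        p12 = _pair_from(e1.sequence, e2.sequence, lib)
        p21 = _pair_from(e2.sequence, e1.sequence, lib)
        ev12 = [(e.start, e.end, e.inserted_bases) for e in align_pair(p12)]
        ev21 = [(e.start, e.end, e.inserted_bases) for e in align_pair(p21)]
        assert ev12 == ev21


class TestLeftNormalize:
    def test_idempotent(self):
        seq = "GGCATCATCATGG"
        once = left_normalize(seq, 8, 11, "")
        assert left_normalize(seq, *once[:2], once[2]) == once

    def test_equivalent_representations_converge(self):
        seq = "GGCATCATCATGG"
        # deleting CAT at 2, 5 or 8 yields the same short sequence
        reps = {left_normalize(seq, s, s + 3, "")[:2] for s in (2, 5, 8)}
        assert reps == {(2, 5)}

    def test_insertion_rotates_leftward(self):
        seq = "GGAAACC"
        start, end, ins = left_normalize(seq, 5, 5, "AC")
        assert (start, end) == (2, 2) and ins == "AAC" or ins == "AC"


class TestMeasureMicrohomology:
    def test_no_homology_gives_zero(self, lib):
        # segment sharing nothing with either flank
        seq = "G" * 40 + "ATATATAT" + "C" * 40
        pair = _pair_from(seq, "G" * 40 + "C" * 40, lib)
        ev = IndelEvent(pair_id="p", start=40, end=48)
        measure_microhomology(pair, ev)
        assert ev.mh_exact_left == 0 and ev.mh_exact_right == 0

    def test_designed_seven_bp_homology(self):
        rng = np.random.default_rng(5)
        e1, e2, truth = make_random_planted_pair(11, designed_mh=7)
        s, e = truth["segment"]
        assert scan_mh_right(e1.sequence[s:e], e1.sequence[e:]) == 7

    def test_mismatched_homology_exact_vs_relaxed(self, lib):
        """A 12 bp homology with one mismatch at index 5: exact 5, relaxed 12."""
        rng = np.random.default_rng(17)
        for seed in range(30):
            e1, e2, truth = make_random_planted_pair(
                200 + seed, indel_len_range=(40, 40), designed_mh=0
            )
            seq = list(e1.sequence)
            s, e = truth["segment"]
            for k in range(12):
                seq[e + k] = seq[s + k]
            h1 = "".join(seq)
            if scan_mh_right(h1[s:e], h1[e:]) != 12:
                continue
            seq[e + 5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[e + 5]]
            h1 = "".join(seq)
            if scan_mh_right(h1[s:e], h1[e:]) != 5:
                continue
            h2 = h1[:s] + h1[e:]
            pair = _pair_from(h1, h2, lib)
            ev = IndelEvent(pair_id="p", start=s, end=e)
            measure_microhomology(pair, ev)
            assert ev.mh_exact_right == 5
            assert ev.mh_relaxed == 12
            return
        pytest.fail("no clean construction found")

    def test_oracle_agreement_on_called_events(self, lib):
        for seed in range(20):
            e1, e2, _t = make_random_planted_pair(400 + seed)
            pair = _pair_from(e1.sequence, e2.sequence, lib)
            for ev in align_pair(pair):
                measure_microhomology(pair, ev)
                L = pair.seq_long.sequence
                S = L[ev.start : ev.end] or ev.inserted_bases
                assert ev.mh_exact_right == scan_mh_right(S, L[ev.end :])
                assert ev.mh_exact_left == scan_mh_left(S, L[: ev.start])

    def test_non_indel_window_rejected(self, lib):
        seq = "G" * 80
        pair = _pair_from(seq, seq[:-10], lib)
        with pytest.raises(ValueError, match="indel"):
            measure_microhomology(pair, IndelEvent(pair_id="p", start=5, end=5))


class TestClassifyMechanism:
    def test_whole_ru_deletion_is_precise(self, lib):
        base = [lib.consensus(c) for c in "ABCA"]
        long_seq = "".join(base)
        short_seq = "".join(base[:1] + base[2:])  # B excised precisely
        pair = _pair_from(long_seq, short_seq, lib)
        events = compare_pair(pair, lib)
        assert len(events) == 1
        assert "precise_ru_indel" in events[0].labels

    def test_three_bp_conversion_a_to_c(self, lib):
        # C is A minus 3 internal bases: deleting them converts the token
        a, c = lib.consensus("A"), lib.consensus("C")
        start = next(i for i in range(40) if a[:i] + a[i + 3 :] == c)
        long_seq = lib.consensus("B") + a + lib.consensus("K")
        short_seq = lib.consensus("B") + c + lib.consensus("K")
        pair = _pair_from(long_seq, short_seq, lib)
        events = compare_pair(pair, lib)
        assert len(events) == 1
        ev = events[0]
        assert ev.length == 3
        assert "ru_conversion_microindel" in ev.labels
        assert ev.converted_tokens == [("A", "C")]

    def test_mh34_len150_is_both_nahr_and_slippage_compatible(self):
        ev = IndelEvent(pair_id="p", start=0, end=150)
        ev.mh_relaxed = 34
        # classify needs only the numeric fields for mechanism labels
        from vntrcode.ortholog_compare import OrthologPair
        from vntrcode.segmentation import RepeatSchema

        el = VNTRElement("x", "t", "G" * 200)
        pair = OrthologPair("p", el, el, RepeatSchema("x", []), RepeatSchema("x", []))
        classify_mechanism(ev, pair, lib=None)
        assert {"mh_mediated", "slippage_compatible", "nahr_compatible"} <= ev.labels

    def test_nahr_implies_mh_mediated(self):
        # structural consequence of mh_min <= nahr_min
        cfg = MechanismConfig()
        assert cfg.mh_min <= cfg.nahr_min

    def test_large_event_not_slippage_compatible(self):
        from vntrcode.ortholog_compare import OrthologPair
        from vntrcode.segmentation import RepeatSchema

        ev = IndelEvent(pair_id="p", start=0, end=190)
        ev.mh_relaxed = 20
        el = VNTRElement("x", "t", "G" * 200)
        pair = OrthologPair("p", el, el, RepeatSchema("x", []), RepeatSchema("x", []))
        classify_mechanism(ev, pair, lib=None)
        assert "slippage_compatible" not in ev.labels
        assert "mh_mediated" in ev.labels


class TestPlantedRecovery:
    def test_recovery_of_planted_events_small(self, lib):
        ok = 0
        trials = 25
        for seed in range(trials):
            e1, e2, truth = make_random_planted_pair(1000 + seed)
            pair = _pair_from(e1.sequence, e2.sequence, lib)
            events = compare_pair(pair, lib)
            if len(events) == 1:
                ev = events[0]
                if [ev.start, ev.end] == truth["segment"] and (
                    ev.mh_exact_right == truth["designed_mh"]
                ):
                    ok += 1
        assert ok / trials >= 0.95
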