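"""Tokenizer, unit classification and de-novo unit discovery."""

import numpy as np
import pytest

from vntrcode.segmentation import (
    AssemblyGapError,
    SegmentationError,
    VNTRElement,
    classify_token,
    decode_code_string,
    discover_units,
    segment_vntr,
)
from vntrcode.synthetic_data import (
    generate_subfamily_set,
    load_packaged_grammar,
    random_element,
)

from .conftest import mutate
from .oracle import bruteforce_segmentation_cost, schema_cost


def _el(seq, eid="e", subfamily="test"):
    return VNTRElement(id=eid, subfamily=subfamily, sequence=seq)


class TestSegmentVntr:
    def test_empty_sequence_gives_empty_schema(self, lib):
        schema = segment_vntr(_el(""), lib)
        assert schema.tokens == [] and schema.code_string == ""

    def test_clean_concatenation_recovers_abca(self, lib):
        seq = "".join(lib.consensus(c) for c in "ABCA")
        schema = segment_vntr(_el(seq), lib)
        assert schema.code_string == "A-B-C-A"
        assert [t.edit_distance for t in schema.tokens] == [0, 0, 0, 0]
        assert all(t.identity == 1.0 for t in schema.tokens)

    @pytest.mark.parametrize("k", [1, 5, 12])
    def test_unmutated_concatenations_recover_exactly(self, lib, k):
        rng = np.random.default_rng(k)
        codes = [sorted(lib.units)[i] for i in rng.integers(0, 20, size=k)]
        seq = "".join(lib.consensus(c) for c in codes)
        schema = segment_vntr(_el(seq), lib)
        assert [t.type_code for t in schema.tokens] == codes
        assert all(t.variant_tag == "" for t in schema.tokens)

    def test_tokens_tile_the_sequence(self, lib):
        rng = np.random.default_rng(3)
        seq = "".join(
            mutate(lib.consensus(c), 2, rng) for c in ["A", "B", "K", "C", "N"]
        )
        schema = segment_vntr(_el(seq), lib)
        assert schema.tokens[0].start == 0
        assert schema.tokens[-1].end == len(seq)
        for t1, t2 in zip(schema.tokens, schema.tokens[1:]):
            assert t1.end == t2.start
        rebuilt = "".join(seq[t.start : t.end] for t in schema.tokens)
        assert rebuilt == seq

    def test_dp_cost_equals_bruteforce_oracle(self, lib, params):
        rng = np.random.default_rng(7)
        codes = sorted(lib.units)
        for _trial in range(10):
            k = int(rng.integers(2, 6))
            units = [
                mutate(lib.consensus(codes[i]), int(rng.integers(0, 3)), rng)
                for i in rng.integers(0, 20, size=k)
            ]
            seq = "".join(units)[:200]
            if len(seq) < 120:
                continue
            schema = segment_vntr(_el(seq), lib, params)
            assert schema_cost(schema, params.tau) == bruteforce_segmentation_cost(
                seq, lib, params
            )

    def test_truncated_terminal_token_flagged(self, lib):
        seq = lib.consensus("A") + lib.consensus("B")[:15]
        schema = segment_vntr(_el(seq), lib)
        assert schema.tokens[-1].truncated
        assert schema.tokens[-1].end - schema.tokens[-1].start == 15
        assert not schema.tokens[0].truncated

    def test_gap_rich_sequence_refused(self, lib):
        seq = lib.consensus("A") + "N" * 10
        with pytest.raises(AssemblyGapError, match="assembly"):
            segment_vntr(_el(seq), lib)

    def test_empty_library_refused(self, lib):
        from vntrcode.ru_library import RULibrary

        with pytest.raises(SegmentationError, match="empty"):
            segment_vntr(_el("ACGT" * 20), RULibrary())

    def test_determinism(self, lib):
        el = random_element(5, 300)
        s1 = segment_vntr(el, lib)
        s2 = segment_vntr(el, lib)
        assert s1.code_string == s2.code_string
        assert [t.start for t in s1.tokens] == [t.start for t in s2.tokens]

    def test_mutation_robustness_small(self, lib):
        """Generating code strings recovered under <=2 substitutions/unit."""
        rng = np.random.default_rng(11)
        codes = sorted(lib.units)
        ok = 0
        trials = 50
        for _ in range(trials):
            picks = [codes[i] for i in rng.integers(0, 20, size=4)]
            seq = "".join(
                mutate(lib.consensus(c), int(rng.integers(0, 3)), rng) for c in picks
            )
            schema = segment_vntr(_el(seq), lib)
            ok += [t.type_code for t in schema.tokens] == picks
        assert ok / trials >= 0.95


class TestClassifyToken:
    def test_exact_base_consensus(self, lib):
        assert classify_token(lib.consensus("B"), lib) == ("B", "", 0)

    def test_exact_variant_consensus(self, lib):
        assert classify_token(lib.consensus("B", "'"), lib) == ("B", "'", 0)

    def test_random_unit_goes_to_sink(self, lib):
        # rejection-sampled: a random GC-rich 40-mer far from every entry
        rng = np.random.default_rng(13)
        for _ in range(50):
            unit = random_element(int(rng.integers(1 << 30)), 40).sequence
            dmin = min(
                __import__("edlib").align(unit, cons, task="distance")["editDistance"]
                for _c, _t, cons in lib.entries()
            )
            if 1 - dmin / 40 < 0.70:
                code, tag, _d = classify_token(unit, lib)
                assert (code, tag) == ("X", "")
                return
        pytest.fail("no sufficiently distant random unit found")

    def test_mutated_unit_recovers_type(self, lib, rng):
        unit = mutate(lib.consensus("K"), 2, rng)
        code, _tag, d = classify_token(unit, lib)
        assert code == "K" and d <= 2

    def test_empty_unit_rejected(self, lib):
        with pytest.raises(SegmentationError):
            classify_token("", lib)


class TestDiscoverUnits:
    def test_identical_units_one_cluster(self):
        units = ["ACGTACGTAC" * 4] * 10
        clusters = discover_units(units)
        assert len(clusters) == 1
        assert clusters[0].consensus == units[0]
        assert clusters[0].support == 10

    def test_per_column_majority_vote(self, lib, rng):
        x = lib.consensus("A")
        y = mutate(x, 3, rng)  # same length, 3 fixed columns changed
        clusters = discover_units([x] * 6 + [y] * 4)
        assert len(clusters) == 1
        assert clusters[0].consensus == x

    def test_sva2_like_set_recovers_dominant_lengths(self, lib, rng):
        units = [mutate(lib.consensus("A"), int(rng.integers(0, 3)), rng) for _ in range(20)]
        units += [mutate(lib.consensus("B"), int(rng.integers(0, 3)), rng) for _ in range(20)]
        clusters = discover_units(units)
        top2 = sorted(c.length for c in clusters[:2])
        assert top2 == [39, 40]

    def test_majority_tie_reported_alphabetically(self):
        clusters = discover_units(["A" * 10, "C" + "A" * 9])
        assert len(clusters) == 1
        assert clusters[0].consensus == "A" * 10
        assert clusters[0].tie_columns == [0]

    def test_different_lengths_never_cluster(self):
        clusters = discover_units(["A" * 40] * 3 + ["A" * 39] * 2)
        assert sorted((c.length, c.support) for c in clusters) == [(39, 2), (40, 3)]

    def test_empty_input_rejected(self):
        with pytest.raises(SegmentationError):
            discover_units([])


class TestCodeStrings:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("A-B'-C.T-X", [("A", ""), ("B", "'"), ("C", "T"), ("X", "")]),
            ("", []),
            ("C''", [("C", "''")]),
        ],
    )
    def test_decode(self, text, expected):
        assert decode_code_string(text) == expected

    def test_schema_code_string_round_trip(self, lib):
        g = load_packaged_grammar("sva_f")
        g.mutation_rate = 0.0
        els, truths = generate_subfamily_set(g, 1, seed=3, lib=lib)
        schema = segment_vntr(els[0], lib)
        assert decode_code_string(schema.code_string) == schema.keys
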