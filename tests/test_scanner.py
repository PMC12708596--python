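import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from hsescan import (
    HSEMatch,
    Orientation,
    PRESETS,
    PromoterRecord,
    ScanParams,
    annotate_tss,
    distance_to_tss,
    filter_nonoverlapping,
    match_unit,
    oracle_scan,
    scan_record,
    summarize,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)
dna_with_n = st.text(alphabet="ACGTN", min_size=0, max_size=60)
small_params = st.builds(
    ScanParams,
    n_units=st.sampled_from([2, 3]),
    max_subs_total=st.integers(0, 2),
    max_ins_per_gap=st.integers(0, 2),
    max_ins_total=st.just(2),
)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq):
    return seq.translate(COMPLEMENT)[::-1]


class TestMatchUnit:
    @pytest.mark.parametrize(
        "seq, orientation, subs, positions",
        [
            ("AGAAT", Orientation.GAA_type, 0, frozenset()),
            ("ACAAT", Orientation.GAA_type, 1, frozenset({1})),
            ("TTTCA", Orientation.TTC_type, 0, frozenset()),
            ("AGCCT", Orientation.GAA_type, 2, frozenset({2, 3})),
            ("ANAAT", Orientation.GAA_type, 1, frozenset({1})),  # N in a core counts
            ("NGAAN", Orientation.GAA_type, 0, frozenset()),  # N at wildcards is free
        ],
    )
    def test_core_hamming_accounting(self, seq, orientation, subs, positions):
        unit = match_unit(seq, 0, orientation)
        assert unit.core_substitutions == subs
        assert unit.substituted_core_positions == positions

    def test_out_of_range_position(self):
        with pytest.raises(ValueError):
            match_unit("ACGT", 0, Orientation.GAA_type)


class TestScanRecord:
    def test_constructed_canonical_element(self, canonical_record):
        ms = scan_record(canonical_record, PRESETS["canonical"])
        assert len(ms) == 1
        (m,) = ms.matches
        assert (m.start, m.end) == (0, 15)
        assert [u.orientation for u in m.units] == [
            Orientation.GAA_type,
            Orientation.TTC_type,
            Orientation.GAA_type,
        ]
        assert m.substitutions_total == 0 and m.insertions_total == 0
        assert m.class_label == "canonical"

    def test_constructed_minimal_element(self, minimal_record):
        ms = scan_record(minimal_record, PRESETS["minimal_perfect"])
        assert len(ms) == 1
        (m,) = ms.matches
        assert (m.start, m.end) == (0, 10)
        assert m.first_orientation is Orientation.GAA_type

    def test_motif_free_background(self, motif_free_record):
        ms = scan_record(motif_free_record, PRESETS["imperfect_triple"])
        assert len(ms) == 0

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(seq=dna_with_n, params=small_params)
    def test_equals_brute_force_oracle(self, seq, params):
        """The central equivalence: scanner output == exhaustive template scan."""
        rec = PromoterRecord("r", seq, len(seq))
        assert scan_record(rec, params).matches == oracle_scan(rec, params).matches

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seq=dna, params=small_params)
    def test_reverse_complement_symmetry(self, seq, params):
        """Mirrored spans, swapped first orientation, same match count."""
        rec = PromoterRecord("r", seq, len(seq))
        rc = PromoterRecord("r", revcomp(seq), len(seq))
        fwd = scan_record(rec, params).matches
        rev = scan_record(rc, params).matches
        assert len(fwd) == len(rev)
        L = len(seq)
        fwd_spans = sorted((L - m.end, L - m.start, m.first_orientation) for m in fwd)
        # orientation of the *last* unit maps to the first unit of the mirror
        rev_spans = sorted(
            (m.start, m.end, m.units[-1].orientation.flipped) for m in rev
        )
        assert fwd_spans == rev_spans

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seq=dna, s1=st.integers(0, 2), s2=st.integers(0, 2),
           i1=st.integers(0, 2), i2=st.integers(0, 2), n=st.sampled_from([2, 3]))
    def test_monotonicity_in_budgets(self, seq, s1, s2, i1, i2, n):
        """Widening the tolerance envelope never loses a matched span."""
        lo = ScanParams(n, min(s1, s2), min(i1, i2), min(i1, i2))
        hi = ScanParams(n, max(s1, s2), max(i1, i2), max(i1, i2))
        rec = PromoterRecord("r", seq, len(seq))
        spans_lo = {(m.start, m.end) for m in scan_record(rec, lo).matches}
        spans_hi = {(m.start, m.end) for m in scan_record(rec, hi).matches}
        assert spans_lo <= spans_hi

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seq=dna_with_n, params=small_params)
    def test_length_identity_and_recount(self, seq, params):
        """end−start = 5·n_units + insertions; stored accounting re-derives."""
        rec = PromoterRecord("r", seq, len(seq))
        for m in scan_record(rec, params).matches:
            assert m.end - m.start == 5 * m.n_units + m.insertions_total
            recount = 0
            for unit in m.units:
                observed = match_unit(seq, unit.start, unit.orientation)
                assert observed == unit
                recount += observed.core_substitutions
            assert recount == m.substitutions_total


class TestDistanceToTss:
    def test_upstream_match(self):
        rec = PromoterRecord("r", "A" * 40 + "AGAACATTCGAGAAT" + "A" * 45, 100)
        m = scan_record(rec, PRESETS["canonical"]).matches[0]
        assert (m.start, m.end) == (40, 55)
        assert distance_to_tss(m, rec) == 45
        assert m.within_100bp is True

    def test_match_exactly_at_window_edge(self):
        rec = PromoterRecord("r", "AGAACATTCGAGAAT" + "C" * 85, 100)
        m = scan_record(rec, PRESETS["canonical"]).matches[0]
        assert distance_to_tss(m, rec) == 85
        assert m.within_100bp is True  # start 0 == tss-100: fully inside

    def test_match_crossing_the_tss(self):
        seq = "C" * 45 + "AGAACATTCGAGAAT" + "C" * 40
        rec = PromoterRecord("r", seq, 50)
        m = scan_record(rec, PRESETS["canonical"]).matches[0]
        assert (m.start, m.end) == (45, 60)
        assert distance_to_tss(m, rec) == -10
        assert m.within_100bp is False

    def test_record_mismatch_is_hard_error(self, canonical_record):
        m = scan_record(canonical_record, PRESETS["canonical"]).matches[0]
        other = PromoterRecord("other", "ACGT", 4)
        with pytest.raises(ValueError):
            distance_to_tss(m, other)


class TestSummarize:
    @staticmethod
    def _scan_all(record):
        return {
            name: annotate_tss(scan_record(record, params), record)
            for name, params in PRESETS.items()
        }

    def test_empty_matchsets_give_zero_counts(self, motif_free_record):
        s = summarize(self._scan_all(motif_free_record), motif_free_record)
        assert s.union_total == 0 and s.count_within_100bp == 0

    def test_canonical_match_abutting_tss(self, canonical_record):
        s = summarize(self._scan_all(canonical_record), canonical_record)
        assert s.count_canonical == 1
        assert s.count_within_100bp >= 1
        assert s.union_total == (
            s.count_canonical
            + s.count_minimal_perfect
            + s.count_imperfect_triple
            + s.count_imperfect_minimal
        )

    def test_perfect_hits_not_double_counted_as_imperfect(self, minimal_record):
        """A perfect minimal element found under the widened envelope keeps
        its perfect label: it never inflates the imperfect count."""
        matchsets = self._scan_all(minimal_record)
        perfect_span_matches = [
            m
            for m in matchsets["imperfect_minimal"].matches
            if m.substitutions_total == 0 and m.insertions_total == 0
        ]
        assert perfect_span_matches, "widened scan must also see the perfect hit"
        s = summarize(matchsets, minimal_record)
        assert s.count_minimal_perfect == 1

    def test_union_total_mirrors_reported_arithmetic(self):
        """The union total is the plain sum of class counts, as in published
        per-promoter tallies (23+41+2=66, 17+69+1=87, 10+26+2=38, 10+20+1=31)."""
        for triple, minimal, perfect, total in [
            (23, 41, 2, 66),
            (17, 69, 1, 87),
            (10, 26, 2, 38),
            (10, 20, 1, 31),
        ]:
            assert triple + minimal + perfect + 0 == total

    def test_record_mismatch_is_hard_error(self, canonical_record, minimal_record):
        matchsets = self._scan_all(minimal_record)
        with pytest.raises(ValueError):
            summarize(matchsets, canonical_record)


def test_filter_nonoverlapping_keeps_left_to_right_subset(canonical_record):
    seq = "AGAACATTCGAGAATTTCG" + "C" * 10  # canonical + overlapping tail unit
    rec = PromoterRecord("r", seq, len(seq))
    matches = list(scan_record(rec, PRESETS["minimal_perfect"]).matches) + list(
        scan_record(rec, PRESETS["canonical"]).matches
    )
    kept = filter_nonoverlapping(matches)
    ends = 0
    for m in sorted(kept, key=lambda m: m.start):
        assert m.start >= ends
        ends = m.end
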