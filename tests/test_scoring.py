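"""Star-rating scoring: sample IDs, BR/TR counting, score formulas,
aberrant-chain removal, complexity, percentiles, pair selection."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from vdjwell.scoring import (
    SampleId,
    ScoredEntry,
    ScoringParams,
    asv_score,
    complexity,
    count_replicates,
    match_score,
    parse_sample_id,
    percentile,
    remove_aberrant_light_chains,
    select_high_confidence_pairs,
    total_score,
)


class TestParseSampleId:
    @pytest.mark.parametrize(
        "raw,project,parent,subclone",
        [
            ("L130/1.1", "L130", "1", "1"),
            ("N158/28", "N158", "28", None),
            ("X/Y.Z.W", "X", "Y.Z", "W"),  # last-dot rule
        ],
    )
    def test_schema(self, raw, project, parent, subclone):
        sid = parse_sample_id(raw)
        assert (sid.project, sid.parent, sid.subclone) == (project, parent, subclone)
        assert sid.raw == raw

    def test_missing_slash_names_the_sample(self):
        with pytest.raises(ValueError, match="NOSLASH"):
            parse_sample_id("NOSLASH")


def sid(raw):
    return parse_sample_id(raw)


class TestCountReplicates:
    def test_bin_in_all_three_subclones(self):
        group = [sid("A/1.1"), sid("A/1.2"), sid("A/1.3")]
        assert count_replicates(group, [True, True, True]) == (3, 0, 3)

    def test_mixed_br_tr_group(self):
        # six samples over subclones {1 (x2), 2, 3, 4, 5}; bin in both
        # 1-samples plus subclones 2 and 3
        group = [sid("A/1.1"), sid("A/1.1"), sid("A/1.2"), sid("A/1.3"), sid("A/1.4"), sid("A/1.5")]
        present = [True, True, True, True, False, False]
        assert count_replicates(group, present) == (3, 1, 6)

    def test_bin_in_single_sample(self):
        group = [sid("A/1.1"), sid("A/1.2")]
        assert count_replicates(group, [True, False]) == (1, 0, 2)

    def test_subclone_absent_samples_are_technical_replicates(self):
        group = [sid("A/1"), sid("A/1")]
        assert count_replicates(group, [True, True]) == (1, 1, 2)


class TestScoreFormulas:
    @pytest.mark.parametrize("n,d,expected", [(300, 1000, 0.3), (1000, 1000, 1.0), (0, 1000, 0.0)])
    def test_asv_score(self, n, d, expected):
        assert asv_score(n, d) == pytest.approx(expected)

    def test_asv_score_domain_errors(self):
        with pytest.raises(ValueError):
            asv_score(1, 0)
        with pytest.raises(ValueError):
            asv_score(11, 10)

    @pytest.mark.parametrize(
        "br,tr,total,nu,expected",
        [(5, 0, 5, 1.0, 5.0), (2, 2, 8, 0.5, 2.5), (1, 0, 1, 1.0, 1.0)],
    )
    def test_match_score(self, br, tr, total, nu, expected):
        assert match_score(br, tr, total, nu) == pytest.approx(expected)

    def test_total_score_ceiling_case(self):
        assert total_score(math.exp(3), 1.0) == pytest.approx(5.0)

    def test_total_score_clamp_mode_arithmetic(self):
        assert total_score(5.0, 1.0) == pytest.approx(math.log(5) + 2)

    def test_total_score_floor_at_zero(self):
        assert total_score(1.0, 0.0) == 0.0
        assert total_score(-2.0, 0.0) == 0.0

    def test_literal_max_mode_reproduces_printed_formula(self):
        params = ScoringParams(literal_max_mode=True)
        assert total_score(1.0, 0.0, params) == pytest.approx(3.0)  # max(3, ln 1)
        assert total_score(math.exp(4), 1.0, params) == pytest.approx(6.0)

    def test_ceilings_must_sum_to_five(self):
        with pytest.raises(ValueError):
            ScoringParams(mu=2, lam=4)


class TestScoreProperties:
    def test_match_score_strictly_increases_in_br(self):
        prev = None
        for br in range(1, 8):
            s = match_score(br, 1, 10, nu=0.5)
            if prev is not None:
                assert s > prev
            prev = s

    def test_nu_one_makes_tr_equal_br_in_support_term(self):
        assert match_score(2, 1, 6, nu=1.0) == pytest.approx(match_score(3, 0, 6, nu=1.0))

    def test_nu_zero_tr_still_reduces_penalty(self):
        with_tr = match_score(2, 2, 8, nu=0.0)
        without = match_score(2, 0, 8, nu=0.0)
        assert with_tr > without  # penalty term uses unweighted BR+TR

    def test_total_score_bounds_on_grid(self):
        params = ScoringParams()
        lo, hi = math.inf, -math.inf
        for total in range(1, 13):
            for br in range(0, total + 1):
                for tr in range(0, total - br + 1):
                    m = match_score(br, tr, total, nu=1.0)
                    for asv in (0.0, 0.25, 0.5, 0.75, 1.0):
                        s = total_score(m, asv, params)
                        lo, hi = min(lo, s), max(hi, s)
        assert lo >= 0.0
        assert hi <= 5.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        match=st.floats(min_value=-5, max_value=1e6, allow_nan=False),
        asv=st.floats(min_value=0, max_value=1),
        nu=st.floats(min_value=0, max_value=1),
    )
    def test_total_score_always_in_unit_star_range(self, match, asv, nu):
        s = total_score(match, asv, ScoringParams(nu=nu))
        assert 0.0 <= s <= 5.0

    def test_total_score_monotone_in_match_and_asv(self):
        for m1, m2 in [(0.5, 1.5), (1.5, 5.0), (5.0, 50.0)]:
            assert total_score(m2, 0.5) >= total_score(m1, 0.5)
        assert total_score(2.0, 0.9) >= total_score(2.0, 0.1)


def entry(sample, chain, aa, score=0.0, asv=0.0, nt="", verified=False):
    e = ScoredEntry(
        sample=parse_sample_id(sample),
        chain_class=chain,
        aa_key=(chain, aa),
        nt_reported=nt or aa,
        count=10,
    )
    e.total_score = score
    e.asv_score = asv
    e.verified = verified
    return e


class TestAberrantRemoval:
    def _run(self, n_with, n_total, chain="VL"):
        entries = []
        for i in range(n_total):
            s = f"A/{i + 1}.1"
            entries.append(entry(s, "VH", f"H{i}"))
            if i < n_with:
                entries.append(entry(s, chain, "SHARED"))
        return remove_aberrant_light_chains(entries)

    def test_light_chain_in_six_of_ten_flagged(self):
        out = self._run(6, 10)
        assert all(e.aberrant_flag for e in out if e.aa_key == ("VL", "SHARED"))

    def test_light_chain_in_exactly_half_retained(self):
        out = self._run(5, 10)
        assert not any(e.aberrant_flag for e in out)

    def test_heavy_chain_never_flagged(self):
        entries = [entry(f"A/{i}.1", "VH", "SAME_H") for i in range(1, 11)]
        out = remove_aberrant_light_chains(entries)
        assert not any(e.aberrant_flag for e in out)


class TestComplexityAndPercentile:
    def test_complexity_counts_products(self):
        es = [entry("A/1.1", "VL", f"L{i}") for i in range(2)]
        es += [entry("A/1.1", "VH", f"H{i}") for i in range(3)]
        assert complexity(es) == 6

    def test_complexity_degenerate_cases(self):
        assert complexity([entry("A/1.1", "VL", "L"), entry("A/1.1", "VH", "H")]) == 1
        assert complexity([entry("A/1.1", "VL", "L")]) == 0

    def test_aberrant_entries_excluded_from_complexity(self):
        es = [entry("A/1.1", "VL", "L1"), entry("A/1.1", "VL", "L2"), entry("A/1.1", "VH", "H")]
        es[1].aberrant_flag = True
        assert complexity(es) == 1

    def test_percentile_conventions(self):
        pop = [1.0, 2.0, 3.0, 4.0]
        assert percentile(4.0, pop) == pytest.approx(3 / 4)
        assert percentile(1.0, pop) == 0.0
        assert percentile(2.5, [2.5]) == 0.0


class TestHighConfidencePairs:
    def test_qualifying_pair_selected(self):
        es = [entry("A/1.1", "VL", "L", 4.5), entry("A/1.1", "VH", "H", 4.2)]
        pairs = select_high_confidence_pairs(es)
        assert len(pairs) == 1
        assert all(e.high_confidence for e in es)

    def test_threshold_is_strict(self):
        es = [entry("A/1.1", "VL", "L", 4.0), entry("A/1.1", "VH", "H", 4.2)]
        assert select_high_confidence_pairs(es) == []

    def test_maximum_scoring_chain_wins(self):
        es = [
            entry("A/1.1", "VL", "L1", 4.2),
            entry("A/1.1", "VL", "L2", 4.8),
            entry("A/1.1", "VH", "H", 4.5),
        ]
        pairs = select_high_confidence_pairs(es)
        assert pairs[0][0].aa_key == ("VL", "L2")

    def test_shared_light_chain_drops_both_pairs(self):
        es = [
            entry("A/1.1", "VL", "L", 4.5),
            entry("A/1.1", "VH", "H1", 4.5),
            entry("B/2.1", "VL", "L", 4.5),
            entry("B/2.1", "VH", "H2", 4.5),
        ]
        assert select_high_confidence_pairs(es) == []

    def test_identical_replicate_pairs_collapse_not_drop(self):
        es = [
            entry("A/1.1", "VL", "L", 4.5),
            entry("A/1.1", "VH", "H", 4.5),
            entry("A/1.2", "VL", "L", 4.4),
            entry("A/1.2", "VH", "H", 4.4),
        ]
        pairs = select_high_confidence_pairs(es)
        assert len(pairs) == 1
        assert pairs[0][0].sample.raw == "A/1.1"  # best-scoring instance kept

    def test_verified_entries_included_regardless_of_score(self):
        es = [entry("A/1.1", "VL", "L", 1.0, verified=True), entry("A/1.1", "VH", "H", 4.5)]
        assert len(select_high_confidence_pairs(es)) == 1

    def test_aberrant_entries_never_pair(self):
        es = [entry("A/1.1", "VL", "L", 4.5), entry("A/1.1", "VH", "H", 4.5)]
        es[0].aberrant_flag = True
        assert select_high_confidence_pairs(es) == []
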