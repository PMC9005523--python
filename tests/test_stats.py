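"""Prevalence, expected counts, co/contravariation, birth order, anticipation."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemeped.errors import AnalysisError
from hemeped.pedigree import Pedigree, Sex
from hemeped.stats import (ExpectedCounts, PrevalenceTable, assess_anticipation,
                           compute_prevalence, expected_ar_counts,
                           haldane_smith_test, make_restrict,
                           wilcoxon_boe_control)
from hemeped.stats import test_cocontravariation as cocontra_row

from .conftest import CLL, MM, ind, make_sibship


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------
class TestPrevalence:
    def test_single_diagnosis_is_100_percent(self):
        prev = compute_prevalence({"CLL": (7, 4, 3)}, "LPD")
        assert prev.pct("CLL") == 100.0

    def test_from_pedigree_counts_sexes(self):
        ped = Pedigree([
            ind("a", dx=CLL, onset=60),
            ind("b", sex=Sex.FEMALE, dx=CLL, onset=65),
            ind("c", dx=MM, onset=70)])
        prev = compute_prevalence(ped, "LPD")
        assert prev.counts("CLL") == (2, 1, 1)
        assert prev.pct("CLL") == 66.7 and prev.pct("MM") == 33.3

    def test_empty_group_errors(self, trio):
        with pytest.raises(AnalysisError):
            compute_prevalence(trio, "MPD")

    def test_percent_sums_to_about_100(self):
        prev = compute_prevalence({"A": (1, 1, 0), "B": (1, 0, 1), "C": (1, 1, 0)},
                                  "LPD")
        assert 99.0 <= sum(prev.df.prevalence_pct) <= 101.0


# ---------------------------------------------------------------------------
# expected counts
# ---------------------------------------------------------------------------
class TestExpectedCounts:
    def test_zero_pool_gives_zero(self):
        prev = PrevalenceTable.from_counts({"HL": (19, 12, 7), "X": (200, 100, 100)},
                                           "LPD")
        assert expected_ar_counts(prev, 0, "HL") == ExpectedCounts(0.0, 0.0, 0.0)

    def test_sex_split_sums_to_total_exactly(self):
        prev = PrevalenceTable.from_counts({"HL": (19, 12, 7), "X": (200, 100, 100)},
                                           "LPD")
        exp = expected_ar_counts(prev, 121, "HL")
        assert math.isclose(exp.male + exp.female, exp.total, abs_tol=1e-9)

    @given(pool=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_pool(self, pool):
        prev = PrevalenceTable.from_counts({"HL": (19, 12, 7), "X": (200, 100, 100)},
                                           "LPD")
        unit = expected_ar_counts(prev, 1, "HL").total
        assert math.isclose(expected_ar_counts(prev, pool, "HL").total,
                            unit * pool, rel_tol=1e-12, abs_tol=1e-12)

    def test_exact_prevalence_switch(self):
        prev = PrevalenceTable.from_counts({"HL": (19, 12, 7), "X": (200, 100, 100)},
                                           "LPD")
        rounded = expected_ar_counts(prev, 121, "HL").total
        exact = expected_ar_counts(prev, 121, "HL", exact_prevalence=True).total
        assert math.isclose(exact, 121 * 19 / 219, rel_tol=1e-12)
        assert rounded != exact  # 1-decimal percent vs unrounded fraction


# ---------------------------------------------------------------------------
# co/contravariation
# ---------------------------------------------------------------------------
class TestCocontravariation:
    def test_obs_equal_exp_is_none(self):
        row = cocontra_row((50, 30, 20), (50.0, 30.0, 20.0))
        assert row.chi_square == 0.0 and row.call == "none" and row.direction == "none"

    def test_zero_expected_cell_errors(self):
        with pytest.raises(AnalysisError, match="pool"):
            cocontra_row((5, 5, 0), (5.0, 5.0, 0.0))

    def test_sex_label_exchange_invariance(self):
        a = cocontra_row((40, 25, 15), (30.0, 18.0, 12.0))
        b = cocontra_row((40, 15, 25), (30.0, 12.0, 18.0))
        assert math.isclose(a.chi_square, b.chi_square)
        assert a.call == b.call

    def test_direction_follows_sign(self):
        up = cocontra_row((80, 50, 30), (50.0, 30.0, 20.0))
        down = cocontra_row((20, 10, 10), (50.0, 30.0, 20.0))
        assert up.direction == "covariation" and down.direction == "contravariation"


# ---------------------------------------------------------------------------
# Haldane & Smith
# ---------------------------------------------------------------------------
def enumeration_moments(s: int, m: int):
    """Exhaustive null moments of the rank sum: all C(s, m) placements."""
    sums = [sum(c) for c in itertools.combinations(range(1, s + 1), m)]
    mean = float(np.mean(sums))
    var = float(np.mean([(x - mean) ** 2 for x in sums]))
    return mean, var


class TestHaldaneSmith:
    def test_single_sibship_centre(self):
        res = haldane_smith_test([make_sibship(3, [2])])
        assert res.rank_sum_observed == 2
        assert res.rank_sum_null_mean == 2
        assert math.isclose(res.rank_sum_null_variance, 2 / 3)
        assert res.decision == "none"

    def test_size_two_enumeration(self):
        # s=2, m=1: A in {1, 2} equiprobable -> mean 1.5, variance 0.25
        res = haldane_smith_test([make_sibship(2, [2])])
        assert res.rank_sum_null_mean == 1.5
        assert math.isclose(res.rank_sum_null_variance, 0.25)

    @pytest.mark.parametrize("s", range(2, 7))
    def test_moments_match_exhaustive_enumeration(self, s):
        for m in range(1, s):
            mean, var = enumeration_moments(s, m)
            res = haldane_smith_test([make_sibship(s, list(range(1, m + 1)))])
            assert math.isclose(res.rank_sum_null_mean, mean, abs_tol=1e-12)
            assert math.isclose(res.rank_sum_null_variance, var, abs_tol=1e-9)

    def test_uninformative_sibships_are_excluded(self):
        sibs = [make_sibship(3, [2]),
                make_sibship(1, [1]),          # singleton
                make_sibship(2, [1, 2])]       # all affected
        res = haldane_smith_test(sibs)
        assert res.n_sibships_informative == 1
        assert res.rank_sum_observed == 2

    def test_no_informative_sibship_errors(self):
        with pytest.raises(AnalysisError):
            haldane_smith_test([make_sibship(1, [1])])

    def test_ci_is_mean_plus_minus_196_sd(self):
        res = haldane_smith_test([make_sibship(4, [3]), make_sibship(5, [2, 4])])
        sd = math.sqrt(res.rank_sum_null_variance)
        assert math.isclose(res.ci95[0], res.rank_sum_null_mean - 1.96 * sd)
        assert math.isclose(res.ci95[1], res.rank_sum_null_mean + 1.96 * sd)

    def test_restrict_changes_m(self):
        sib = make_sibship(4, [1, 4])
        full = haldane_smith_test([sib])
        assert full.rank_sum_observed == 5
        with pytest.raises(AnalysisError):
            haldane_smith_test([sib], make_restrict(sex=Sex.FEMALE))


# ---------------------------------------------------------------------------
# Wilcoxon control
# ---------------------------------------------------------------------------
class TestWilcoxonControl:
    def test_score_definition(self):
        # affected youngest of three (two older healthy) -> score +2
        res = wilcoxon_boe_control([make_sibship(3, [3])])
        assert res.defined and res.mean_score == 2.0

    def test_only_child_is_undefined(self):
        res = wilcoxon_boe_control([make_sibship(1, [1])])
        assert not res.defined

    def test_balanced_middle_child_score_zero(self):
        res = wilcoxon_boe_control([make_sibship(3, [2])])
        assert not res.defined  # single zero score drops, leaving nothing


# ---------------------------------------------------------------------------
# anticipation
# ---------------------------------------------------------------------------
class TestAnticipation:
    def test_equal_onsets_no_trend(self):
        members = [ind("gf", dx=MM, onset=60), ind("gm", sex=Sex.FEMALE),
                   ind("m", father="gf", mother="gm", sex=Sex.FEMALE, rank=1,
                       dx=MM, onset=60),
                   ind("f2", sex=Sex.MALE),
                   ind("c", father="f2", mother="m", rank=1, dx=CLL, onset=60)]
        rep = assess_anticipation(Pedigree(members))
        assert rep.trend_defined
        assert rep.trend_statistic == 0.0 and rep.onset_slope == 0.0

    def test_single_stratum_trend_undefined(self, trio):
        rep = assess_anticipation(trio)
        assert not rep.trend_defined

    def test_no_onset_ages_errors(self):
        ped = Pedigree([ind("a", dx=CLL)])
        with pytest.raises(AnalysisError):
            assess_anticipation(ped)

    def test_strata_ordered_oldest_to_youngest(self):
        members = [ind("gf", dx=MM, onset=75), ind("gm", sex=Sex.FEMALE),
                   ind("m", father="gf", mother="gm", sex=Sex.FEMALE, rank=1,
                       dx=MM, onset=65),
                   ind("f2", sex=Sex.MALE),
                   ind("c", father="f2", mother="m", rank=1, dx=CLL, onset=50)]
        rep = assess_anticipation(Pedigree(members))
        assert list(rep.strata.generation) == [0, 1, 2]
        assert list(rep.strata.median_onset) == [75, 65, 50]
        assert rep.onset_slope < 0

    def test_reference_prevalence_comparison(self):
        members = [ind(f"a{i}", dx=CLL, onset=60) for i in range(8)]
        members += [ind(f"b{i}", sex=Sex.FEMALE, dx=MM, onset=65) for i in range(2)]
        ref = PrevalenceTable.from_counts(
            {"CLL": (50, 30, 20), "MM": (50, 25, 25)}, "LPD")
        rep = assess_anticipation(Pedigree(members), reference=ref)
        cmp_ = rep.prevalence_comparison.set_index("label")
        assert cmp_.loc["CLL", "familial_pct"] == 80.0
        assert cmp_.loc["CLL", "reference_pct"] == 50.0
        assert (cmp_.p_value <= 1).all()
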