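"""Unit and property tests for the type-1/type-2 SDT estimation chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metacog.sdt_core import (
    S1,
    S2,
    Type2CountTable,
    bin_confidence,
    build_type2_counts,
    compute_type1,
    efficiency_from_trials,
    fit_meta_d,
)

from _oracles import grid_search_meta_d, rank_split_bins
from conftest import make_trials


class TestComputeType1:
    def test_matches_normal_quantile_oracle(self, counts_trials):
        # z(0.8) - z(0.3) and -(z(0.8) + z(0.3))/2, frozen from scipy.stats.norm.ppf
        t1 = compute_type1(counts_trials)
        assert t1.d_prime == pytest.approx(1.3660217462809552, abs=1e-12)
        assert t1.criterion_c == pytest.approx(-0.1586103604324367, abs=1e-12)
        assert t1.hit_rate == 0.8 and t1.fa_rate == 0.3

    def test_equal_rates_give_zero(self):
        stim = [S2] * 100 + [S1] * 100
        resp = ([S2] * 50 + [S1] * 50) * 2
        t1 = compute_type1(make_trials(stim, resp))
        assert t1.d_prime == pytest.approx(0.0, abs=1e-12)
        assert t1.criterion_c == pytest.approx(0.0, abs=1e-12)

    def test_extreme_rates_corrected(self):
        # perfect performance: rates corrected to 0.995 / 0.005, z = +/-2.5758...
        stim = [S2] * 100 + [S1] * 100
        resp = [S2] * 100 + [S1] * 100
        t1 = compute_type1(make_trials(stim, resp))
        assert np.isfinite(t1.d_prime)
        assert t1.d_prime == pytest.approx(2 * 2.5758293035489004, abs=1e-12)
        assert t1.hit_rate == pytest.approx(0.995)
        assert t1.fa_rate == pytest.approx(0.005)

    def test_errors_name_missing_class(self):
        with pytest.raises(ValueError, match="empty"):
            compute_type1(make_trials([], []))
        with pytest.raises(ValueError, match="left"):
            compute_type1(make_trials([S2, S2], [S2, S1]))
        with pytest.raises(ValueError, match="right"):
            compute_type1(make_trials([S1, S1], [S2, S1]))


class TestBinConfidence:
    def test_distinct_values_equal_quartiles(self):
        bins = bin_confidence([1.0, 2.0, 3.0, 4.0, 5.0, 5.5, 5.8, 6.0], 4)
        assert bins.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_tie_groups_follow_rank_split_oracle(self):
        vals = [3, 3, 3, 3, 5, 5, 5, 5]
        assert bin_confidence(vals, 4).tolist() == rank_split_bins(vals, 4).tolist()
        # the 4-way tie on 3 straddles the first quartile boundary: all go low
        assert bin_confidence(vals, 4).tolist() == [1, 1, 1, 1, 3, 3, 3, 3]

    @pytest.mark.filterwarnings("ignore:constant confidence")
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1.0, max_value=6.0, allow_nan=False), min_size=4, max_size=60),
        st.integers(min_value=2, max_value=4),
    )
    def test_monotone_and_matches_oracle(self, vals, nbins):
        bins = bin_confidence(vals, nbins)
        assert bins.min() >= 1 and bins.max() <= nbins
        order = np.argsort(vals, kind="stable")
        assert np.all(np.diff(bins[order]) >= 0)  # monotone in the rating
        if len(set(vals)) > 1:
            assert bins.tolist() == rank_split_bins(vals, nbins).tolist()

    def test_distinct_inputs_balanced(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.linspace(1, 6, 41))
        sizes = np.bincount(bin_confidence(vals, 4))[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_four_bins_used_with_enough_distinct_values(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 6, 200)
        assert set(bin_confidence(vals, 4)) == {1, 2, 3, 4}

    def test_errors_and_constant_warning(self):
        with pytest.raises(ValueError, match="at least"):
            bin_confidence([1.0, 2.0], 4)
        with pytest.warns(RuntimeWarning, match="constant"):
            bins = bin_confidence([3.0] * 10, 4)
        assert set(bins) == {1}


class TestType2Counts:
    def test_direct_count_and_order_invariance(self):
        df = make_trials([S2, S2], [S2, S2], conf_bin=[4, 4])
        tab = build_type2_counts(df, 4)
        assert tab.s2_correct.tolist() == [0, 0, 0, 2]
        assert tab.s1_correct.sum() == tab.s1_incorrect.sum() == tab.s2_incorrect.sum() == 0
        df2 = make_trials([S2, S1, S2], [S2, S2, S1], conf_bin=[1, 2, 3])
        shuffled = df2.sample(frac=1, random_state=7)
        a, b = build_type2_counts(df2, 4), build_type2_counts(shuffled, 4)
        for name in ("s1_correct", "s1_incorrect", "s2_correct", "s2_incorrect"):
            assert getattr(a, name).tolist() == getattr(b, name).tolist()

    def test_marginals_match_independent_tally(self, ideal_session):
        df = ideal_session.head(200).copy()
        df["confidence_bin"] = bin_confidence(df["confidence_raw"].to_numpy(), 4)
        tab = build_type2_counts(df, 4)
        # naive per-row tally
        naive = {}
        for row in df.itertuples(index=False):
            key = (row.response_side, row.accuracy, row.confidence_bin)
            naive[key] = naive.get(key, 0) + 1
        for b in range(1, 5):
            assert tab.s2_correct[b - 1] == naive.get((S2, 1, b), 0)
            assert tab.s1_incorrect[b - 1] == naive.get((S1, 0, b), 0)
        assert tab.n_total == 200
        t1 = compute_type1(df)
        n_resp_s2 = tab.s2_correct.sum() + tab.s2_incorrect.sum()
        assert n_resp_s2 == (df["response_side"] == S2).sum()

    def test_missing_bin_errors(self):
        with pytest.raises(ValueError, match="confidence_bin"):
            build_type2_counts(make_trials([S2], [S2]), 4)


def _expected_counts_from_model(d, c, crit_down, crit_up, n=1e6):
    """Analytic (non-integer) type-2 counts for an observer whose meta level
    equals its type-1 level; independent norm.cdf derivation."""
    from scipy.stats import norm

    hi = np.concatenate(([c], crit_up, [np.inf]))
    lo = np.concatenate(([c], crit_down, [-np.inf]))
    out = {}
    for stim, mu in ((S1, -d / 2), (S2, d / 2)):
        out[(stim, S2)] = np.diff(norm.cdf(hi, loc=mu)) * (n / 2)
        out[(stim, S1)] = -np.diff(norm.cdf(lo, loc=mu)) * (n / 2)
    return Type2CountTable(
        nbins=len(crit_up) + 1,
        s1_correct=out[(S1, S1)],
        s1_incorrect=out[(S2, S1)],
        s2_correct=out[(S2, S2)],
        s2_incorrect=out[(S1, S2)],
    )


class TestFitMetaD:
    def test_self_consistent_at_generating_value(self):
        # expected counts generated with meta-d' == d' = 1.5 must fit back at 1.5
        d, c = 1.5, 0.1
        tab = _expected_counts_from_model(
            d, c, crit_down=np.array([c - 0.3, c - 0.9, c - 1.6]),
            crit_up=np.array([c + 0.4, c + 1.0, c + 1.7]),
        )
        from metacog.sdt_core import Type1Summary

        hit = tab.s2_correct.sum() / (tab.s2_correct.sum() + tab.s1_incorrect.sum())
        fa = tab.s2_incorrect.sum() / (tab.s2_incorrect.sum() + tab.s1_correct.sum())
        from scipy.stats import norm

        t1 = Type1Summary(
            d_prime=norm.ppf(hit) - norm.ppf(fa),
            criterion_c=-0.5 * (norm.ppf(hit) + norm.ppf(fa)),
            n_trials=int(tab.n_total),
            hit_rate=hit,
            fa_rate=fa,
        )
        assert t1.d_prime == pytest.approx(d, abs=1e-9)
        fit = fit_meta_d(tab, t1)
        assert fit.meta_d == pytest.approx(1.5, abs=0.01)
        assert fit.efficiency == pytest.approx(1.0, abs=0.01)

    def test_small_table_matches_grid_search_oracle(self):
        tab = Type2CountTable(
            nbins=4,
            s2_correct=np.array([2, 4, 8, 16.0]),
            s2_incorrect=np.array([6, 4, 2, 1.0]),
            s1_correct=np.array([2, 4, 8, 16.0]),
            s1_incorrect=np.array([6, 4, 2, 1.0]),
        )
        # type-1 summary from the table's own stimulus/response counts
        n_s2 = tab.s2_correct.sum() + tab.s1_incorrect.sum()
        n_s1 = tab.s1_correct.sum() + tab.s2_incorrect.sum()
        hit = tab.s2_correct.sum() / n_s2
        fa = tab.s2_incorrect.sum() / n_s1
        from scipy.stats import norm

        from metacog.sdt_core import Type1Summary

        t1 = Type1Summary(
            d_prime=norm.ppf(hit) - norm.ppf(fa),
            criterion_c=-0.5 * (norm.ppf(hit) + norm.ppf(fa)),
            n_trials=int(tab.n_total),
            hit_rate=hit,
            fa_rate=fa,
        )
        fit = fit_meta_d(tab, t1)
        oracle_md, oracle_ll = grid_search_meta_d(tab, t1)
        assert fit.meta_d == pytest.approx(oracle_md, abs=0.01)

    def test_criteria_mirror_ordering_and_loglik(self, ideal_session):
        df = ideal_session.copy()
        df["confidence_bin"] = bin_confidence(df["confidence_raw"].to_numpy(), 4)
        t1 = compute_type1(df)
        fit = fit_meta_d(build_type2_counts(df, 4), t1)
        assert np.all(np.diff(fit.type2_criteria_s2) > 0)  # ascending above
        assert np.all(np.diff(fit.type2_criteria_s1) < 0)  # descending below
        assert np.all(fit.type2_criteria_s2 >= fit.meta_criterion)
        assert np.all(fit.type2_criteria_s1 <= fit.meta_criterion)
        assert fit.log_likelihood <= 0

    def test_label_symmetry(self, ideal_session):
        fit = efficiency_from_trials(ideal_session, 4)
        flipped = ideal_session.copy()
        swap = {S1: S2, S2: S1}
        flipped["stimulus_side"] = flipped["stimulus_side"].map(swap)
        flipped["response_side"] = flipped["response_side"].map(swap)
        fit2 = efficiency_from_trials(flipped, 4)
        assert fit2.meta_d == pytest.approx(fit.meta_d, abs=1e-6)
        assert abs(fit2.criterion_c) == pytest.approx(abs(fit.criterion_c), abs=1e-9)

    def test_nonpositive_d_prime_flagged(self):
        from metacog.sdt_core import Type1Summary

        tab = Type2CountTable(
            nbins=4,
            s2_correct=np.array([5, 5, 5, 5.0]),
            s2_incorrect=np.array([5, 5, 5, 5.0]),
            s1_correct=np.array([5, 5, 5, 5.0]),
            s1_incorrect=np.array([5, 5, 5, 5.0]),
        )
        t1 = Type1Summary(d_prime=0.0, criterion_c=0.0, n_trials=80, hit_rate=0.5, fa_rate=0.5)
        fit = fit_meta_d(tab, t1)
        assert "nonpositive_d_prime" in fit.flags
        assert fit.excluded and not np.isfinite(fit.efficiency)

    def test_degenerate_single_bin_flagged(self):
        from metacog.sdt_core import Type1Summary

        tab = Type2CountTable(
            nbins=4,
            s2_correct=np.array([0, 0, 0, 40.0]),
            s2_incorrect=np.array([0, 0, 0, 10.0]),
            s1_correct=np.array([0, 0, 0, 40.0]),
            s1_incorrect=np.array([0, 0, 0, 10.0]),
        )
        t1 = Type1Summary(d_prime=1.0, criterion_c=0.0, n_trials=100, hit_rate=0.8, fa_rate=0.2)
        fit = fit_meta_d(tab, t1)
        assert "degenerate_counts" in fit.flags
        assert fit.excluded and not np.isfinite(fit.efficiency)


class TestEfficiencyFromTrials:
    def test_composition_identity(self, ideal_session):
        composed = efficiency_from_trials(ideal_session, 4)
        df = ideal_session.copy()
        t1 = compute_type1(df)
        df["confidence_bin"] = bin_confidence(df["confidence_raw"].to_numpy(), 4)
        manual = fit_meta_d(build_type2_counts(df, 4), t1)
        assert composed.meta_d == manual.meta_d
        assert composed.log_likelihood == manual.log_likelihood

    def test_shuffling_confidence_degrades_efficiency(self, ideal_session):
        base = efficiency_from_trials(ideal_session, 4).efficiency
        rng = np.random.default_rng(9)
        shuffled_effs = []
        for _ in range(50):
            df = ideal_session.copy()
            df["confidence_raw"] = rng.permutation(df["confidence_raw"].to_numpy())
            shuffled_effs.append(efficiency_from_trials(df, 4).efficiency)
        assert np.mean(shuffled_effs) < base - 0.5  # shuffling destroys the coupling

    def test_efficiency_non_increasing_in_confidence_corruption(self, ideal_session):
        rng = np.random.default_rng(11)
        means = []
        for p in (0.0, 0.25, 0.5, 0.75, 1.0):
            effs = []
            for _ in range(8):
                df = ideal_session.copy()
                conf = df["confidence_raw"].to_numpy().copy()
                mask = rng.random(len(conf)) < p
                conf[mask] = rng.uniform(conf.min(), conf.max(), mask.sum())
                df["confidence_raw"] = conf
                effs.append(efficiency_from_trials(df, 4).efficiency)
            means.append(np.mean(effs))
        assert all(b <= a + 0.06 for a, b in zip(means, means[1:]))
        assert means[-1] < means[0] - 0.5
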