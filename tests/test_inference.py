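import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from follownet.inference import (
    LRTResult,
    derive_seed,
    holm_correct,
    likelihood_ratio_test,
    loo_stability,
    node_permutation_test,
)
from follownet.models import FitSummary


def exhaustive_oracle(values, labels, level_hi):
    """Brute-force two-sided permutation p over all label assignments."""
    values = np.asarray(values, float)
    n = len(values)
    k = sum(1 for lab in labels if lab == level_hi)
    obs_idx = frozenset(i for i, lab in enumerate(labels) if lab == level_hi)
    obs = values[list(obs_idx)].mean() - np.delete(values, list(obs_idx)).mean()
    count = total = 0
    for combo in itertools.combinations(range(n), k):
        stat = values[list(combo)].mean() - np.delete(values, list(combo)).mean()
        total += 1
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
    return count / total


class TestNodePermutation:
    def test_constant_metric_gives_p_one(self):
        res = node_permutation_test(
            [1.0] * 8, ["wild"] * 4 + ["sanctuary"] * 4, n_perm=99, seed=0
        )
        assert res.p_value == 1.0
        assert res.observed_stat == 0.0

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(21)
        for trial in range(12):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, n - 1))
            values = rng.normal(size=n)
            labels = np.array(["sanctuary"] * n, dtype=object)
            labels[rng.choice(n, size=k, replace=False)] = "wild"
            res = node_permutation_test(
                values, labels, exhaustive=True
            )
            assert res.method == "exhaustive"
            assert res.n_perm == math.comb(n, k)
            assert res.p_value == pytest.approx(
                exhaustive_oracle(values, labels, "wild"), abs=1e-12
            )

    def test_separated_groups_exhaustive(self):
        values = [1.0] * 3 + [0.0] * 3
        labels = ["wild"] * 3 + ["sanctuary"] * 3
        res = node_permutation_test(values, labels, exhaustive=True)
        # only the observed assignment and its mirror reach |diff| = 1
        assert res.p_value == pytest.approx(2 / 20)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=20)
        labels = ["wild"] * 9 + ["sanctuary"] * 11
        a = node_permutation_test(values, labels, n_perm=200, seed=42)
        b = node_permutation_test(values, labels, n_perm=200, seed=42)
        np.testing.assert_array_equal(a.null_stats, b.null_stats)
        assert a.p_value == b.p_value

    def test_two_tailed_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=14)
        labels = np.array(["wild"] * 6 + ["sanctuary"] * 8, dtype=object)
        swapped = np.where(labels == "wild", "sanctuary", "wild")
        a = node_permutation_test(values, labels, n_perm=500, seed=9)
        b = node_permutation_test(values, swapped, n_perm=500, seed=9)
        assert a.p_value == b.p_value
        assert a.observed_stat == pytest.approx(-b.observed_stat)

    def test_stratified_preserves_within_group_ratio(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=12)
        labels = np.array(["wild", "sanctuary"] * 6, dtype=object)
        strata = np.repeat(["g1", "g2", "g3"], 4)
        res = node_permutation_test(
            values, labels, n_perm=50, seed=3, stratify_by=strata
        )
        assert 0 < res.p_value <= 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="two label levels"):
            node_permutation_test([1.0, 2.0], ["wild", "wild"])
        with pytest.raises(ValueError, match="n_perm"):
            node_permutation_test(
                [1.0, 2.0, 3.0, 4.0],
                ["wild", "wild", "sanctuary", "sanctuary"],
                n_perm=0,
            )

    def test_type_one_error_calibrated_under_null(self):
        # exchangeable values: rejection rate at alpha=0.05 within binomial
        # tolerance of the nominal level
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 500
        for rep in range(n_rep):
            values = rng.normal(size=20)
            labels = np.array(["wild"] * 10 + ["sanctuary"] * 10, dtype=object)
            rng.shuffle(labels)
            res = node_permutation_test(
                values, labels, n_perm=199, seed=int(rng.integers(2**31))
            )
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_correct([0.03]), [0.03])

    def test_textbook_step_down(self):
        np.testing.assert_allclose(
            holm_correct([0.01, 0.04]), [0.02, 0.04]
        )

    def test_monotonicity_enforcement(self):
        np.testing.assert_allclose(
            holm_correct([0.01, 0.02, 0.5]), [0.03, 0.04, 0.5]
        )

    def test_returns_named_series(self):
        out = holm_correct([0.2, 0.01], labels=["a", "b"])
        assert list(out.index) == ["a", "b"]
        assert out["b"] == pytest.approx(0.02)

    def test_adjusted_at_least_raw_and_input_order(self):
        rng = np.random.default_rng(3)
        p = rng.random(15)
        adj = holm_correct(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([0.5, 1.2])


def _summary(llf, k, nobs):
    return FitSummary(
        params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
        llf=llf, k_params=k, nobs=nobs, method="stub",
    )


class TestLRT:
    def test_identical_models(self):
        res = likelihood_ratio_test(_summary(-10.0, 3, 50), _summary(-10.0, 2, 50))
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(_summary(-10.0, 2, 50), _summary(-11.0, 2, 50))

    def test_observation_mismatch_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(_summary(-10.0, 3, 50), _summary(-11.0, 2, 49))

    def test_reduced_better_than_full_rejected(self):
        with pytest.raises(ValueError, match="log-likelihood"):
            likelihood_ratio_test(_summary(-12.0, 3, 50), _summary(-10.0, 2, 50))

    def test_null_distribution_approximately_uniform(self):
        # Poisson regression with a pure-noise covariate: LRT p-values
        # should be uniform under H0
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            n = 150
            y = rng.poisson(3.0, size=n)
            x = rng.normal(size=n)
            Xf = pd.DataFrame({"Intercept": np.ones(n), "x": x})
            Xn = pd.DataFrame({"Intercept": np.ones(n)})
            f = sm.GLM(y, Xf, family=sm.families.Poisson()).fit()
            r = sm.GLM(y, Xn, family=sm.families.Poisson()).fit()
            res = likelihood_ratio_test(
                _summary(f.llf, 2, n), _summary(r.llf, 1, n)
            )
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestLooStability:
    @staticmethod
    def _fit(records):
        X = pd.DataFrame(
            {"Intercept": 1.0, "x": records["x"].to_numpy(float)},
            index=records.index,
        )
        res = sm.OLS(records["y"].to_numpy(float), X).fit()
        return FitSummary(
            params=res.params, bse=res.bse, llf=res.llf,
            k_params=2, nobs=int(res.nobs), method="ols",
        )

    def test_exchangeable_subjects_not_flagged(self):
        base = pd.DataFrame({"x": [0.0, 1.0] * 4, "y": [1.0, 2.0] * 4})
        records = pd.concat(
            [base.assign(subject=f"s{i}") for i in range(6)], ignore_index=True
        )
        out = loo_stability(self._fit, records, "subject", "x")
        assert not out["flagged"].any()
        assert len(out) == 6

    def test_planted_extreme_subject_flagged(self):
        rng = np.random.default_rng(11)
        frames = []
        for i in range(8):
            x = rng.normal(size=10)
            y = 1.0 + 0.5 * x + rng.normal(scale=0.1, size=10)
            frames.append(pd.DataFrame({"x": x, "y": y, "subject": f"s{i}"}))
        # one subject with a wildly different slope
        x = rng.normal(size=10)
        frames.append(
            pd.DataFrame({"x": x, "y": 1.0 - 3.0 * x, "subject": "outlier"})
        )
        records = pd.concat(frames, ignore_index=True)
        out = loo_stability(self._fit, records, "subject", "x")
        assert out.loc[out["excluded"] == "outlier", "flagged"].item()

    def test_one_refit_per_subject(self):
        records = pd.DataFrame(
            {
                "x": np.tile([0.0, 1.0, 2.0], 5),
                "y": np.tile([1.0, 2.0, 3.0], 5),
                "subject": np.repeat([f"s{i}" for i in range(5)], 3),
            }
        )
        out = loo_stability(self._fit, records, "subject", "x")
        assert len(out) == 5

    def test_too_few_subjects_rejected(self):
        records = pd.DataFrame(
            {"x": [0.0, 1.0], "y": [1.0, 2.0], "subject": ["a", "b"]}
        )
        with pytest.raises(ValueError):
            loo_stability(self._fit, records, "subject", "x")


def test_derived_seeds_stable_and_distinct():
    a = derive_seed(1, "proximity", "strength")
    assert a == derive_seed(1, "proximity", "strength")
    assert a != derive_seed(1, "proximity", "reach")
    assert a != derive_seed(2, "proximity", "strength")
    assert 0 <= a < 2**31
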