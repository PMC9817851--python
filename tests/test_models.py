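import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import follownet as fn
from follownet.association import AssociationMatrix
from follownet.models import (
    build_dyad_table,
    build_party_records,
    early_late_contrast,
    fit_hurdle,
    fit_party_size,
    party_size,
)


def simulate_party_records(
    rng, n_subjects=60, follows_each=25, beta_origin=0.0, sigma_u=0.0,
    base=6.0,
):
    """Direct simulation from the party-size model (no network machinery)."""
    origin = np.array(["wild", "sanctuary"])[
        (np.arange(n_subjects) >= n_subjects // 2).astype(int)
    ]
    u = rng.normal(0.0, sigma_u, size=n_subjects) if sigma_u > 0 else np.zeros(
        n_subjects
    )
    rows = []
    for i in range(n_subjects):
        rank_z = rng.normal()
        age_z = rng.normal()
        sex = "M" if i % 2 else "F"
        for j in range(follows_each):
            dur = rng.uniform(300, 600)
            log_mu = (
                np.log(base)
                + (beta_origin if origin[i] == "wild" else 0.0)
                + u[i]
                + np.log(dur / 450.0)
            )
            rows.append(
                {
                    "follow_id": f"f{i}_{j}",
                    "focal_id": f"s{i}",
                    "origin": origin[i],
                    "sex": sex,
                    "rank_z": rank_z,
                    "age_z": age_z,
                    "arrival_age_years": 2.0 if i % 2 else 4.0,
                    "associates": rng.poisson(np.exp(log_mu)),
                    "log_duration_offset": np.log(dur / 450.0),
                    "log_popsize_offset": 0.0,
                    "log_family_units_offset": 0.0,
                }
            )
    rec = pd.DataFrame(rows)
    rec["party_size"] = rec["associates"] + 1
    return rec


class TestPartySize:
    def test_focal_alone(self):
        assert party_size({"party_member_ids": ()}) == 1

    def test_includes_focal(self):
        assert party_size({"party_member_ids": ("a", "b", "c", "d", "e")}) == 6

    def test_definitional_for_random_party(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(0, 15))
            members = tuple(f"m{i}" for i in range(k))
            assert party_size({"party_member_ids": members}) == k + 1


class TestBuildPartyRecords:
    def test_covariates_standardised_and_offsets_logged(self, toy_dataset):
        rec = build_party_records(toy_dataset)
        assert len(rec) == 4
        assert rec["rank_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert rec["rank_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            rec["log_popsize_offset"], np.log(4.0)
        )
        # matrilines m1, m2, m3 -> three family units
        np.testing.assert_allclose(
            rec["log_family_units_offset"], np.log(3.0)
        )
        assert rec.loc[0, "party_size"] == 3


class TestFitPartySize:
    def test_offset_algebra_doubling_duration(self):
        rng = np.random.default_rng(5)
        rec = simulate_party_records(rng, n_subjects=30, follows_each=10)
        doubled = rec.copy()
        doubled["log_duration_offset"] = rec["log_duration_offset"] + np.log(2.0)
        a = fit_party_size(rec, random_intercepts=False, cluster_robust=False)
        b = fit_party_size(doubled, random_intercepts=False, cluster_robust=False)
        assert b.params["Intercept"] == pytest.approx(
            a.params["Intercept"] - np.log(2.0), abs=1e-8
        )
        for name in ("origin[wild]", "rank_z", "age_z", "sex[M]"):
            assert b.params[name] == pytest.approx(a.params[name], abs=1e-8)

    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(6)
        rec = simulate_party_records(rng, n_subjects=20, follows_each=10)
        y = rec["associates"].to_numpy(float)
        off = rec["log_duration_offset"].to_numpy(float)
        import statsmodels.api as sm

        res = sm.GLM(
            y, np.ones((len(y), 1)), family=sm.families.Poisson(), offset=off
        ).fit()
        closed_form = np.log(y.sum() / np.exp(off).sum())
        assert res.params[0] == pytest.approx(closed_form, abs=1e-10)

    def test_null_consistency_large_n(self):
        rng = np.random.default_rng(7)
        rec = simulate_party_records(
            rng, n_subjects=100, follows_each=40, beta_origin=0.0
        )
        fit = fit_party_size(rec, random_intercepts=False, cluster_robust=False)
        assert abs(fit.params["origin[wild]"]) < 0.05

    def test_recovers_injected_origin_effect(self):
        rng = np.random.default_rng(8)
        covered = 0
        for _ in range(20):
            rec = simulate_party_records(
                rng, n_subjects=60, follows_each=25, beta_origin=-0.3,
                sigma_u=0.25,
            )
            fit = fit_party_size(rec)
            b, se = fit.params["origin[wild]"], fit.bse["origin[wild]"]
            covered += abs(b - (-0.3)) <= 3 * se
        assert covered >= 18

    def test_repeated_fits_identical(self):
        rng = np.random.default_rng(9)
        rec = simulate_party_records(rng, n_subjects=30, follows_each=10,
                                     sigma_u=0.2)
        a = fit_party_size(rec)
        b = fit_party_size(rec)
        pd.testing.assert_series_equal(a.params, b.params)
        assert a.llf == b.llf

    def test_single_origin_level_rejected(self):
        rng = np.random.default_rng(10)
        rec = simulate_party_records(rng, n_subjects=10, follows_each=5)
        rec["origin"] = "wild"
        with pytest.raises(ValueError, match="single level"):
            fit_party_size(rec)


class TestEarlyLateContrast:
    def test_single_stratum_rejected(self):
        rng = np.random.default_rng(11)
        rec = simulate_party_records(rng, n_subjects=10, follows_each=5)
        rec = rec[rec["origin"] == "wild"].copy()
        rec["arrival_age_years"] = 1.5
        with pytest.raises(ValueError, match="stratum"):
            early_late_contrast(rec)

    def test_arrival_exactly_at_cutoff_is_later(self):
        rng = np.random.default_rng(12)
        rec = simulate_party_records(rng, n_subjects=12, follows_each=6)
        rec = rec[rec["origin"] == "wild"].copy()
        subjects = rec["focal_id"].unique()
        arrival = {s: (1.0 if i < len(subjects) // 2 else 3.0)
                   for i, s in enumerate(subjects)}
        rec["arrival_age_years"] = rec["focal_id"].map(arrival)
        _, full = early_late_contrast(rec, cutoff_years=3.0)
        # exactly-3 subjects sit in the "later" stratum: only the 1.0-year
        # arrivals count as early, so the early share is 1/2
        early_share = (
            rec.groupby("focal_id")["arrival_age_years"].first() < 3.0
        ).mean()
        assert early_share == 0.5
        assert "early[True]" in full.params.index

    def test_detects_injected_early_late_effect(self):
        # designed power run: low-noise generator, ~1500 wild-born follows
        cfg = fn.SyntheticConfig(
            group_sizes=(16, 15),
            wild_per_group=(12, 12),
            n_days=150,
            follows_per_day=5,
            gregariousness_sd=0.10,
            early_late_effect_party=0.2,
            matriline_boost=0.0,
        )
        hits = 0
        n_rep = 15
        for rep in range(n_rep):
            ds, _ = fn.generate(dataclasses.replace(cfg, seed=40_000 + rep))
            rec = build_party_records(ds)
            lrt, _ = early_late_contrast(rec)
            hits += lrt.p_value < 0.05
        assert hits >= 0.8 * n_rep


def _matrix_from(values, ids):
    vals = np.asarray(values, float)
    return AssociationMatrix(ids, vals)


class TestBuildDyadTable:
    @pytest.fixture
    def demographics(self):
        return pd.DataFrame(
            {
                "group_id": ["G1"] * 3,
                "origin": ["wild", "wild", "sanctuary"],
                "sex": ["F", "M", "F"],
                "age_years": [15.0, 9.0, 20.0],
                "matriline_id": ["m1", "m1", "m2"],
                "rank": [0.0, 0.0, 0.0],
            },
            index=["A", "B", "C"],
        )

    def test_origin_combinatorics(self, demographics):
        vals = np.array(
            [[np.nan, 0.5, 0.0], [0.5, np.nan, 0.2], [0.0, 0.2, np.nan]]
        )
        dyads = build_dyad_table(_matrix_from(vals, ["A", "B", "C"]), demographics)
        assert sorted(dyads["dyad_origin"]) == ["WS", "WS", "WW"]

    def test_matriline_and_age_classes(self, demographics):
        vals = np.array(
            [[np.nan, 0.5, 0.0], [0.5, np.nan, 0.2], [0.0, 0.2, np.nan]]
        )
        dyads = build_dyad_table(
            _matrix_from(vals, ["A", "B", "C"]), demographics,
            adult_cutoff_years=12.0,
        )
        ab = dyads[(dyads["id_a"] == "A") & (dyads["id_b"] == "B")].iloc[0]
        assert ab["same_matriline"]
        assert ab["dyad_age"] == "subadult-adult"
        assert ab["dyad_sex"] == "MF"

    def test_category_counts_match_enumeration(self):
        rng = np.random.default_rng(13)
        n = 10
        dem = pd.DataFrame(
            {
                "group_id": ["G1"] * n,
                "origin": rng.choice(["wild", "sanctuary"], size=n),
                "sex": rng.choice(["F", "M"], size=n),
                "age_years": rng.uniform(3, 30, size=n),
                "matriline_id": rng.choice(["m1", "m2", "m3"], size=n),
                "rank": np.zeros(n),
            },
            index=[f"i{k}" for k in range(n)],
        )
        vals = rng.random((n, n))
        vals = np.triu(vals, 1) + np.triu(vals, 1).T
        dyads = build_dyad_table(_matrix_from(vals, list(dem.index)), dem)
        assert len(dyads) == n * (n - 1) // 2
        for a, b in itertools.combinations(dem.index, 2):
            row = dyads[
                (dyads["id_a"] == a) & (dyads["id_b"] == b)
            ].iloc[0]
            n_wild = (dem.loc[[a, b], "origin"] == "wild").sum()
            assert row["dyad_origin"] == {0: "SS", 1: "WS", 2: "WW"}[n_wild]
            n_adult = (dem.loc[[a, b], "age_years"] >= 12.0).sum()
            assert (
                row["dyad_age"]
                == ["subadult-subadult", "subadult-adult", "adult-adult"][n_adult]
            )

    def test_cross_group_and_missing_excluded(self, demographics):
        dem = demographics.copy()
        dem.loc["C", "group_id"] = "G2"
        vals = np.array(
            [[np.nan, np.nan, 0.1], [np.nan, np.nan, 0.2], [0.1, 0.2, np.nan]]
        )
        dyads = build_dyad_table(_matrix_from(vals, ["A", "B", "C"]), dem)
        # A-B has a missing index; A-C and B-C are cross-group
        assert len(dyads) == 0

    def test_unknown_id_rejected(self, demographics):
        vals = np.zeros((2, 2))
        with pytest.raises(ValueError, match="missing from demographics"):
            build_dyad_table(_matrix_from(vals, ["A", "Z"]), demographics)


def simulate_dyad_table(rng, n=600, beta_bin=(0.0, 0.0), beta_gam=(0.0, 0.0),
                        shape=2.0):
    """Two-part synthetic dyad data with known origin coefficients.

    beta_* are the (WS, WW) contrasts against the SS reference; intercepts
    are -0.2 (logit) and log(0.05) (gamma mean).
    """
    origin = rng.choice(["SS", "WS", "WW"], size=n, p=[0.3, 0.45, 0.25])
    sex = rng.choice(["FF", "MF", "MM"], size=n)
    age = rng.choice(
        ["subadult-subadult", "subadult-adult", "adult-adult"], size=n
    )
    mat = rng.random(n) < 0.15
    logit = (
        -0.2
        + np.select([origin == "WS", origin == "WW"], list(beta_bin), 0.0)
        + 0.3 * (sex == "MM")
        + 0.5 * mat
    )
    connected = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    log_mu = (
        np.log(0.05)
        + np.select([origin == "WS", origin == "WW"], list(beta_gam), 0.0)
        + 0.2 * mat
    )
    ai = np.where(
        connected, rng.gamma(shape, np.exp(log_mu) / shape, size=n), 0.0
    )
    return pd.DataFrame(
        {
            "id_a": [f"a{i}" for i in range(n)],
            "id_b": [f"b{i}" for i in range(n)],
            "ai_value": ai,
            "nonzero": connected,
            "dyad_origin": origin,
            "dyad_sex": sex,
            "dyad_age": age,
            "same_matriline": mat,
            "group_id": "G1",
            "log_popsize_offset": 0.0,
        }
    )


class TestFitHurdle:
    def test_loglik_factorisation_and_determinism(self):
        rng = np.random.default_rng(14)
        dyads = simulate_dyad_table(rng)
        fit = fit_hurdle(dyads)
        assert fit.loglik_total == pytest.approx(
            fit.binomial.llf + fit.gamma.llf
        )
        again = fit_hurdle(dyads)
        pd.testing.assert_series_equal(fit.gamma.params, again.gamma.params)

    def test_zero_rows_do_not_touch_gamma_part(self):
        rng = np.random.default_rng(15)
        dyads = simulate_dyad_table(rng)
        fit = fit_hurdle(dyads)
        # perturb the covariates of zero dyads only
        perturbed = dyads.copy()
        zeros = ~perturbed["nonzero"]
        perturbed.loc[zeros, "dyad_sex"] = "MM"
        fit2 = fit_hurdle(perturbed)
        pd.testing.assert_series_equal(fit.gamma.params, fit2.gamma.params)

    def test_all_zero_unfittable(self):
        rng = np.random.default_rng(16)
        dyads = simulate_dyad_table(rng)
        dyads["ai_value"] = 0.0
        dyads["nonzero"] = False
        with pytest.raises(ValueError, match="zero"):
            fit_hurdle(dyads)

    def test_recovers_two_part_coefficients(self):
        rng = np.random.default_rng(17)
        truth_bin, truth_gam = (0.4, 0.8), (0.15, 0.3)
        covered = 0
        for _ in range(20):
            dyads = simulate_dyad_table(
                rng, n=700, beta_bin=truth_bin, beta_gam=truth_gam
            )
            fit = fit_hurdle(dyads, use_offset=False)
            ok = True
            for part, truths in (
                (fit.binomial, truth_bin),
                (fit.gamma, truth_gam),
            ):
                for name, truth in zip(
                    ("dyad_origin[WS]", "dyad_origin[WW]"), truths
                ):
                    b, se = part.params[name], part.bse[name]
                    ok &= abs(b - truth) <= 3 * se
            covered += ok
        assert covered >= 18

    def test_joint_lrt_null_uniform(self):
        rng = np.random.default_rng(18)
        pvals = []
        for _ in range(200):
            dyads = simulate_dyad_table(rng, n=400)
            fit = fit_hurdle(dyads, use_offset=False)
            pvals.append(fit.lrt_joint.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_gamma_shape_recovered(self):
        rng = np.random.default_rng(19)
        dyads = simulate_dyad_table(rng, n=4000, shape=2.0)
        fit = fit_hurdle(dyads, use_offset=False)
        assert fit.gamma_shape == pytest.approx(2.0, rel=0.15)
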