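"""Party-size Poisson regression and the two-part hurdle model for dyadic
association indices.

Party size is the focal's subgroup size including the focal itself, so the
stochastic response modelled here is the associate count (party size minus
one): a Poisson response whose support correctly starts at zero.  The model
regresses it on origin, standardised rank and age, and sex, with log follow
duration and log group-demography terms as offsets; by default the focal
enters as a random intercept (latent gregariousness), which is what makes the
likelihood-ratio test on origin honest about repeated follows of the same
individual.

Association indices are analysed with a hurdle model: a Binomial (logit) part
for whether a dyad is connected at all, and a Gamma (log link) part for the
magnitude of the nonzero indices.  Dyad-level covariates are the origin pair
(WW/WS/SS), sex pair, age-class pair and shared matriline, with log group
size as offset.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .association import AssociationMatrix
from .glmm import fit_poisson_random_intercept
from .inference import LRTResult, likelihood_ratio_test

DEFAULT_ADULT_CUTOFF = 12.0
DEFAULT_EARLY_LATE_CUTOFF = 3.0


@dataclasses.dataclass
class FitSummary:
    """Uniform face of a fitted model for LRTs and reporting."""

    params: pd.Series
    bse: pd.Series
    llf: float
    k_params: int
    nobs: int
    method: str
    extra: dict = dataclasses.field(default_factory=dict)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse})


def party_size(follow) -> int:
    """Number of individuals in the focal's party, including the focal."""
    if hasattr(follow, "party_member_ids"):
        party = follow.party_member_ids
    else:
        party = follow["party_member_ids"]
    return len(party) + 1


def build_party_records(dataset) -> pd.DataFrame:
    """One row per retained follow with response, covariates and offsets.

    Offsets: log in-view duration, log group size ("population size") and log
    number of family units (matrilines, unassigned individuals counting as
    their own unit).  rank and age are z-scored over the analysis set.
    """
    dem = dataset.demographics
    follows = dataset.follows
    if len(follows) == 0:
        raise ValueError("no follows to analyse")
    group_sizes = dem.groupby("group_id").size()

    def _n_family_units(mat):
        return mat.nunique(dropna=True) + int(mat.isna().sum())

    family_units = dem.groupby("group_id")["matriline_id"].agg(_n_family_units)
    rec = pd.DataFrame(
        {
            "follow_id": follows["follow_id"].to_numpy(),
            "focal_id": follows["focal_id"].to_numpy(),
            "date": follows["date"].to_numpy(),
            "group_id": follows["group_id"].to_numpy(),
            "party_size": [party_size(row) for _, row in follows.iterrows()],
        }
    )
    rec["associates"] = rec["party_size"] - 1
    rec["origin"] = dem.loc[rec["focal_id"], "origin"].to_numpy()
    rec["sex"] = dem.loc[rec["focal_id"], "sex"].to_numpy()
    rec["arrival_age_years"] = dem.loc[rec["focal_id"], "arrival_age_years"].to_numpy()
    for col, src in (("rank_z", "rank"), ("age_z", "age_years")):
        raw = dem.loc[rec["focal_id"], src].to_numpy(dtype=float)
        sd = raw.std()
        rec[col] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    rec["log_duration_offset"] = np.log(follows["in_view_seconds"].to_numpy(float))
    rec["log_popsize_offset"] = np.log(group_sizes.loc[rec["group_id"]].to_numpy(float))
    rec["log_family_units_offset"] = np.log(
        family_units.loc[rec["group_id"]].to_numpy(float)
    )
    return rec


def _party_design(
    records: pd.DataFrame,
    include_origin: bool,
    extra_terms: tuple = (),
) -> pd.DataFrame:
    X = pd.DataFrame(index=records.index)
    X["Intercept"] = 1.0
    if include_origin:
        levels = sorted(records["origin"].unique())
        if len(levels) < 2:
            raise ValueError("origin has a single level; nothing to contrast")
        X["origin[wild]"] = (records["origin"] == "wild").astype(float)
    X["rank_z"] = records["rank_z"].to_numpy(float)
    X["age_z"] = records["age_z"].to_numpy(float)
    X["sex[M]"] = (records["sex"] == "M").astype(float)
    for term in extra_terms:
        X[term] = records[term].to_numpy(float)
    return X


def _party_offset(records: pd.DataFrame, offsets, offset_mode: str) -> np.ndarray:
    total = np.zeros(len(records))
    if "duration" in offsets:
        total = total + records["log_duration_offset"].to_numpy(float)
    if offset_mode == "separate":
        if "popsize" in offsets:
            total = total + records["log_popsize_offset"].to_numpy(float)
        if "family_units" in offsets:
            total = total + records["log_family_units_offset"].to_numpy(float)
    elif offset_mode == "ratio":
        # single demographic offset log(popsize / family units)
        total = (
            total
            + records["log_popsize_offset"].to_numpy(float)
            - records["log_family_units_offset"].to_numpy(float)
        )
    else:
        raise ValueError(f"unknown offset_mode {offset_mode!r}")
    return total


def fit_party_size(
    records: pd.DataFrame,
    include_origin: bool = True,
    random_intercepts: bool = True,
    offsets: tuple = ("duration", "popsize", "family_units"),
    offset_mode: str = "separate",
    response: str = "associates",
    extra_terms: tuple = (),
    cluster_robust: bool = True,
) -> FitSummary:
    """Poisson regression of party size (associate count) with offsets.

    With ``random_intercepts`` (default) the focal individual enters as a
    normal random intercept and the fit is marginal ML (LRT-able logliks);
    otherwise a fixed-effects Poisson GLM is fitted, with cluster-robust
    standard errors by focal unless ``cluster_robust=False``.
    """
    if response not in ("associates", "party_size"):
        raise ValueError("response must be 'associates' or 'party_size'")
    y = records[response].to_numpy(float)
    X = _party_design(records, include_origin, extra_terms)
    offset = _party_offset(records, offsets, offset_mode)
    if random_intercepts:
        fit = fit_poisson_random_intercept(y, X, records["focal_id"], offset=offset)
        if not fit.converged:
            raise RuntimeError(
                "random-intercept Poisson fit did not converge "
                f"(llf={fit.llf:.3f}, sigma_u={fit.sigma_u:.3f})"
            )
        return FitSummary(
            params=fit.params,
            bse=fit.bse,
            llf=fit.llf,
            k_params=fit.k_params,
            nobs=fit.nobs,
            method="poisson_glmm_focal_ri",
            extra={
                "sigma_u": fit.sigma_u,
                "sigma_u_se": fit.sigma_u_se,
                "n_focals": fit.n_groups,
                "response": response,
                "offsets": list(offsets),
                "offset_mode": offset_mode,
            },
        )
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (separation/collinearity)")
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    if cluster_robust:
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": records["focal_id"].to_numpy()}
        )
    else:
        res = model.fit()
    if not res.converged:
        raise RuntimeError("Poisson GLM did not converge")
    return FitSummary(
        params=res.params,
        bse=res.bse,
        llf=float(res.llf),
        k_params=X.shape[1],
        nobs=int(res.nobs),
        method="poisson_glm" + ("_cluster" if cluster_robust else ""),
        extra={"response": response, "offsets": list(offsets),
               "offset_mode": offset_mode},
    )


def origin_lrt(records: pd.DataFrame, **fit_kwargs) -> tuple[LRTResult, FitSummary]:
    """LRT of the origin fixed effect (full vs null), returning the full fit."""
    full = fit_party_size(records, include_origin=True, **fit_kwargs)
    null = fit_party_size(records, include_origin=False, **fit_kwargs)
    return likelihood_ratio_test(full, null), full


def early_late_contrast(
    records: pd.DataFrame,
    cutoff_years: float = DEFAULT_EARLY_LATE_CUTOFF,
    **fit_kwargs,
) -> tuple[LRTResult, FitSummary]:
    """Early- vs later-orphaned contrast among wild-born focals.

    Arrival age below ``cutoff_years`` is "early"; exactly at the cutoff is
    "later".  Same model family as the origin analysis, with the binary
    early indicator in place of origin, tested by LRT.
    """
    wild = records[records["origin"] == "wild"].copy()
    if wild["arrival_age_years"].isna().any():
        missing = wild.loc[wild["arrival_age_years"].isna(), "focal_id"].iloc[0]
        raise ValueError(f"wild-born focal {missing!r} lacks an arrival age")
    wild["early[True]"] = (wild["arrival_age_years"] < cutoff_years).astype(float)
    strata = wild.groupby("focal_id")["early[True]"].first()
    if strata.nunique() < 2:
        raise ValueError("all wild-born focals fall in a single early/late stratum")
    full = fit_party_size(
        wild, include_origin=False, extra_terms=("early[True]",), **fit_kwargs
    )
    null = fit_party_size(wild, include_origin=False, **fit_kwargs)
    return likelihood_ratio_test(full, null), full


# ---------------------------------------------------------------------------
# dyadic hurdle model


def _pair_code(a: str, b: str, order: dict) -> str:
    x, y = sorted((a, b), key=order.get)
    return x + y


def build_dyad_table(
    A: AssociationMatrix,
    demographics: pd.DataFrame,
    adult_cutoff_years: float = DEFAULT_ADULT_CUTOFF,
) -> pd.DataFrame:
    """One row per within-group dyad with derived categorical covariates.

    dyad_origin in {WW, WS, SS}; dyad_sex in {FF, MF, MM}; dyad_age over
    subadult (< ``adult_cutoff_years``) / adult classes; same_matriline is
    False when either matriline is unknown.  Dyads with a missing association
    index (never co-sampled, or cross-group) are excluded.
    """
    dem = demographics
    unknown = [i for i in A.ids if i not in dem.index]
    if unknown:
        raise ValueError(f"individuals missing from demographics: {unknown[:5]}")
    group_sizes = dem.groupby("group_id").size()
    origin_order = {"wild": 0, "sanctuary": 1}
    sex_order = {"M": 0, "F": 1}
    rows = []
    n = len(A.ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = A.ids[i], A.ids[j]
            if dem.at[a, "group_id"] != dem.at[b, "group_id"]:
                continue
            ai = A.values[i, j]
            if not np.isfinite(ai):
                continue
            oa, ob = dem.at[a, "origin"], dem.at[b, "origin"]
            code = _pair_code("W" if oa == "wild" else "S",
                              "W" if ob == "wild" else "S",
                              {"W": 0, "S": 1})
            sex = _pair_code(dem.at[a, "sex"], dem.at[b, "sex"], sex_order)
            adult_a = dem.at[a, "age_years"] >= adult_cutoff_years
            adult_b = dem.at[b, "age_years"] >= adult_cutoff_years
            n_adult = int(adult_a) + int(adult_b)
            age = ("subadult-subadult", "subadult-adult", "adult-adult")[n_adult]
            mat_a, mat_b = dem.at[a, "matriline_id"], dem.at[b, "matriline_id"]
            same = bool(pd.notna(mat_a) and pd.notna(mat_b) and mat_a == mat_b)
            group = dem.at[a, "group_id"]
            rows.append(
                {
                    "id_a": a,
                    "id_b": b,
                    "ai_value": float(ai),
                    "nonzero": bool(ai > 0),
                    "dyad_origin": code,
                    "dyad_sex": sex,
                    "dyad_age": age,
                    "same_matriline": same,
                    "group_id": group,
                    "log_popsize_offset": float(np.log(group_sizes[group])),
                }
            )
    return pd.DataFrame(rows)


def _dyad_design(dyads: pd.DataFrame, include_origin: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=dyads.index)
    X["Intercept"] = 1.0
    if include_origin:
        for level in ("WS", "WW"):  # SS is the reference
            col = dyads["dyad_origin"] == level
            if col.any():
                X[f"dyad_origin[{level}]"] = col.astype(float)
    for level in ("MF", "MM"):  # FF reference
        col = dyads["dyad_sex"] == level
        if col.any():
            X[f"dyad_sex[{level}]"] = col.astype(float)
    for level in ("subadult-adult", "adult-adult"):  # subadult-subadult reference
        col = dyads["dyad_age"] == level
        if col.any():
            X[f"dyad_age[{level}]"] = col.astype(float)
    X["same_matriline[True]"] = dyads["same_matriline"].astype(float)
    return X


def _gamma_profile_llf(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Profile the Gamma shape out by 1-D ML given fitted means."""

    def negll(log_a):
        a = np.exp(log_a)
        return -float(
            np.sum(
                a * log_a
                - a * np.log(mu)
                + (a - 1.0) * np.log(y)
                - a * y / mu
                - gammaln(a)
            )
        )

    res = minimize_scalar(negll, bounds=(-6.0, 12.0), method="bounded",
                          options={"xatol": 1e-10})
    shape = float(np.exp(res.x))
    return -float(res.fun), shape


@dataclasses.dataclass
class HurdleFit:
    """Two-part fit: Binomial connection part + Gamma magnitude part."""

    binomial: FitSummary
    gamma: FitSummary
    gamma_shape: float
    loglik_total: float
    lrt_binomial: LRTResult | None = None
    lrt_gamma: LRTResult | None = None
    lrt_joint: LRTResult | None = None


def _fit_hurdle_parts(dyads: pd.DataFrame, include_origin: bool, use_offset: bool):
    y_bin = dyads["nonzero"].to_numpy(float)
    X_bin = _dyad_design(dyads, include_origin)
    offset = dyads["log_popsize_offset"].to_numpy(float) if use_offset else None
    if np.linalg.matrix_rank(X_bin.to_numpy(float)) < X_bin.shape[1]:
        raise ValueError("binomial design is rank-deficient (collinear covariates)")
    res_bin = sm.GLM(
        y_bin, X_bin, family=sm.families.Binomial(), offset=offset
    ).fit(maxiter=200)
    if not res_bin.converged:
        raise RuntimeError("binomial hurdle part did not converge")
    bin_fit = FitSummary(
        params=res_bin.params,
        bse=res_bin.bse,
        llf=float(res_bin.llf),
        k_params=X_bin.shape[1],
        nobs=int(res_bin.nobs),
        method="binomial_logit",
    )

    nz = dyads[dyads["nonzero"]]
    if len(nz) == 0:
        raise ValueError("gamma part unfittable: no nonzero association indices")
    y_gam = nz["ai_value"].to_numpy(float)
    X_gam = _dyad_design(nz, include_origin)
    if np.linalg.matrix_rank(X_gam.to_numpy(float)) < X_gam.shape[1]:
        raise ValueError("gamma design is rank-deficient (collinear covariates)")
    off_gam = nz["log_popsize_offset"].to_numpy(float) if use_offset else None
    res_gam = sm.GLM(
        y_gam, X_gam, family=sm.families.Gamma(link=sm.families.links.Log()),
        offset=off_gam,
    ).fit(maxiter=200)
    if not res_gam.converged:
        raise RuntimeError("gamma hurdle part did not converge")
    mu = np.asarray(res_gam.mu, dtype=float)
    llf_gam, shape = _gamma_profile_llf(y_gam, mu)
    gam_fit = FitSummary(
        params=res_gam.params,
        bse=res_gam.bse,
        llf=llf_gam,
        k_params=X_gam.shape[1] + 1,  # + profiled shape
        nobs=int(res_gam.nobs),
        method="gamma_log",
        extra={"shape": shape},
    )
    return bin_fit, gam_fit, shape


def fit_hurdle(
    dyads: pd.DataFrame,
    include_origin: bool = True,
    use_offset: bool = True,
) -> HurdleFit:
    """Fit the hurdle model; with ``include_origin`` also LRT the origin pair.

    The two parts factorise: the Binomial part is fitted on the connection
    indicator over all dyads, the Gamma part on the index magnitude over the
    connected dyads only, so loglik_total is their sum.  The origin LRT is
    reported per part and jointly (summed chi-square and df).
    """
    if not dyads["nonzero"].any() or dyads["nonzero"].all():
        raise ValueError(
            "hurdle model needs at least one zero and one nonzero dyad"
        )
    bin_fit, gam_fit, shape = _fit_hurdle_parts(dyads, include_origin, use_offset)
    out = HurdleFit(
        binomial=bin_fit,
        gamma=gam_fit,
        gamma_shape=shape,
        loglik_total=bin_fit.llf + gam_fit.llf,
    )
    if include_origin and dyads["dyad_origin"].nunique() > 1:
        bin_null, gam_null, _ = _fit_hurdle_parts(dyads, False, use_offset)
        out.lrt_binomial = likelihood_ratio_test(bin_fit, bin_null)
        out.lrt_gamma = likelihood_ratio_test(gam_fit, gam_null)
        from scipy import stats as _stats

        chi2 = out.lrt_binomial.chi2 + out.lrt_gamma.chi2
        df = out.lrt_binomial.df + out.lrt_gamma.df
        out.lrt_joint = LRTResult(
            chi2=chi2,
            df=df,
            p_value=float(_stats.chi2.sf(chi2, df)),
            loglik_full=out.loglik_total,
            loglik_null=bin_null.llf + gam_null.llf,
        )
    return out
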