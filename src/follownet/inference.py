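"""Permutation tests on node attributes, Holm correction, LRTs and
leave-one-out stability diagnostics.

The node-label permutation test holds the network (hence every individual's
metric) fixed and shuffles the origin label across individuals, preserving the
label counts, so the null distribution reflects "these metric values, randomly
relabelled".  Monte-Carlo p-values use the add-one estimator
(1 + #{|null| >= |observed|}) / (n_perm + 1); exhaustive enumeration over all
C(n, k) label assignments gives the exact two-sided p.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import zlib

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_TIE_TOL = 1e-12
EXHAUSTIVE_CAP = 500_000


def derive_seed(master: int, *keys) -> int:
    """Deterministic child seed (< 2^31) from a master seed and string keys."""
    tag = ":".join([str(int(master))] + [str(k) for k in keys])
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


@dataclasses.dataclass
class PermutationResult:
    metric_name: str
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    method: str = "monte_carlo"
    statistic: str = "mean"
    labels: tuple = ()

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "observed": self.observed_stat,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "method": self.method,
            "statistic": self.statistic,
            "labels": list(self.labels),
        }


def _group_stat(values: np.ndarray, mask_hi: np.ndarray, statistic: str):
    """difference hi − lo of the group statistic, row-wise over 2-D masks."""
    v = values[None, :] if mask_hi.ndim == 2 else values
    if statistic == "mean":
        k = mask_hi.sum(axis=-1)
        tot = (np.where(mask_hi, v, 0.0)).sum(axis=-1)
        n = values.size
        return tot / k - (values.sum() - tot) / (n - k)
    if statistic == "median":
        hi = np.where(mask_hi, v, np.nan)
        lo = np.where(~mask_hi, v, np.nan)
        return np.nanmedian(hi, axis=-1) - np.nanmedian(lo, axis=-1)
    raise ValueError(f"unknown statistic {statistic!r}")


def node_permutation_test(
    values,
    labels,
    metric_name: str = "",
    n_perm: int = 1000,
    seed: int = 0,
    stratify_by=None,
    statistic: str = "mean",
    exhaustive: bool = False,
) -> PermutationResult:
    """Two-tailed permutation test of a group difference in a node metric.

    ``values`` and ``labels`` are aligned sequences (one entry per
    individual); labels must have exactly two levels.  The observed statistic
    is statistic(level_hi) − statistic(level_lo), where level_hi is the
    alphabetically later level (so for wild/sanctuary labels it is
    wild − sanctuary).  Rows with a missing metric value are dropped.
    ``stratify_by`` restricts shuffles to within the given grouping, keeping
    each group's label ratio fixed.  ``exhaustive=True`` enumerates all label
    assignments instead of sampling (unstratified only).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape != labels.shape:
        raise ValueError("values and labels must be aligned")
    strata = None if stratify_by is None else np.asarray(stratify_by, dtype=object)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    if strata is not None:
        strata = strata[keep]
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two label levels, got {levels}")
    counts = [int(np.sum(labels == lv)) for lv in levels]
    if min(counts) < 2:
        raise ValueError("need at least two individuals per label")
    mask_hi = labels == levels[1]
    observed = float(_group_stat(values, mask_hi, statistic))
    n = values.size
    k = int(mask_hi.sum())

    if exhaustive:
        if strata is not None:
            raise ValueError("exhaustive enumeration is unstratified only")
        total = math.comb(n, k)
        if total > EXHAUSTIVE_CAP:
            raise ValueError(
                f"{total} label assignments exceed the exhaustive cap"
            )
        null = np.empty(total)
        base = np.zeros(n, dtype=bool)
        for row, combo in enumerate(itertools.combinations(range(n), k)):
            mask = base.copy()
            mask[list(combo)] = True
            null[row] = _group_stat(values, mask, statistic)
        p = float(np.mean(np.abs(null) >= abs(observed) - _TIE_TOL))
        return PermutationResult(
            metric_name, observed, null, p, total, None,
            method="exhaustive", statistic=statistic, labels=tuple(levels),
        )

    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    masks = np.empty((n_perm, n), dtype=bool)
    if strata is None:
        for row in range(n_perm):
            masks[row] = rng.permutation(mask_hi)
    else:
        for row in range(n_perm):
            perm = mask_hi.copy()
            for stratum in pd.unique(strata):
                idx = np.flatnonzero(strata == stratum)
                perm[idx] = rng.permutation(perm[idx])
            masks[row] = perm
    null = np.asarray(_group_stat(values, masks, statistic), dtype=float)
    p = float(
        (1 + np.sum(np.abs(null) >= abs(observed) - _TIE_TOL)) / (n_perm + 1)
    )
    return PermutationResult(
        metric_name, observed, null, p, n_perm, seed,
        method="monte_carlo", statistic=statistic, labels=tuple(levels),
    )


def holm_correct(p_values, labels=None):
    """Step-down Holm adjustment, returned in input order (capped at 1).

    ``labels`` names the tests; when given, a named Series is returned.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty one-dimensional sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="holm")[1]
    if labels is not None:
        if len(labels) != p.size:
            raise ValueError("labels and p_values must be aligned")
        return pd.Series(adjusted, index=list(labels), name="p_holm")
    return adjusted


@dataclasses.dataclass
class LRTResult:
    chi2: float
    df: int
    p_value: float
    loglik_full: float
    loglik_null: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def likelihood_ratio_test(full, reduced) -> LRTResult:
    """Chi-square LRT of nested fits; both must expose llf, k_params, nobs."""
    if full.nobs != reduced.nobs:
        raise ValueError(
            f"fits use different observation counts ({full.nobs} vs {reduced.nobs})"
        )
    df = int(full.k_params - reduced.k_params)
    if df <= 0:
        raise ValueError("the reduced model must have fewer parameters")
    if full.llf < reduced.llf - 1e-6:
        raise ValueError(
            "full-model log-likelihood below the reduced model's: "
            f"{full.llf:.6f} < {reduced.llf:.6f} (non-nested fits?)"
        )
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p_value=p,
                     loglik_full=float(full.llf), loglik_null=float(reduced.llf))


def loo_stability(
    fit_fn,
    records: pd.DataFrame,
    subject_col: str,
    coef_name: str,
    se_multiple: float = 1.0,
) -> pd.DataFrame:
    """Refit excluding each subject in turn and flag influential subjects.

    ``fit_fn(records) -> fit`` must return an object with params/bse Series.
    A subject is flagged when its exclusion moves ``coef_name`` by more than
    ``se_multiple`` times the full-data standard error.  A refit failure is
    recorded for that subject, not fatal.
    """
    subjects = pd.unique(records[subject_col])
    if len(subjects) < 3:
        raise ValueError("leave-one-out stability needs at least three subjects")
    full = fit_fn(records)
    est_full = float(full.params[coef_name])
    se_full = float(full.bse[coef_name])
    rows = []
    for subject in subjects:
        subset = records[records[subject_col] != subject]
        try:
            fit = fit_fn(subset)
            est = float(fit.params[coef_name])
            delta = est - est_full
            rows.append(
                {
                    "excluded": subject,
                    "estimate": est,
                    "delta": delta,
                    "flagged": bool(abs(delta) > se_multiple * se_full + 1e-10),
                    "error": "",
                }
            )
        except Exception as exc:  # refit failure is diagnostic, not fatal
            rows.append(
                {
                    "excluded": subject,
                    "estimate": np.nan,
                    "delta": np.nan,
                    "flagged": False,
                    "error": str(exc),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["full_estimate"] = est_full
    out.attrs["full_se"] = se_full
    return out
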