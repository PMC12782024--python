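"""Signed-difference regressors and regional grey-matter association.

For each sound condition, the regressor of interest is the signed
difference

    delta(i, c) = mean bisection point of controls for condition c
                  minus patient i's bisection point for c

so a positive delta means the patient's curve sits left of the control
average (duration overestimation relative to controls).  Per region, a
linear model

    volume ~ delta + diagnosis (5-level factor) + age + tiv + mmse

is fitted over the combined patient cohort and the delta slope tested.
Family-wise error across the pre-specified region-of-interest family is
controlled either by max-|t| permutation (permuting delta within
diagnosis strata, since diagnosis is in the model) or Bonferroni.

Direction bookkeeping follows the sign convention of the regressor: when
the overall (cohort-mean) delta for a condition is positive, an inverse
(negative) volume–delta correlation indicates regional atrophy; when the
overall sign is negative, a direct (positive) correlation does.

A synthetic-voxel mode is provided in which each region contributes a
grid of voxels; there the cluster-forming threshold (p < 0.001
uncorrected) is applied before peak-level max-|t| FWE correction within
the region family, mirroring voxel-wise morphometry at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .cohort import DEFAULT_ROI_FAMILY

__all__ = [
    "build_signed_differences",
    "fit_roi_glm",
    "fwe_correct",
    "run_association",
]

CLUSTER_FORMING_P = 0.001  # uncorrected threshold of the voxel mode
MIN_PERMUTATIONS = 10
WARN_PERMUTATIONS = 100


class ConditionError(ValueError):
    """Raised when a condition lacks valid control bisection points."""


def build_signed_differences(
    metrics: pd.DataFrame, control_label: str = "controls"
) -> pd.DataFrame:
    """Signed-difference table: control mean bp minus each patient's bp.

    ``metrics`` is the participant x condition table from
    ``psychometrics.participant_metrics`` (columns ``participant_id, group,
    semantic_category, valence, bp, fit_ok``).  Only rows with ``fit_ok``
    enter the control means; patients with a valid bp get one delta per
    condition.  The per-condition control mean and the overall sign of the
    patient deltas are carried along for direction bookkeeping.
    """
    m = metrics.copy()
    m["condition"] = m["semantic_category"] + "-" + m["valence"]
    ok = m[m["fit_ok"].astype(bool) & np.isfinite(m["bp"])]
    controls = ok[ok["group"] == control_label]
    patients = ok[ok["group"] != control_label]
    rows = []
    for cond, sub in patients.groupby("condition"):
        ctl = controls[controls["condition"] == cond]["bp"]
        if len(ctl) == 0:
            raise ConditionError(
                f"no valid control bisection points for condition {cond!r}"
            )
        ctl_mean = float(ctl.mean())
        for _, r in sub.iterrows():
            rows.append(
                {
                    "participant_id": r["participant_id"],
                    "group": r["group"],
                    "condition": cond,
                    "control_mean_bp": ctl_mean,
                    "patient_bp": float(r["bp"]),
                    "delta": ctl_mean - float(r["bp"]),
                }
            )
    out = pd.DataFrame(rows)
    signs = out.groupby("condition")["delta"].mean().rename("overall_mean_delta")
    return out.merge(signs, on="condition")


def _design(
    roi: pd.DataFrame, deltas: pd.DataFrame, condition: str, regions
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    d = deltas[deltas["condition"] == condition][["participant_id", "delta"]]
    merged = roi.merge(d, on="participant_id", how="inner").dropna(
        subset=["age", "tiv", "mmse", "delta"]
    )
    if len(merged) < 10:
        raise ValueError(
            f"only {len(merged)} complete patient rows for condition {condition!r}"
        )
    groups = sorted(merged["group"].unique())
    dummies = np.column_stack(
        [(merged["group"] == g).to_numpy(float) for g in groups[1:]]
    ) if len(groups) > 1 else np.empty((len(merged), 0))
    X = np.column_stack(
        [
            np.ones(len(merged)),
            merged["delta"].to_numpy(float),
            dummies,
            merged[["age", "tiv", "mmse"]].to_numpy(float),
        ]
    )
    names = ["intercept", "delta", *[f"group[{g}]" for g in groups[1:]],
             "age", "tiv", "mmse"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify aliased columns by checking rank without each one
        aliased = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1))
            == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    Y = merged[list(regions)].to_numpy(float)
    return X, Y, merged["delta"].to_numpy(float), names, merged


def _delta_tstats(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS slope and t statistic of the delta column for every region."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # p x R
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(XtX_inv[1, 1] * sigma2)
    return beta[1], beta[1] / se, dof


def fit_roi_glm(
    roi: pd.DataFrame,
    deltas: pd.DataFrame,
    condition: str,
    regions: tuple[str, ...] = DEFAULT_ROI_FAMILY,
) -> pd.DataFrame:
    """Per-region GLM of volume on the condition's signed difference.

    Returns one row per region: ``slope``, ``t``, ``p_raw`` (two-sided),
    and ``atrophy_direction`` — True when the slope's sign is the one that
    indicates atrophy given the overall sign of the deltas.
    """
    X, Y, delta, _, merged = _design(roi, deltas, condition, regions)
    slope, t, dof = _delta_tstats(X, Y)
    p_raw = 2 * stats.t.sf(np.abs(t), dof)
    overall = float(delta.mean())
    atrophy = slope * overall < 0  # inverse correlation when overall sign positive
    return pd.DataFrame(
        {
            "region": regions,
            "condition": condition,
            "slope": slope,
            "t": t,
            "dof": dof,
            "p_raw": p_raw,
            "overall_mean_delta": overall,
            "atrophy_direction": atrophy,
        }
    )


def fwe_correct(
    assoc: pd.DataFrame,
    method: str = "permutation_maxT",
    n_perm: int = 2000,
    seed: int = 0,
    roi: pd.DataFrame | None = None,
    deltas: pd.DataFrame | None = None,
    stratify: bool = True,
) -> pd.DataFrame:
    """Family-wise-error-adjusted p values for a region family.

    ``bonferroni`` multiplies raw p by the family size (capped at 1).
    ``permutation_maxT`` re-fits the GLM under ``n_perm`` permutations of
    the delta regressor — within diagnosis strata by default, because
    diagnosis is in the model — and refers each observed |t| to the null
    distribution of the familywise max |t|.  Adjusted p values are floored
    at the raw p so the family adjustment can only be more conservative.
    """
    out = assoc.copy()
    m = len(out)
    if m < 1:
        raise ValueError("empty association family")
    if method == "bonferroni":
        out["p_fwe"] = np.minimum(out["p_raw"] * m, 1.0)
        return out
    if method != "permutation_maxT":
        raise ValueError(f"unknown FWE method {method!r}")
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm={n_perm} < {MIN_PERMUTATIONS}")
    if n_perm < WARN_PERMUTATIONS:
        warnings.warn(f"n_perm={n_perm} is low; adjusted p values will be coarse")
    if roi is None or deltas is None:
        raise ValueError("permutation_maxT needs the roi and deltas tables")
    if not stratify:
        warnings.warn(
            "unstratified permutation ignores the diagnosis factor in the model"
        )
    condition = out["condition"].iloc[0]
    regions = tuple(out["region"])
    X, Y, _, _, merged = _design(roi, deltas, condition, regions)
    t_obs = np.abs(out["t"].to_numpy(float))
    rng = substream(seed, f"fwe/{condition}")
    groups = merged["group"].to_numpy()
    strata = (
        [np.flatnonzero(groups == g) for g in np.unique(groups)]
        if stratify
        else [np.arange(len(merged))]
    )
    max_t = np.empty(n_perm)
    Xp = X.copy()
    for b in range(n_perm):
        col = X[:, 1].copy()
        for idx in strata:
            col[idx] = col[rng.permutation(idx)]
        Xp[:, 1] = col
        _, t_b, _ = _delta_tstats(Xp, Y)
        max_t[b] = np.abs(t_b).max()
    exceed = (max_t[:, None] >= t_obs[None, :]).sum(axis=0)
    p_fwe = (1.0 + exceed) / (n_perm + 1.0)
    out["p_fwe"] = np.maximum(p_fwe, out["p_raw"])
    return out


def run_association(
    roi: pd.DataFrame,
    deltas: pd.DataFrame,
    condition: str,
    regions: tuple[str, ...] = DEFAULT_ROI_FAMILY,
    method: str = "permutation_maxT",
    n_perm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the per-region GLM and apply FWE correction in one call."""
    assoc = fit_roi_glm(roi, deltas, condition, regions)
    return fwe_correct(
        assoc, method=method, n_perm=n_perm, seed=seed, roi=roi, deltas=deltas
    )


def associate_voxelwise(
    voxels: pd.DataFrame,
    deltas: pd.DataFrame,
    condition: str,
    family: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic-voxel mode: cluster-forming threshold then peak-level FWE.

    ``voxels`` is laid out like the region table but with one column per
    voxel; ``family`` maps each region of interest to its voxel columns.
    Voxels surviving p < 0.001 uncorrected enter a peak-level max-|t|
    permutation test within the region's voxel family.  Returns one row
    per region with the peak voxel, its t and the peak-level adjusted p
    (NaN when no voxel survives the cluster-forming threshold).
    """
    all_cols = [c for cols in family.values() for c in cols]
    X, Y, _, _, merged = _design(voxels, deltas, condition, tuple(all_cols))
    _, t_all, dof = _delta_tstats(X, Y)
    p_unc = 2 * stats.t.sf(np.abs(t_all), dof)
    col_index = {c: j for j, c in enumerate(all_cols)}
    rng = substream(seed, f"voxel-fwe/{condition}")
    groups = merged["group"].to_numpy()
    strata = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    Xp = X.copy()
    max_t = np.empty((n_perm, len(family)))
    region_cols = {r: [col_index[c] for c in cols] for r, cols in family.items()}
    for b in range(n_perm):
        col = X[:, 1].copy()
        for idx in strata:
            col[idx] = col[rng.permutation(idx)]
        Xp[:, 1] = col
        _, t_b, _ = _delta_tstats(Xp, Y)
        for k, (r, cols) in enumerate(region_cols.items()):
            max_t[b, k] = np.abs(t_b[cols]).max()
    rows = []
    for k, (region, cols) in enumerate(region_cols.items()):
        t_r = t_all[cols]
        surviving = np.abs(t_r)[p_unc[cols] < CLUSTER_FORMING_P]
        if len(surviving) == 0:
            rows.append({"region": region, "condition": condition,
                         "peak_t": np.nan, "n_suprathreshold": 0, "p_fwe": np.nan})
            continue
        peak = float(np.abs(t_r).max())
        p_fwe = float((1.0 + (max_t[:, k] >= peak).sum()) / (n_perm + 1.0))
        rows.append({"region": region, "condition": condition,
                     "peak_t": peak, "n_suprathreshold": int(len(surviving)),
                     "p_fwe": p_fwe})
    return pd.DataFrame(rows)
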