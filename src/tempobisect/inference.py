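"""Group-level statistics: confound screening, linear mixed models on the
bisection point and log Weber's ratio, post hoc contrasts of estimated
marginal means, deviation scores and exploratory correlations.

The central model is a linear mixed model with diagnostic group, semantic
category and valence as fully crossed fixed effects (all two- and
three-way interactions) and a participant random intercept, fitted by
REML; effects are tested with Wald z statistics.  Post hoc comparisons
are pairwise z contrasts of estimated marginal means, averaging over the
factors not in the contrast with equal cell weights (balanced-design
convention); p values are reported raw by default, with an optional Holm
adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .design import REFERENCE_MEAN

__all__ = [
    "screen_confounders",
    "fit_mixed_model",
    "GroupModelResult",
    "ContrastResult",
    "posthoc_contrasts",
    "main_effect_contrast",
    "deviation_from_arithmetic_mean",
    "exploratory_correlations",
]

FACTORS = ("group", "semantic_category", "valence")
NORMALITY_ALPHA = 0.05  # Shapiro screen threshold (fixed, reproducible rule)


def screen_confounders(
    candidates: pd.DataFrame, group_col: str = "group", alpha: float = 0.05
) -> pd.DataFrame:
    """One-way group screens of candidate confounders.

    For each candidate column: one-way ANOVA when Levene's test and a
    Shapiro normality screen of the pooled residuals both pass, otherwise
    Kruskal–Wallis.  A candidate is flagged ``include_as_covariate`` when
    its p value falls below ``alpha``.  Constant candidates are reported as
    degenerate and not tested.
    """
    groups = candidates[group_col]
    labels = groups.unique()
    if len(labels) < 2 or any((groups == g).sum() < 2 for g in labels):
        raise ValueError("need >= 2 groups with >= 2 members each")
    rows = []
    for col in candidates.columns:
        if col == group_col:
            continue
        x = candidates[col]
        samples = [x[groups == g].dropna().to_numpy(float) for g in labels]
        samples = [s for s in samples if len(s) >= 2]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            rows.append(
                {"candidate": col, "test": "none", "statistic": np.nan,
                 "p": np.nan, "include_as_covariate": False, "degenerate": True}
            )
            continue
        lev_p = stats.levene(*samples).pvalue
        resid = np.concatenate([s - s.mean() for s in samples])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm_p = stats.shapiro(resid).pvalue if 3 <= len(resid) <= 5000 else 1.0
        if lev_p >= alpha and norm_p >= NORMALITY_ALPHA:
            test, res = "anova", stats.f_oneway(*samples)
        else:
            test, res = "kruskal", stats.kruskal(*samples)
        rows.append(
            {"candidate": col, "test": test,
             "statistic": float(res.statistic), "p": float(res.pvalue),
             "include_as_covariate": bool(res.pvalue < alpha), "degenerate": False}
        )
    return pd.DataFrame(rows)


@dataclass
class GroupModelResult:
    """Fixed effects, variance components and machinery for contrasts."""

    response: str
    fixed_effects: pd.DataFrame  # term, estimate, se, z, p
    random_intercept_var: float
    residual_var: float
    converged: bool
    message: str = ""
    # contrast machinery (not part of the reported summary)
    _params: np.ndarray = field(default=None, repr=False)
    _cov: np.ndarray = field(default=None, repr=False)
    _levels: dict = field(default=None, repr=False)
    _cell_design: pd.DataFrame = field(default=None, repr=False)


def _cell_design_matrix(levels: dict[str, list]) -> pd.DataFrame:
    """Fixed-effect design rows for every factor cell (treatment coding,
    matching the patsy formula ``C(group)*C(semantic_category)*C(valence)``)."""
    cells = list(itertools.product(*(levels[f] for f in FACTORS)))
    df = pd.DataFrame(cells, columns=list(FACTORS))
    df["y"] = 0.0
    from patsy import dmatrix

    X = dmatrix(
        "C(group) * C(semantic_category) * C(valence)", df, return_type="dataframe"
    )
    X.index = pd.MultiIndex.from_frame(df[list(FACTORS)])
    return X


def fit_mixed_model(data: pd.DataFrame, response: str) -> GroupModelResult:
    """REML linear mixed model: full-factorial fixed effects of group,
    semantic category and valence; participant random intercept; Wald z.

    ``data`` is a long table with one row per participant x condition and
    columns ``participant_id, group, semantic_category, valence`` plus the
    response (``bp`` or ``log_wr``).  Rows with missing response are
    dropped (listwise exclusion happens upstream).  Non-convergence is
    flagged, never silently replaced by a fallback.
    """
    needed = {"participant_id", *FACTORS, response}
    missing = needed - set(data.columns)
    if missing:
        raise ValueError(f"long table missing columns {sorted(missing)}")
    d = data.dropna(subset=[response]).copy()
    counts = d.groupby("group")["participant_id"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        return GroupModelResult(
            response, pd.DataFrame(), np.nan, np.nan, False,
            f"groups with < 2 participants: {bad}",
        )
    formula = f"{response} ~ C(group) * C(semantic_category) * C(valence)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, d, groups=d["participant_id"])
        try:
            fit = model.fit(reml=True)
        except Exception:
            try:  # fall back to a gradient-free optimizer on hard surfaces
                fit = model.fit(reml=True, method="powell")
            except Exception as exc:
                return GroupModelResult(
                    response, pd.DataFrame(), np.nan, np.nan, False, str(exc)
                )
    k = model.k_fe
    params = np.asarray(fit.params)[:k]
    cov = np.asarray(fit.cov_params())[:k, :k]
    se = np.sqrt(np.diag(cov))
    z = params / se
    p = 2 * stats.norm.sf(np.abs(z))
    fixed = pd.DataFrame(
        {"term": model.exog_names, "estimate": params, "se": se, "z": z, "p": p}
    )
    levels = {f: sorted(d[f].unique()) for f in FACTORS}
    converged = bool(fit.converged and np.all(np.isfinite(se)))
    return GroupModelResult(
        response,
        fixed,
        float(fit.cov_re.iloc[0, 0]),
        float(fit.scale),
        converged,
        "" if converged else "mixed model did not converge",
        _params=params,
        _cov=cov,
        _levels=levels,
        _cell_design=_cell_design_matrix(levels),
    )


@dataclass
class ContrastResult:
    description: str
    estimate: float
    z: float
    p: float


def _emm_rows(model: GroupModelResult, margin: tuple[str, ...]) -> pd.DataFrame:
    """Estimated-marginal-mean contrast rows: one row of L per margin cell,
    averaging the cell design over the factors not in ``margin`` with equal
    weights."""
    X = model._cell_design
    frame = X.index.to_frame(index=False)
    keys = list(margin)
    L = {}
    for cell, idx in frame.groupby(keys).groups.items():
        L[cell] = X.to_numpy()[np.asarray(idx)].mean(axis=0)
    return pd.DataFrame(L).T


def _contrast(model: GroupModelResult, l: np.ndarray, description: str) -> ContrastResult:
    est = float(l @ model._params)
    var = float(l @ model._cov @ l)
    if var <= 0:
        return ContrastResult(description, est, 0.0, 1.0)
    z = est / np.sqrt(var)
    return ContrastResult(description, est, z, float(2 * stats.norm.sf(abs(z))))


def main_effect_contrast(model: GroupModelResult, factor: str) -> ContrastResult:
    """z test of the two-level main effect (EMM difference) of a factor;
    for ``group`` use :func:`posthoc_contrasts` instead."""
    if not model.converged:
        raise ValueError("model did not converge")
    rows = _emm_rows(model, (factor,))
    levels = list(rows.index)
    if len(levels) != 2:
        raise ValueError(f"factor {factor} is not two-level; levels={levels}")
    l = rows.loc[levels[1]].to_numpy() - rows.loc[levels[0]].to_numpy()
    return _contrast(model, l, f"{factor}: {levels[1]} - {levels[0]}")


def posthoc_contrasts(
    model: GroupModelResult,
    family: str,
    holm: bool = False,
) -> list[ContrastResult]:
    """Pairwise z contrasts of estimated marginal means.

    Families: ``"category×diagnosis"`` (group pairs within each semantic
    category), ``"category×valence"`` (valence within category and category
    within valence), ``"diagnosis main"`` (group pairs averaged over
    conditions).  Raw p values by default; ``holm=True`` applies a Holm
    step-down adjustment within the family.
    """
    if not model.converged:
        raise ValueError("model did not converge")
    out: list[ContrastResult] = []
    if family == "diagnosis main":
        rows = _emm_rows(model, ("group",))
        for a, b in itertools.combinations(rows.index, 2):
            l = rows.loc[a].to_numpy() - rows.loc[b].to_numpy()
            out.append(_contrast(model, l, f"{a} - {b}"))
    elif family == "category×diagnosis":
        rows = _emm_rows(model, ("group", "semantic_category"))
        for cat in model._levels["semantic_category"]:
            sub = rows.loc[[i for i in rows.index if i[1] == cat]]
            for a, b in itertools.combinations(sub.index, 2):
                l = sub.loc[[a]].to_numpy()[0] - sub.loc[[b]].to_numpy()[0]
                out.append(_contrast(model, l, f"{a[0]} - {b[0]} | {cat}"))
    elif family == "category×valence":
        rows = _emm_rows(model, ("semantic_category", "valence"))
        for cat in model._levels["semantic_category"]:
            cells = [i for i in rows.index if i[0] == cat]
            for a, b in itertools.combinations(cells, 2):
                l = rows.loc[[a]].to_numpy()[0] - rows.loc[[b]].to_numpy()[0]
                out.append(_contrast(model, l, f"{cat}: {a[1]} - {b[1]}"))
        for val in model._levels["valence"]:
            cells = [i for i in rows.index if i[1] == val]
            for a, b in itertools.combinations(cells, 2):
                l = rows.loc[[a]].to_numpy()[0] - rows.loc[[b]].to_numpy()[0]
                out.append(_contrast(model, l, f"{val}: {a[0]} - {b[0]}"))
    else:
        raise ValueError(f"unknown contrast family {family!r}")
    if holm:
        ps = np.array([c.p for c in out])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(1.0, running)
        out = [
            ContrastResult(c.description, c.estimate, c.z, float(a))
            for c, a in zip(out, adj)
        ]
    return out


def deviation_from_arithmetic_mean(bp):
    """Deviation of a bisection point from the 3.5 s reference mean.

    Positive deviations indicate duration underestimation (the curve sits
    right of veridical), negative deviations overestimation.
    """
    return np.asarray(bp, dtype=float) - REFERENCE_MEAN if np.ndim(bp) else float(bp) - REFERENCE_MEAN


def exploratory_correlations(
    patient_means: pd.DataFrame,
    metric_cols: tuple[str, ...] = ("mean_bp", "mean_wr"),
    covariate_cols: tuple[str, ...] = ("digit_span_forward", "digit_span_reverse", "matrices", "mmse"),
) -> pd.DataFrame:
    """Correlations between condition-averaged bisection metrics and
    cognitive scores.

    Spearman rank correlation by default; Pearson when both marginals pass a
    Shapiro normality screen.  Pairs with fewer than 4 complete observations
    are skipped (logged in the output with method ``"skipped"``).
    """
    rows = []
    for m in metric_cols:
        for c in covariate_cols:
            if c not in patient_means.columns or m not in patient_means.columns:
                continue
            sub = patient_means[[m, c]].dropna()
            if len(sub) < 4:
                rows.append({"x": m, "y": c, "method": "skipped",
                             "coefficient": np.nan, "p": np.nan, "n": len(sub)})
                continue
            x, y = sub[m].to_numpy(float), sub[c].to_numpy(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal = (
                    np.ptp(x) > 0 and np.ptp(y) > 0
                    and stats.shapiro(x).pvalue >= NORMALITY_ALPHA
                    and stats.shapiro(y).pvalue >= NORMALITY_ALPHA
                )
                if normal:
                    method, res = "pearson", stats.pearsonr(x, y)
                else:
                    method, res = "spearman", stats.spearmanr(x, y)
            rows.append({"x": m, "y": c, "method": method,
                         "coefficient": float(res.statistic),
                         "p": float(res.pvalue), "n": len(sub)})
    return pd.DataFrame(rows)
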