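"""Cohort-level statistics: W-scores, partial correlations, ordinal PVS
models, group comparisons, FDR correction and the AD-continuum curve.

W-scores are covariate-adjusted normative deviations: a marker is
regressed on covariates in the reference (CN-) group and each
participant's deviation is the residual in units of the reference residual
SD.  For the ALPS index the sign is flipped (lower index = higher
abnormality) so all W-scored markers increase with pathology.

Partial correlations follow the residual definition: correlate OLS
residuals of x and y on the covariates, with a t-test on
``n - n_covariates - 2`` degrees of freedom.  The rank variant (for the
ordinal PVS grades) rank-transforms x and y only, leaving covariates
numeric.  Two covariate models are standard here: model 1 adjusts for age,
sex and TIV; model 2 additionally for APOE e4 carriage; cognition models
adjust for age, sex, education and APOE e4.

Ordinal outcomes use a proportional-odds cumulative-logit model
(maximum likelihood via statsmodels' OrderedModel; no random effects by
default — the synthetic single-cohort data has no site structure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import CubicSpline
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
    "COGNITION_COVARIATES",
    "MEDIATION_COVARIATES",
    "STAGE_ORDER",
    "WScoreModel",
    "PartialCorrResult",
    "OrdinalFit",
    "ContinuumCurve",
    "fit_wscore_model",
    "w_score",
    "partial_corr",
    "ordinal_fit",
    "fdr_adjust",
    "group_compare",
    "continuum_curve",
]

MODEL1_COVARIATES = ("age", "sex", "tiv")
MODEL2_COVARIATES = ("age", "sex", "tiv", "apoe4_carrier")
COGNITION_COVARIATES = ("age", "sex", "education", "apoe4_carrier")
MEDIATION_COVARIATES = ("age", "sex", "apoe4_carrier")

#: AD-continuum stage ordering used for the W-score curve axis.
STAGE_ORDER = ("CN-", "CN+", "MCI+", "AD+")


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(df))] + [np.asarray(df[c], dtype=float) for c in covariates]
    )
    return X


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and residuals; raises on rank deficiency."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear covariates?)")
    return coef, y - X @ coef


# -- W-scores ----------------------------------------------------------------


@dataclass
class WScoreModel:
    """Reference-group normative regression for one marker."""

    marker: str
    covariates: tuple[str, ...]
    coef: np.ndarray  # intercept first
    residual_sd: float
    sign_flip: bool
    n_reference: int
    degenerate: bool = False

    def predict(self, record) -> float:
        x = np.concatenate(([1.0], [float(record[c]) for c in self.covariates]))
        return float(x @ self.coef)


def fit_wscore_model(
    reference: pd.DataFrame,
    marker: str,
    covariates: Sequence[str] = MODEL1_COVARIATES,
    sign_flip: bool = False,
) -> WScoreModel:
    """Fit the normative model on reference (CN-) records only.

    The marker (negated when ``sign_flip``) is regressed on the covariates;
    the residual SD uses ``n - p - 1`` in the denominator.  A residual SD
    of (numerically) zero is flagged degenerate rather than silently kept.
    """
    n = len(reference)
    p = len(covariates)
    if n < p + 3:
        raise ValueError(
            f"need at least {p + 3} reference records for {p} covariates, got {n}"
        )
    y = np.asarray(reference[marker], dtype=float)
    if sign_flip:
        y = -y
    X = _design(reference, covariates)
    coef, resid = _ols(X, y)
    dof = n - p - 1
    residual_sd = float(np.sqrt((resid @ resid) / dof))
    degenerate = residual_sd < 1e-12 * max(1.0, float(np.abs(y).max()))
    return WScoreModel(
        marker=marker,
        covariates=tuple(covariates),
        coef=coef,
        residual_sd=residual_sd,
        sign_flip=sign_flip,
        n_reference=n,
        degenerate=degenerate,
    )


def w_score(model: WScoreModel, record) -> float:
    """Normative deviation of one record: (observed - predicted) / ref SD."""
    if model.degenerate:
        raise ValueError(
            f"W-score model for {model.marker!r} is degenerate (zero residual SD)"
        )
    obs = float(record[model.marker])
    if model.sign_flip:
        obs = -obs
    return (obs - model.predict(record)) / model.residual_sd


# -- partial correlation -----------------------------------------------------


@dataclass
class PartialCorrResult:
    x: str
    y: str
    r: float
    p: float
    n: int
    method: str
    covariates: tuple[str, ...]
    model: str = ""


def partial_corr(
    data: pd.DataFrame,
    x: str,
    y: str,
    covariates: Sequence[str] = (),
    method: str = "pearson",
    model: str = "",
) -> PartialCorrResult:
    """Covariate-adjusted correlation between two columns.

    ``method='pearson'`` correlates the OLS residuals of x and y on the
    covariates; ``method='spearman'`` rank-transforms x and y first
    (covariates stay numeric).  The p-value is two-sided from a
    t-distribution with ``n - len(covariates) - 2`` degrees of freedom.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    cols = [x, y, *covariates]
    sub = data[cols].dropna()
    n = len(sub)
    k = len(covariates)
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} complete cases, got {n}")
    xv = np.asarray(sub[x], dtype=float)
    yv = np.asarray(sub[y], dtype=float)
    if method == "spearman":
        xv = sps.rankdata(xv)
        yv = sps.rankdata(yv)
    X = _design(sub, covariates)
    _, rx = _ols(X, xv)
    _, ry = _ols(X, yv)
    sx = float(np.sqrt(rx @ rx))
    sy = float(np.sqrt(ry @ ry))
    tol_x = 1e-10 * max(1.0, float(np.abs(xv).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(yv).max()))
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero-variance residuals; partial correlation undefined")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    dof = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrResult(
        x=x, y=y, r=r, p=p, n=n, method=method, covariates=tuple(covariates), model=model
    )


# -- ordinal regression ------------------------------------------------------


@dataclass
class OrdinalFit:
    outcome: str
    cutpoints: np.ndarray
    coef: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    converged: bool
    n: int
    model: str = ""


def ordinal_fit(
    data: pd.DataFrame,
    outcome: str,
    exposures: Sequence[str],
    covariates: Sequence[str] = (),
    model: str = "",
) -> OrdinalFit:
    """Proportional-odds cumulative-logit fit of an ordinal grade.

    Reports slope, SE and Wald p per exposure/covariate.  Degenerate
    outcomes (a single observed grade) raise; non-convergence and
    (near-)separation are flagged on the result, not silenced.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    predictors = [*exposures, *covariates]
    sub = data[[outcome, *predictors]].dropna()
    grades = np.asarray(sub[outcome])
    if len(np.unique(grades)) < 2:
        raise ValueError(f"outcome {outcome!r} has fewer than 2 observed grades")
    endog = pd.Categorical(grades, ordered=True)
    exog = sub[predictors].astype(float)
    mod = OrderedModel(endog, exog, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mod.fit(method="bfgs", maxiter=500, disp=False)
    converged = bool(res.mle_retvals.get("converged", False))
    params = res.params
    bse = res.bse
    pvals = res.pvalues
    coef = {name: float(params[name]) for name in predictors}
    se = {name: float(bse[name]) for name in predictors}
    p = {name: float(pvals[name]) for name in predictors}
    n_cut = len(endog.categories) - 1
    # statsmodels parameterizes thresholds as first cutpoint + log-increments
    raw = np.asarray(params[len(predictors):])
    cutpoints = np.concatenate(([raw[0]], raw[0] + np.cumsum(np.exp(raw[1:n_cut]))))
    if not np.all(np.isfinite(list(coef.values()))):
        converged = False
    return OrdinalFit(
        outcome=outcome,
        cutpoints=cutpoints,
        coef=coef,
        se=se,
        pvalues=p,
        converged=converged,
        n=len(sub),
        model=model,
    )


# -- multiple-comparison correction ------------------------------------------


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- demographics ------------------------------------------------------------


def group_compare(
    cohort: pd.DataFrame,
    group_col: str = "group",
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-group summaries with one-way ANOVA / chi-square p-values.

    Continuous fields report mean +- SD per group and the ANOVA p;
    categorical fields report counts (%) and the chi-square p.
    """
    groups = [g for g in STAGE_ORDER if g in set(cohort[group_col])]
    if len(groups) < 2:
        groups = sorted(set(cohort[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    for g in groups:
        if (cohort[group_col] == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    rows = []
    for var in continuous:
        samples = [
            np.asarray(cohort.loc[cohort[group_col] == g, var].dropna(), dtype=float)
            for g in groups
        ]
        stat, p = sps.f_oneway(*samples)
        row = {"variable": var, "kind": "continuous", "statistic": float(stat), "p": float(p)}
        for g, s in zip(groups, samples):
            row[g] = f"{s.mean():.3f} ± {s.std(ddof=1):.3f}"
        rows.append(row)
    for var in categorical:
        table = pd.crosstab(cohort[group_col], cohort[var])
        table = table.reindex(groups)
        if table.to_numpy().sum(axis=0).min() == 0 or table.shape[1] < 2:
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = sps.chi2_contingency(table.to_numpy())
        row = {"variable": var, "kind": "categorical", "statistic": float(stat), "p": float(p)}
        for g in groups:
            counts = table.loc[g]
            total = counts.sum()
            pos = counts.drop(0, errors="ignore").sum()
            row[g] = f"{int(pos)} ({100 * pos / max(total, 1):.1f}%)"
        rows.append(row)
    return pd.DataFrame(rows)


# -- continuum curve ---------------------------------------------------------


@dataclass
class ContinuumCurve:
    """Smooth W-score trajectory over the ordered AD-continuum stages."""

    stages: tuple[str, ...]
    stage_x: np.ndarray
    stage_means: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    method: str = "natural cubic spline through stage means"
    n_boot: int = 0
    seed: int = 0

    def value_at_stage(self, stage: str) -> float:
        return float(self.stage_means[self.stages.index(stage)])


def continuum_curve(
    w_scores: pd.Series | np.ndarray,
    stages: Sequence[str],
    stage_order: Sequence[str] = STAGE_ORDER,
    n_boot: int = 500,
    seed: int = 0,
    n_grid: int = 121,
) -> ContinuumCurve:
    """Fit the stage-wise W-score trajectory with a bootstrap band.

    Stages are placed on an ordered 0..K-1 axis; a natural cubic spline is
    drawn through the per-stage means (so fitted stage values equal the
    stage means exactly), with a pointwise percentile band from resampling
    within stages.  Requires at least 4 observations per stage.
    """
    w = np.asarray(w_scores, dtype=float)
    stages = np.asarray(stages)
    levels = [s for s in stage_order if s in set(stages)]
    if len(levels) < 2:
        raise ValueError("need at least 2 stages with data")
    samples = [w[stages == s] for s in levels]
    for lev, s in zip(levels, samples):
        if len(s) < 4:
            raise ValueError(f"need >= 4 observations per stage; stage {lev!r} has {len(s)}")
    x = np.arange(len(levels), dtype=float)
    means = np.array([s.mean() for s in samples])
    grid = np.linspace(x[0], x[-1], n_grid)

    def _fit(values: np.ndarray) -> np.ndarray:
        if len(x) >= 3:
            return CubicSpline(x, values, bc_type="natural")(grid)
        return np.interp(grid, x, values)

    fit = _fit(means)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_grid))
    for b in range(n_boot):
        bm = np.array([rng.choice(s, size=len(s), replace=True).mean() for s in samples])
        boots[b] = _fit(bm)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return ContinuumCurve(
        stages=tuple(levels),
        stage_x=x,
        stage_means=means,
        grid_x=grid,
        grid_y=fit,
        band_lo=lo,
        band_hi=hi,
        n_boot=n_boot,
        seed=seed,
    )
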