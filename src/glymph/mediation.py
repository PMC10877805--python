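"""Product-of-coefficients mediation with nonparametric bootstrap inference.

For exposure x, mediator m, outcome y and covariates C, three OLS fits
give the decomposition

    a  : slope of x in  m ~ x + C
    b, c' : slopes of m and x in  y ~ x + m + C
    c  : slope of x in  y ~ x + C

with indirect effect a*b, direct effect c' and total effect c; for OLS the
identity c = c' + a*b holds exactly on any dataset.  Inference on the
indirect effect uses case-resampling bootstrap percentile intervals
(default 5000 replicates, 95%), with a proportion-based two-sided p-value
2*min(P(theta* <= 0), P(theta* >= 0)).  A bias-corrected-and-accelerated
(BCa) interval is available behind a flag.

Variables are z-scored before fitting by default so coefficients are on a
standardized (beta) scale.  Exposures enter one model at a time; the
battery runs every exposure x outcome cell for a mediator and applies
Benjamini-Hochberg FDR across the battery's indirect-effect p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import MEDIATION_COVARIATES, fdr_adjust

__all__ = ["MediationResult", "mediate", "mediation_battery"]


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    covariates: tuple[str, ...]
    a: float
    b: float
    indirect: float
    direct: float
    total: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_boot: int
    seed: int
    standardized: bool
    ci_method: str = "percentile"
    fdr_p: float | None = None

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "a": self.a,
            "b": self.b,
            "indirect": self.indirect,
            "direct": self.direct,
            "total": self.total,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "fdr_p": self.fdr_p,
            "n": self.n,
            "n_boot": self.n_boot,
        }


def _batched_slope(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, col: int, chunk: int = 1000
) -> np.ndarray:
    """Coefficient ``col`` of OLS(y ~ X) refit on each bootstrap index row."""
    B = idx.shape[0]
    out = np.empty(B)
    for start in range(0, B, chunk):
        sl = idx[start : start + chunk]
        Xb = X[sl]  # (b, n, k)
        yb = y[sl]  # (b, n)
        xtx = np.einsum("bni,bnj->bij", Xb, Xb)
        xty = np.einsum("bni,bn->bi", Xb, yb)
        try:
            coefs = np.linalg.solve(xtx, xty[..., None])[..., 0]
        except np.linalg.LinAlgError:
            coefs = np.stack(
                [np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(xtx, xty)]
            )
        out[start : start + chunk] = coefs[:, col]
    return out


def _fit_paths(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[float, float, float, float]:
    """Point estimates (a, b, c', c) by three OLS fits."""
    n = len(x)
    ones = np.ones((n, 1))
    Xa = np.hstack([ones, x[:, None], C])
    Xb = np.hstack([ones, x[:, None], m[:, None], C])
    for X, name in ((Xa, "m ~ x + C"), (Xb, "y ~ x + m + C")):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design in {name}")
    a = np.linalg.lstsq(Xa, m, rcond=None)[0][1]
    coefs_b = np.linalg.lstsq(Xb, y, rcond=None)[0]
    c_prime, b = coefs_b[1], coefs_b[2]
    c = np.linalg.lstsq(Xa, y, rcond=None)[0][1]
    return float(a), float(b), float(c_prime), float(c)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def mediate(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates: Sequence[str] = MEDIATION_COVARIATES,
    n_boot: int = 5000,
    seed: int = 0,
    standardize: bool = True,
    ci_method: str = "percentile",
) -> MediationResult:
    """Single-exposure mediation analysis with bootstrap CI on a*b.

    Complete cases only; deterministic given ``seed``.  ``ci_method`` is
    ``'percentile'`` (default) or ``'bca'``.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be at least 100, got {n_boot}")
    if ci_method not in ("percentile", "bca"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    cols = [exposure, mediator, outcome, *covariates]
    sub = data[cols].dropna()
    n = len(sub)
    if n < len(covariates) + 4:
        raise ValueError(f"need at least {len(covariates) + 4} complete cases, got {n}")

    x = np.asarray(sub[exposure], dtype=float)
    m = np.asarray(sub[mediator], dtype=float)
    y = np.asarray(sub[outcome], dtype=float)
    C = np.column_stack([np.asarray(sub[c], dtype=float) for c in covariates]) if covariates else np.empty((n, 0))
    if standardize:
        x, m, y = _zscore(x), _zscore(m), _zscore(y)

    a, b, c_prime, c = _fit_paths(x, m, y, C)
    indirect = a * b

    ones = np.ones((n, 1))
    Xa = np.hstack([ones, x[:, None], C])
    Xb = np.hstack([ones, x[:, None], m[:, None], C])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a_star = _batched_slope(Xa, m, idx, col=1)
    b_star = _batched_slope(Xb, y, idx, col=2)
    ind_star = a_star * b_star

    if ci_method == "percentile":
        ci_low, ci_high = np.percentile(ind_star, [2.5, 97.5])
    else:
        ci_low, ci_high = _bca_interval(ind_star, indirect, x, m, y, C)

    p_low = float(np.mean(ind_star <= 0.0))
    p_high = float(np.mean(ind_star >= 0.0))
    p = min(1.0, 2.0 * min(p_low, p_high))

    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        covariates=tuple(covariates),
        a=a,
        b=b,
        indirect=indirect,
        direct=c_prime,
        total=c,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=p,
        n=n,
        n_boot=n_boot,
        seed=seed,
        standardized=standardize,
        ci_method=ci_method,
    )


def _bca_interval(
    ind_star: np.ndarray,
    theta_hat: float,
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated interval (jackknife acceleration)."""
    from scipy.stats import norm

    n = len(x)
    prop = np.clip(np.mean(ind_star < theta_hat), 1e-10, 1 - 1e-10)
    z0 = norm.ppf(prop)
    jack = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        a_i, b_i, _, _ = _fit_paths(x[keep], m[keep], y[keep], C[keep])
        jack[i] = a_i * b_i
        keep[i] = True
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * (np.sum((jm - jack) ** 2) ** 1.5)
    acc = 0.0 if den == 0 else num / den
    lo_z, hi_z = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    q = [
        norm.cdf(z0 + (z0 + zq) / (1 - acc * (z0 + zq))) for zq in (lo_z, hi_z)
    ]
    lo, hi = np.percentile(ind_star, [100 * q[0], 100 * q[1]])
    return float(lo), float(hi)


def mediation_battery(
    cohort: pd.DataFrame,
    exposures: Sequence[str] = ("wmh_burden", "suvr"),
    mediators: Sequence[str] = ("alps", "choroid_norm"),
    outcomes: Sequence[str] = ("memory", "executive", "visuospatial", "language"),
    covariates: Sequence[str] = MEDIATION_COVARIATES,
    n_boot: int = 5000,
    seed: int = 0,
    standardize: bool = True,
) -> list[MediationResult]:
    """Run every exposure x outcome cell per mediator, FDR per mediator.

    Benjamini-Hochberg adjustment is applied to the indirect-effect
    p-values within each mediator's battery (2 exposures x 4 outcomes = 8
    cells by default), matching how batteries of mediation models are
    reported.  Per-cell seeds are derived deterministically from ``seed``.
    """
    results: list[MediationResult] = []
    ss = np.random.SeedSequence(seed)
    cell_seeds = iter(ss.generate_state(len(mediators) * len(exposures) * len(outcomes)))
    for mediator in mediators:
        batch: list[MediationResult] = []
        for exposure in exposures:
            for outcome in outcomes:
                cell_seed = int(next(cell_seeds) % (2**31))
                try:
                    res = mediate(
                        cohort,
                        exposure,
                        mediator,
                        outcome,
                        covariates=covariates,
                        n_boot=n_boot,
                        seed=cell_seed,
                        standardize=standardize,
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"mediation cell ({exposure} -> {mediator} -> {outcome}): {exc}"
                    ) from exc
                batch.append(res)
        adjusted = fdr_adjust([r.p for r in batch])
        for res, fp in zip(batch, adjusted):
            res.fdr_p = float(fp)
        results.extend(batch)
    return results
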