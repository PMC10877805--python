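"""End-to-end cohort analysis: filtering, demographics, W-scores and the
continuum curve, marker/cognition association batteries, ordinal PVS
models, and the mediation battery.

``analyze_cohort`` consumes a cohort table (all markers precomputed or
synthetic) and writes the tidy report bundle; each stage is also usable on
its own.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import markers, stats
from .config import RunConfig
from .cohort import COG_DOMAINS
from .mediation import mediation_battery
from .stats import (
    COGNITION_COVARIATES,
    MODEL1_COVARIATES,
    MODEL2_COVARIATES,
    continuum_curve,
    fdr_adjust,
    fit_wscore_model,
    group_compare,
    ordinal_fit,
    partial_corr,
    w_score,
)

logger = logging.getLogger("glymph")

__all__ = ["analyze_cohort", "marker_association_table", "cognition_association_table"]

_MARKER_METHOD = {"alps": "pearson", "choroid_norm": "pearson"}
_PVS_OUTCOMES = ("bg_pvs_grade", "wm_pvs_grade")
_EXPOSURES = ("suvr", "wmh_burden")


def _model_covariates(model: int) -> tuple[str, ...]:
    return MODEL1_COVARIATES if model == 1 else MODEL2_COVARIATES


def marker_association_table(positives: pd.DataFrame, models=(1, 2)) -> pd.DataFrame:
    """Exposure-marker partial correlations under covariate models 1 and 2."""
    rows = []
    for model in models:
        covs = _model_covariates(model)
        for marker in ("alps", "choroid_norm"):
            for exposure in _EXPOSURES:
                res = partial_corr(
                    positives,
                    exposure,
                    marker,
                    covariates=covs,
                    method=_MARKER_METHOD[marker],
                    model=f"model{model}",
                )
                rows.append(
                    {
                        "model": f"model{model}",
                        "marker": marker,
                        "exposure": exposure,
                        "method": res.method,
                        "r": res.r,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)


def pvs_association_table(positives: pd.DataFrame, models=(1, 2)) -> pd.DataFrame:
    """Cumulative-logit PVS grade models per covariate model."""
    rows = []
    for model in models:
        covs = _model_covariates(model)
        for outcome in _PVS_OUTCOMES:
            fit = ordinal_fit(
                positives, outcome, exposures=_EXPOSURES, covariates=covs, model=f"model{model}"
            )
            for exposure in _EXPOSURES:
                rows.append(
                    {
                        "model": f"model{model}",
                        "outcome": outcome,
                        "exposure": exposure,
                        "beta": fit.coef[exposure],
                        "se": fit.se[exposure],
                        "p": fit.pvalues[exposure],
                        "converged": fit.converged,
                        "n": fit.n,
                    }
                )
    return pd.DataFrame(rows)


def cognition_association_table(positives: pd.DataFrame) -> pd.DataFrame:
    """Marker-cognition partial correlations with battery-wise FDR.

    Continuous markers use the product-moment method, ordinal PVS grades
    the rank method; FDR is applied across the 4 domains within each
    marker, mirroring a marker-wise corrected report.
    """
    marker_method = dict(_MARKER_METHOD)
    marker_method.update({"bg_pvs_grade": "spearman", "wm_pvs_grade": "spearman"})
    rows = []
    for marker, method in marker_method.items():
        batch = []
        for domain in COG_DOMAINS:
            res = partial_corr(
                positives, marker, domain, covariates=COGNITION_COVARIATES, method=method
            )
            batch.append(
                {
                    "marker": marker,
                    "domain": domain,
                    "method": method,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
        fdr = fdr_adjust([b["p"] for b in batch])
        for row, fp in zip(batch, fdr):
            row["fdr_p"] = float(fp)
        rows.extend(batch)
    return pd.DataFrame(rows)


def wscore_table(study: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """W-scores for SUVR, ALPS (sign-flipped) and choroid volume vs CN-."""
    reference = study[study["group"] == "CN-"]
    out = study[["id", "group"]].copy()
    for marker, flip in (("suvr", False), ("alps", True), ("choroid_norm", False)):
        model = fit_wscore_model(
            reference, marker, covariates=MODEL1_COVARIATES, sign_flip=flip
        )
        out[f"w_{marker}"] = [w_score(model, row) for _, row in study.iterrows()]
    return out


def analyze_cohort(study: pd.DataFrame, config: RunConfig, out_dir=None) -> dict:
    """Run the full statistical chain on a study table.

    Returns a dict of in-memory results; when ``out_dir`` is given, also
    writes the tidy TSV/JSON report bundle plus a manifest embedding the
    seed and configuration hash.
    """
    report = markers.filter_cohort(study, lenient=config.lenient_qc)
    kept = report.kept
    positives = kept[kept["group"] != "CN-"].copy()
    logger.info("cohort filtered: %s", report.group_counts)

    demographics = group_compare(
        kept,
        continuous=["age", "education", "tiv", "wmh_burden", "suvr", "choroid_norm", "alps"],
        categorical=["sex", "apoe4_carrier", *markers.VASCULAR_FLAGS],
    )
    marker_assoc = marker_association_table(positives)
    pvs_assoc = pvs_association_table(positives)
    cog_assoc = cognition_association_table(positives)
    med = mediation_battery(
        positives,
        n_boot=config.n_boot,
        seed=config.seed,
        standardize=config.standardize_mediation,
    )
    med_table = pd.DataFrame([r.to_row() for r in med])

    wtab = wscore_table(kept, config)
    curves = {}
    for marker in ("suvr", "alps", "choroid_norm"):
        curves[marker] = continuum_curve(
            wtab[f"w_{marker}"], wtab["group"], n_boot=500, seed=config.seed
        )

    results = {
        "filter_report": report,
        "demographics": demographics,
        "marker_associations": marker_assoc,
        "pvs_associations": pvs_assoc,
        "cognition_associations": cog_assoc,
        "mediation": med_table,
        "mediation_results": med,
        "w_scores": wtab,
        "continuum_curves": curves,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.write(out_dir)
        demographics.to_csv(out_dir / "demographics.tsv", sep="\t", index=False)
        marker_assoc.to_csv(out_dir / "marker_associations.tsv", sep="\t", index=False)
        pvs_assoc.to_csv(out_dir / "pvs_associations.tsv", sep="\t", index=False)
        cog_assoc.to_csv(out_dir / "cognition_associations.tsv", sep="\t", index=False)
        med_table.to_csv(out_dir / "mediation.tsv", sep="\t", index=False)
        wtab.to_csv(out_dir / "w_scores.tsv", sep="\t", index=False)
        curve_frames = []
        for marker, curve in curves.items():
            curve_frames.append(
                pd.DataFrame(
                    {
                        "marker": marker,
                        "x": curve.grid_x,
                        "fit": curve.grid_y,
                        "lo": curve.band_lo,
                        "hi": curve.band_hi,
                    }
                )
            )
        pd.concat(curve_frames, ignore_index=True).to_csv(
            out_dir / "continuum_curves.tsv", sep="\t", index=False
        )
        config.write_manifest(out_dir, extra={"stage": "analyze", "n_kept": len(kept)})
    return results
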