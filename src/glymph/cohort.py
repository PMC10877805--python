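"""Synthetic cohort generation from a linear-Gaussian structural model.

The generator emulates an amyloid-positive, multi-marker aging cohort: two
exposures (log WMH burden as the small-vessel-disease marker, global
amyloid SUVR), two continuous glymphatic markers (the DTI-ALPS index and
TIV-normalized choroid plexus volume), four cognitive composites
(memory, executive, visuospatial, language), two ordinal perivascular-space
grades, demographic covariates, and the QC fields the filtering rules
consume.

Model structure
---------------
Each continuous endogenous variable is

    value = loc + scale * (gamma . C_std + s * z)

where ``C_std`` holds standardized covariates (age, sex, education, APOE4,
TIV), ``gamma`` the covariate effects, ``z`` a unit-variance structured
score built from independent Gaussian shocks, and ``s = sqrt(1 - |gamma|^2)``
so the standardized variable has unit variance.  Effect sizes are injected
as covariate-adjusted (partial) correlations: the loading vectors of the
``z`` scores are back-solved analytically so that the residual correlation
of each targeted pair equals the requested value exactly.  Because the
``z`` scores are independent of all covariates, the injected values are
the population partial correlations under any adjustment set drawn from
the covariates, which is what the downstream estimators measure.

Ordinal PVS grades arise from a cumulative-logit latent model
(latent = beta_abeta * SUVR + beta_wmh * WMH + logistic noise, cut at three
increasing thresholds), matching the proportional-odds model fitted
downstream.  SUVR is mapped through a monotone transform onto a normal
truncated at the positivity cutoff (> 1.11) so the generated cohort is
amyloid-positive by construction; a separate generator produces the
amyloid-negative reference group used for W-score normalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr
from scipy.stats import truncnorm

__all__ = [
    "COG_DOMAINS",
    "ENDOGENOUS",
    "COHORT_COLUMNS",
    "SCHEMA_VERSION",
    "SemParams",
    "default_sem_params",
    "null_sem_params",
    "loading_matrix",
    "implied_residual_corr",
    "implied_mediation_effects",
    "generate_cohort",
    "generate_reference",
    "generate_study",
]

COG_DOMAINS = ("memory", "executive", "visuospatial", "language")
EXPOSURES = ("wmh_burden", "suvr")
MARKERS = ("alps", "choroid_norm")
ENDOGENOUS = EXPOSURES + MARKERS + COG_DOMAINS
COVARIATES = ("age", "sex", "education", "apoe4_carrier", "tiv")

SCHEMA_VERSION = "1"

COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "education",
    "apoe4_carrier",
    "tiv",
    "suvr",
    "wmh_volume",
    "wmh_burden",
    "choroid_mm3",
    "choroid_norm",
    "bg_pvs_grade",
    "wm_pvs_grade",
    "alps",
    "memory",
    "executive",
    "visuospatial",
    "language",
    "diagnosis",
    "fazekas",
    "gds",
    "acpc_angle_deg",
    "pet_dti_interval_months",
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "smoking",
    "heart_disease",
]

# Shock basis for the structured scores:
# [u_wmh, u_abeta, e_alps, e_choroid, e_memory, e_executive, e_visuospatial, e_language]
_N_SHOCKS = 8


def _default_cog(mem: float, exe: float, vis: float, lan: float) -> dict[str, float]:
    return {"memory": mem, "executive": exe, "visuospatial": vis, "language": lan}


def _zero_cog() -> dict[str, float]:
    return _default_cog(0.0, 0.0, 0.0, 0.0)


@dataclass
class SemParams:
    """Generative parameters for the synthetic cohort.

    Path-coefficient fields are covariate-adjusted correlations between the
    named variables (``a_*``: exposure -> marker; ``b_*``: marker ->
    cognition; ``c_*``: exposure -> cognition).  ``covariate_effects``
    gives standardized covariate slopes per endogenous variable; each
    variable's residual SD is then ``sqrt(1 - sum(slopes^2))`` so that
    standardized variables have unit implied variance.  ``pvs_thresholds``
    are the cumulative-logit cutpoints (strictly increasing) on the latent
    PVS severity scale.
    """

    n: int = 93
    n_reference: int = 40
    seed: int = 0

    # exposure -> marker adjusted correlations (age, sex, TIV, APOE4)
    a_wmh_alps: float = -0.458
    a_abeta_alps: float = -0.249
    a_wmh_choroid: float = 0.294
    a_abeta_choroid: float = 0.223

    # marker -> cognition adjusted correlations (age, sex, education, APOE4)
    b_alps_cog: dict[str, float] = field(
        default_factory=lambda: _default_cog(0.470, 0.358, 0.223, 0.419)
    )
    b_choroid_cog: dict[str, float] = field(
        default_factory=lambda: _default_cog(-0.315, -0.321, -0.233, -0.261)
    )

    # exposure -> cognition adjusted correlations (direct + mediated paths)
    c_wmh_cog: dict[str, float] = field(
        default_factory=lambda: _default_cog(-0.261, -0.220, -0.332, -0.207)
    )
    c_abeta_cog: dict[str, float] = field(
        default_factory=lambda: _default_cog(-0.481, -0.651, -0.200, -0.397)
    )

    # standardized covariate slopes per endogenous variable
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "wmh_burden": {"age": 0.40},
            "suvr": {"apoe4_carrier": 0.30},
            "alps": {"age": -0.25, "apoe4_carrier": -0.10},
            "choroid_norm": {"age": 0.20},
            "memory": {"age": -0.25, "apoe4_carrier": -0.15},
            "executive": {"age": -0.25, "apoe4_carrier": -0.15},
            "visuospatial": {"age": -0.25, "apoe4_carrier": -0.15},
            "language": {"age": -0.25, "apoe4_carrier": -0.15},
        }
    )

    # marker location/scale: (mean, SD) on the natural scale, pooled over
    # the amyloid-positive cohort
    marker_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "wmh_burden": (0.50, 0.65),
            "suvr": (1.35, 0.18),
            "alps": (1.30, 0.15),
            "choroid_norm": (1.06, 0.25),
            "memory": (0.0, 1.0),
            "executive": (0.0, 1.0),
            "visuospatial": (0.0, 1.0),
            "language": (0.0, 1.0),
        }
    )
    # (mean, SD) for the amyloid-negative reference group
    reference_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "wmh_burden": (-0.006, 0.505),
            "suvr": (1.024, 0.047),
            "alps": (1.355, 0.155),
            "choroid_norm": (1.085, 0.339),
            "memory": (0.5, 0.9),
            "executive": (0.5, 0.9),
            "visuospatial": (0.5, 0.9),
            "language": (0.5, 0.9),
        }
    )

    # cumulative-logit PVS model: slopes on the raw exposures and three
    # increasing latent cutpoints per region
    pvs_beta: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "bg": {"suvr": -1.212, "wmh_burden": 0.489},
            "wm": {"suvr": -0.754, "wmh_burden": -0.054},
        }
    )
    pvs_thresholds: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "bg": (-3.4, -1.4, 0.6),
            "wm": (-3.0, -1.0, 1.0),
        }
    )

    # covariate marginals
    age_mean: float = 75.0
    age_sd: float = 8.5
    education_mean: float = 16.0
    education_sd: float = 2.4
    tiv_mean: float = 1465.0
    tiv_sd: float = 160.0
    male_p: float = 0.38
    apoe4_p: float = 0.5

    amyloid_cutoff: float = 1.11
    # diagnosis mix of the amyloid-positive cohort (CN+, MCI+, AD+)
    diagnosis_counts: tuple[int, int, int] = (48, 26, 19)
    # vascular risk-factor prevalences
    vascular_p: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.45,
            "diabetes": 0.08,
            "hyperlipidemia": 0.48,
            "smoking": 0.17,
            "heart_disease": 0.12,
        }
    )

    # bootstrap replicate count consumed by downstream mediation analyses
    n_boot: int = 5000

    def __post_init__(self) -> None:
        if self.n < 0 or self.n_reference < 0:
            raise ValueError("n and n_reference must be non-negative")
        for region, cuts in self.pvs_thresholds.items():
            if not all(a < b for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"pvs_thresholds[{region!r}] must be strictly increasing")
        for var, effects in self.covariate_effects.items():
            norm2 = sum(v**2 for v in effects.values())
            if norm2 >= 1.0:
                raise ValueError(
                    f"covariate effects for {var!r} imply non-positive residual "
                    f"variance (sum of squares {norm2:.3f} >= 1)"
                )
        for scales in (self.marker_scales, self.reference_scales):
            for var, (_, sd) in scales.items():
                if sd <= 0:
                    raise ValueError(f"scale SD for {var!r} must be positive")
        # validates feasibility of the requested correlation structure
        loading_matrix(self)

    # -- residual structure -------------------------------------------------

    def residual_sd(self, var: str) -> float:
        """Residual SD of the standardized variable after covariate effects."""
        norm2 = sum(v**2 for v in self.covariate_effects.get(var, {}).values())
        return float(np.sqrt(1.0 - norm2))

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        import json

        # json round-trip turns tuples into YAML-safe lists
        data = json.loads(json.dumps(dataclasses.asdict(self)))
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SemParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("marker_scales", "reference_scales"):
            if key in data:
                data[key] = {k: tuple(v) for k, v in data[key].items()}
        if "pvs_thresholds" in data:
            data["pvs_thresholds"] = {
                k: tuple(v) for k, v in data["pvs_thresholds"].items()
            }
        if "diagnosis_counts" in data:
            data["diagnosis_counts"] = tuple(data["diagnosis_counts"])
        return cls(**data)


def default_sem_params(**overrides) -> SemParams:
    """The documented default generator configuration."""
    return dataclasses.replace(SemParams(), **overrides) if overrides else SemParams()


def null_sem_params(n: int = 93, seed: int = 0, **overrides) -> SemParams:
    """All path coefficients zero; covariate effects retained."""
    nulls = dict(
        n=n,
        seed=seed,
        a_wmh_alps=0.0,
        a_abeta_alps=0.0,
        a_wmh_choroid=0.0,
        a_abeta_choroid=0.0,
        b_alps_cog=_zero_cog(),
        b_choroid_cog=_zero_cog(),
        c_wmh_cog=_zero_cog(),
        c_abeta_cog=_zero_cog(),
        pvs_beta={"bg": {"suvr": 0.0, "wmh_burden": 0.0}, "wm": {"suvr": 0.0, "wmh_burden": 0.0}},
    )
    nulls.update(overrides)
    return default_sem_params(**nulls)


def loading_matrix(params: SemParams) -> dict[str, np.ndarray]:
    """Back-solve unit-norm shock loadings realizing the requested partial
    correlations.

    Each endogenous variable's structured score is a linear combination of
    eight independent shocks; pairwise residual correlations are dot
    products of the loading vectors.  Raises ``ValueError`` when the
    requested correlations are jointly infeasible (implied covariance not
    positive semi-definite).
    """

    def _unit_complete(vec: np.ndarray, slot: int, name: str) -> np.ndarray:
        resid = 1.0 - float(vec @ vec)
        if resid < -1e-10:
            raise ValueError(
                f"requested correlations for {name!r} imply covariance that is "
                "not positive semi-definite (loading norm exceeds 1)"
            )
        vec = vec.copy()
        vec[slot] = np.sqrt(max(resid, 0.0))
        return vec

    lam: dict[str, np.ndarray] = {}
    lam["wmh_burden"] = np.eye(_N_SHOCKS)[0]
    lam["suvr"] = np.eye(_N_SHOCKS)[1]

    v = np.zeros(_N_SHOCKS)
    v[0], v[1] = params.a_wmh_alps, params.a_abeta_alps
    lam["alps"] = _unit_complete(v, 2, "alps")

    v = np.zeros(_N_SHOCKS)
    v[0], v[1] = params.a_wmh_choroid, params.a_abeta_choroid
    lam["choroid_norm"] = _unit_complete(v, 3, "choroid_norm")

    l_alps = lam["alps"][2]
    l_chor = lam["choroid_norm"][3]
    for slot, dom in enumerate(COG_DOMAINS, start=4):
        v = np.zeros(_N_SHOCKS)
        v[0] = params.c_wmh_cog[dom]
        v[1] = params.c_abeta_cog[dom]
        if l_alps <= 1e-12 or l_chor <= 1e-12:
            # markers fully determined by exposures; marker->cognition targets
            # are then redundant with the exposure targets
            v[2] = 0.0
            v[3] = 0.0
        else:
            v[2] = (params.b_alps_cog[dom] - lam["alps"][:2] @ v[:2]) / l_alps
            v[3] = (params.b_choroid_cog[dom] - lam["choroid_norm"][:2] @ v[:2]) / l_chor
        lam[dom] = _unit_complete(v, slot, dom)
    return lam


def implied_residual_corr(params: SemParams) -> pd.DataFrame:
    """Population covariate-adjusted correlations among endogenous variables."""
    lam = loading_matrix(params)
    mat = np.array([lam[v] for v in ENDOGENOUS])
    corr = mat @ mat.T
    return pd.DataFrame(corr, index=list(ENDOGENOUS), columns=list(ENDOGENOUS))


def implied_mediation_effects(
    params: SemParams, exposure: str, mediator: str, outcome: str
) -> dict[str, float]:
    """Population standardized mediation decomposition implied by the model.

    Standardization is by total SD (covariate variance included), matching
    what a z-scored single-exposure mediation fit estimates.  Returns the
    a/b paths, indirect (a*b), direct (c') and total (c) effects.
    """
    corr = implied_residual_corr(params)
    r_xm = corr.loc[exposure, mediator]
    r_xy = corr.loc[exposure, outcome]
    r_my = corr.loc[mediator, outcome]
    s_x = params.residual_sd(exposure)
    s_m = params.residual_sd(mediator)
    s_y = params.residual_sd(outcome)
    denom = 1.0 - r_xm**2
    a = r_xm * s_m / s_x
    b = s_y * (r_my - r_xm * r_xy) / (s_m * denom)
    direct = s_y * (r_xy - r_xm * r_my) / (s_x * denom)
    total = s_y * r_xy / s_x
    return {
        "a": float(a),
        "b": float(b),
        "indirect": float(a * b),
        "direct": float(direct),
        "total": float(total),
    }


# -- sampling ----------------------------------------------------------------


def _standardized_covariates(params: SemParams, cov: pd.DataFrame) -> pd.DataFrame:
    def bern_std(x, p):
        return (x - p) / np.sqrt(p * (1 - p))

    return pd.DataFrame(
        {
            "age": (cov["age"] - params.age_mean) / params.age_sd,
            "sex": bern_std(cov["sex"], params.male_p),
            "education": (cov["education"] - params.education_mean) / params.education_sd,
            "apoe4_carrier": bern_std(cov["apoe4_carrier"], params.apoe4_p),
            "tiv": (cov["tiv"] - params.tiv_mean) / params.tiv_sd,
        }
    )


def _draw_covariates(params: SemParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(params.age_mean, params.age_sd, n),
            "sex": rng.binomial(1, params.male_p, n),
            "education": rng.normal(params.education_mean, params.education_sd, n),
            "apoe4_carrier": rng.binomial(1, params.apoe4_p, n),
            "tiv": rng.normal(params.tiv_mean, params.tiv_sd, n),
        }
    )


def _structured_scores(
    params: SemParams, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    lam = loading_matrix(params)
    shocks = rng.standard_normal((n, _N_SHOCKS))
    return {var: shocks @ lam[var] for var in ENDOGENOUS}


def _standardized_values(
    params: SemParams, cov_std: pd.DataFrame, scores: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    out = {}
    for var in ENDOGENOUS:
        effects = params.covariate_effects.get(var, {})
        systematic = np.zeros(len(cov_std))
        for cname in sorted(effects):
            slope = effects[cname]
            systematic = systematic + slope * cov_std[cname].to_numpy()
        out[var] = systematic + params.residual_sd(var) * scores[var]
    return out


def _truncated_suvr(
    z: np.ndarray, loc: float, scale: float, cutoff: float, above: bool
) -> np.ndarray:
    """Map unit-variance scores monotonically onto a truncated normal SUVR."""
    u = ndtr(z)
    if above:
        a, b = (cutoff - loc) / scale, np.inf
    else:
        a, b = -np.inf, (cutoff - loc) / scale
    # keep strictly inside the open interval to avoid infinite quantiles
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _qc_and_risk(
    params: SemParams, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {
        "gds": rng.integers(0, 5, n),
        "acpc_angle_deg": np.round(rng.uniform(0.0, 15.0, n), 1),
        "pet_dti_interval_months": np.round(rng.uniform(0.5, 11.5, n), 1),
    }
    # canonical flag order so draw order is independent of dict key order
    for flag in sorted(params.vascular_p):
        out[flag] = rng.binomial(1, params.vascular_p[flag], n)
    return out


def _pvs_grades(
    params: SemParams, wmh: np.ndarray, suvr: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    grades = {}
    n = len(wmh)
    for region in ("bg", "wm"):
        beta = params.pvs_beta[region]
        eta = beta["suvr"] * suvr + beta["wmh_burden"] * wmh
        latent = eta + rng.logistic(0.0, 1.0, n)
        cuts = np.asarray(params.pvs_thresholds[region])
        grades[f"{region}_pvs_grade"] = 1 + (latent[:, None] > cuts[None, :]).sum(axis=1)
    return grades


def _assemble(
    params: SemParams,
    cov: pd.DataFrame,
    values: dict[str, np.ndarray],
    scales: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    id_prefix: str,
    reference: bool,
) -> pd.DataFrame:
    n = len(cov)
    raw: dict[str, np.ndarray] = {}
    for var in ENDOGENOUS:
        loc, scale = scales[var]
        if var == "suvr":
            raw[var] = _truncated_suvr(
                values[var], loc, scale, params.amyloid_cutoff, above=not reference
            )
        else:
            raw[var] = loc + scale * values[var]

    df = pd.DataFrame(index=range(n))
    df["id"] = [f"{id_prefix}{i + 1:04d}" for i in range(n)]
    for c in COVARIATES:
        df[c] = cov[c].to_numpy()
    df["age"] = np.round(df["age"], 1)
    df["education"] = np.round(np.clip(df["education"], 6, 22), 1)
    df["tiv"] = np.round(df["tiv"], 1)
    df["suvr"] = np.round(raw["suvr"], 4)
    df["wmh_burden"] = raw["wmh_burden"]
    df["wmh_volume"] = 10.0 ** raw["wmh_burden"]
    df["choroid_norm"] = raw["choroid_norm"]
    df["choroid_mm3"] = raw["choroid_norm"] * df["tiv"]
    df["alps"] = raw["alps"]
    for dom in COG_DOMAINS:
        df[dom] = raw[dom]

    for key, arr in _pvs_grades(params, raw["wmh_burden"], raw["suvr"], rng).items():
        df[key] = arr

    if reference:
        df["diagnosis"] = "CN"
        df["fazekas"] = (raw["wmh_burden"] > np.median(raw["wmh_burden"])).astype(int)
    else:
        # label diagnoses by overall cognitive severity, preserving the
        # configured CN+/MCI+/AD+ mix
        severity = -np.mean([values[d] for d in COG_DOMAINS], axis=0)
        order = np.argsort(severity)  # ascending: least impaired first
        counts = np.asarray(params.diagnosis_counts, dtype=float)
        frac = counts / counts.sum()
        n_cn = int(round(frac[0] * n))
        n_mci = int(round(frac[1] * n))
        labels = np.empty(n, dtype=object)
        labels[order[:n_cn]] = "CN"
        labels[order[n_cn : n_cn + n_mci]] = "MCI"
        labels[order[n_cn + n_mci :]] = "dementia"
        df["diagnosis"] = labels
        z_wmh = values["wmh_burden"]
        df["fazekas"] = np.digitize(z_wmh, [-0.8, 0.3, 1.2])

    for key, arr in _qc_and_risk(params, n, rng).items():
        df[key] = arr

    return df[COHORT_COLUMNS]


def generate_cohort(params: SemParams) -> pd.DataFrame:
    """Generate the amyloid-positive analysis cohort (``params.n`` rows).

    Deterministic given ``params.seed``; ``n = 0`` yields an empty table
    with the full schema.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})
    cov = _draw_covariates(params, n, rng)
    cov_std = _standardized_covariates(params, cov)
    scores = _structured_scores(params, n, rng)
    values = _standardized_values(params, cov_std, scores)
    return _assemble(params, cov, values, params.marker_scales, rng, "POS", reference=False)


def generate_reference(params: SemParams) -> pd.DataFrame:
    """Generate the amyloid-negative, cognitively normal reference group.

    ``params.n_reference`` rows with CN diagnosis, SUVR below the
    positivity cutoff and mild (< 2) WMH severity grades, suitable as the
    normative sample for W-score models.
    """
    # offset stream so reference draws do not overlap the positive cohort's
    rng = np.random.default_rng((int(params.seed), 1))
    n = params.n_reference
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})
    cov = _draw_covariates(params, n, rng)
    cov_std = _standardized_covariates(params, cov)
    scores = _structured_scores(params, n, rng)
    values = _standardized_values(params, cov_std, scores)
    return _assemble(params, cov, values, params.reference_scales, rng, "REF", reference=True)


def generate_study(params: SemParams) -> pd.DataFrame:
    """Full study table: reference group followed by the positive cohort."""
    ref = generate_reference(params)
    pos = generate_cohort(params)
    if ref.empty:
        return pos
    if pos.empty:
        return ref
    return pd.concat([ref, pos], ignore_index=True)
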