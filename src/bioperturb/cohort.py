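"""Synthetic two-group cohort generator.

Emulates a 36 + 36 overweight-adolescent cohort in which each of ~25 blood
biochemical markers is log-normally distributed: log10 concentrations are
drawn multivariate normal with a group-specific correlation matrix, a
case-minus-control location shift per marker, and an additional monotone
shift per steatosis-severity grade for a subset of markers. Clinical
covariates (age, sex, BMI-for-age z, waist circumference) are drawn
independently except for an optional linear coupling of BMI-z into chosen
markers on the log scale, which reproduces the weak positive BMI
correlations of liver-associated markers seen in real panels.

The defaults in :func:`default_study_config` encode the study conditions
the package is designed around — positive case shifts for ALT, GGT, TGF-β,
triglycerides and AST, negative shifts for HO-1, alkaline phosphatase and
HDL-c, and grade trends for ALT and triglycerides — and are not meant to be
tweaked casually; :func:`null_study_config` is the matched no-effect
configuration used for calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panel import BiomarkerPanel


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations (non-PSD correlation, ...)."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class CovariateModel:
    """Group-wise distributions for the clinical covariates.

    Ages in years, waist in cm, BMI as a BMI-for-age z-score (the cohort is
    overweight by design, hence z-scores centred well above +1). ``bmi_grade_slope``
    adds a per-grade-step increment to case BMI-z; ``bmi_marker_coupling``
    maps marker name -> coupling coefficient lambda, adding
    lambda * sd_log10(marker) * standardized(BMI-z) to that marker's log10
    value, which induces Pearson rho ≈ lambda / sqrt(1 + lambda^2) between
    BMI-z and the marker on the log scale.
    """

    age_mean: tuple[float, float] = (12.5, 14.0)  # (control, case)
    age_sd: float = 2.0
    age_range: tuple[float, float] = (10.0, 19.0)
    sex_p_male: float = 0.5
    bmi_mean: tuple[float, float] = (2.0, 2.1)
    bmi_sd: float = 0.6
    bmi_grade_slope: float = 0.25
    waist_mean: tuple[float, float] = (90.0, 97.0)
    waist_sd: float = 9.0
    bmi_marker_coupling: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    All per-marker vectors are aligned with ``marker_names``. Effects and
    grade slopes are on the log10 scale (case minus control; additional
    shift per severity-grade step, applied as grade x slope).
    """

    n_control: int
    n_case: int
    grade_split: tuple[int, int]  # (mild, moderate/severe) cases
    marker_names: list[str]
    log10_means_control: np.ndarray
    log10_sds: np.ndarray
    effect_log10: np.ndarray
    grade_slope_log10: np.ndarray
    corr_control: np.ndarray
    corr_case: np.ndarray
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("log10_means_control", "log10_sds", "effect_log10",
                     "grade_slope_log10", "corr_control", "corr_case"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.grade_split = tuple(int(v) for v in self.grade_split)

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def validate(self) -> "CohortConfig":
        p = self.n_markers
        if len(set(self.marker_names)) != p:
            raise ConfigurationError("duplicate marker names")
        for name in ("log10_means_control", "log10_sds", "effect_log10",
                     "grade_slope_log10"):
            if getattr(self, name).shape != (p,):
                raise ConfigurationError(f"{name} must have length {p}")
        if np.any(self.log10_sds <= 0):
            raise ConfigurationError("all log10_sds must be > 0")
        if sum(self.grade_split) != self.n_case:
            raise ConfigurationError(
                f"grade_split {self.grade_split} does not sum to n_case={self.n_case}"
            )
        for label, mat in (("corr_control", self.corr_control),
                           ("corr_case", self.corr_case)):
            _check_correlation_matrix(mat, p, label)
        return self


def _check_correlation_matrix(mat: np.ndarray, p: int, label: str,
                              tol: float = 1e-8) -> None:
    if mat.shape != (p, p):
        raise ConfigurationError(f"{label} must be {p}x{p}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ConfigurationError(f"{label} is not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ConfigurationError(f"{label} must have unit diagonal")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol:
        raise ConfigurationError(
            f"{label} is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )


def nearest_psd(mat: np.ndarray) -> np.ndarray:
    """Nearest-PSD repair (eigenvalue clipping + rescale to unit diagonal).

    Applied only on explicit request; invalid matrices are otherwise rejected.
    """
    mat = np.asarray(mat, dtype=float)
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    fixed = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


# ---------------------------------------------------------------------------
# the study conditions
# ---------------------------------------------------------------------------

#: The 25 analysed blood parameters (native units in parentheses where the
#: defaults assume them): routine hepatic, lipid, glycemic, thyroid and
#: hematology panels plus the two ELISA markers TGF-β (pg/mL) and HO-1 (ng/mL).
STUDY_MARKERS = [
    "Glucose", "Insulin", "Homa-IR", "totC", "LDL-c", "HDL-c", "Triglycerides",
    "Urea", "Creatinine", "CRP", "AST", "ALT", "GGT", "Alkaline phosphatase",
    "Total bilirubin", "Direct bilirubin", "Vitamin D", "fT4", "TSH",
    "Ferritin", "Hemoglobin", "Hematocrit", "Albumin", "TGF-β", "HO-1",
]

# typical adolescent medians (native units) -> log10 location; spreads are
# log10 SDs chosen to match realistic biological coefficients of variation
# (tight for hematology/albumin/fT4, wide for CRP/ferritin/insulin/ELISA markers)
_LOG10_MEANS = {
    "Glucose": np.log10(85.0), "Insulin": np.log10(14.0), "Homa-IR": np.log10(3.0),
    "totC": np.log10(160.0), "LDL-c": np.log10(95.0), "HDL-c": np.log10(45.0),
    "Triglycerides": np.log10(100.0), "Urea": np.log10(25.0),
    "Creatinine": np.log10(0.6), "CRP": np.log10(1.5), "AST": np.log10(25.0),
    "ALT": np.log10(20.0), "GGT": np.log10(18.0),
    "Alkaline phosphatase": np.log10(210.0), "Total bilirubin": np.log10(0.5),
    "Direct bilirubin": np.log10(0.15), "Vitamin D": np.log10(26.0),
    "fT4": np.log10(1.2), "TSH": np.log10(2.1), "Ferritin": np.log10(50.0),
    "Hemoglobin": np.log10(13.5), "Hematocrit": np.log10(40.0),
    "Albumin": np.log10(4.4), "TGF-β": np.log10(25.0), "HO-1": np.log10(2.0),
}
_LOG10_SDS = {
    "Glucose": 0.04, "Insulin": 0.25, "Homa-IR": 0.28, "totC": 0.08,
    "LDL-c": 0.10, "HDL-c": 0.08, "Triglycerides": 0.14, "Urea": 0.10,
    "Creatinine": 0.07, "CRP": 0.40, "AST": 0.09, "ALT": 0.12, "GGT": 0.10,
    "Alkaline phosphatase": 0.12, "Total bilirubin": 0.18,
    "Direct bilirubin": 0.18, "Vitamin D": 0.12, "fT4": 0.05, "TSH": 0.22,
    "Ferritin": 0.28, "Hemoglobin": 0.04, "Hematocrit": 0.035,
    "Albumin": 0.03, "TGF-β": 0.25, "HO-1": 0.20,
}
# case-minus-control shifts on the log10 scale: up for the liver-injury and
# lipid markers, down for HO-1, alkaline phosphatase and HDL-c
_EFFECTS = {
    "ALT": 0.15, "GGT": 0.12, "TGF-β": 0.30, "Triglycerides": 0.10,
    "AST": 0.08, "HO-1": -0.12, "Alkaline phosphatase": -0.08, "HDL-c": -0.06,
}
# additional per-grade-step slope (severity trend) for markers that track grade
_GRADE_SLOPES = {"ALT": 0.08, "Triglycerides": 0.05}


def _factor_correlation(factors: list[dict[str, float]]) -> np.ndarray:
    """Correlation matrix from a loading model: corr = LL' + uniqueness.

    Guaranteed positive semidefinite for any loadings with row sums of
    squares <= 1 (asserted here).
    """
    p = len(STUDY_MARKERS)
    idx = {m: i for i, m in enumerate(STUDY_MARKERS)}
    L = np.zeros((p, len(factors)))
    for k, loading in enumerate(factors):
        for marker, lam in loading.items():
            L[idx[marker], k] = lam
    communality = (L ** 2).sum(axis=1)
    assert communality.max() <= 1.0, "factor loadings overload a marker"
    corr = L @ L.T
    np.fill_diagonal(corr, 1.0)
    return corr


#: Shared physiological factors: cholesterol axis, triglyceride/metabolic
#: axis, insulin-resistance axis, liver-enzyme axis, erythroid axis,
#: bilirubin axis, inflammation axis.
_CONTROL_FACTORS: list[dict[str, float]] = [
    {"totC": 0.90, "LDL-c": 0.88, "HDL-c": 0.38},
    {"Triglycerides": 0.80, "HDL-c": -0.30, "LDL-c": 0.15, "totC": 0.15},
    {"Insulin": 0.95, "Homa-IR": 0.95, "Glucose": 0.45, "Triglycerides": 0.25},
    {"AST": 0.75, "ALT": 0.80, "GGT": 0.60, "Alkaline phosphatase": 0.30,
     "Triglycerides": 0.20},
    {"Hemoglobin": 0.93, "Hematocrit": 0.95},
    {"Total bilirubin": 0.85, "Direct bilirubin": 0.82},
    {"CRP": 0.55, "Ferritin": 0.55},
]

#: Case-group factors: a tighter, broader liver axis that recruits
#: triglycerides, TGF-β and hemoglobin, and an fT4 node loading negatively
#: on the metabolic axes so all its correlations (Homa-IR, triglycerides,
#: LDL-c, GGT, ...) are negative.
_CASE_FACTORS: list[dict[str, float]] = [
    {"totC": 0.90, "LDL-c": 0.88, "HDL-c": 0.38, "fT4": -0.35},
    {"Triglycerides": 0.80, "HDL-c": -0.30, "LDL-c": 0.15, "totC": 0.15},
    {"Insulin": 0.95, "Homa-IR": 0.95, "Glucose": 0.45, "Triglycerides": 0.25,
     "fT4": -0.40},
    {"AST": 0.78, "ALT": 0.85, "GGT": 0.75, "Alkaline phosphatase": 0.25,
     "Triglycerides": 0.45, "TGF-β": 0.40, "Hemoglobin": 0.28, "fT4": -0.28},
    {"Hemoglobin": 0.90, "Hematocrit": 0.95},
    {"Total bilirubin": 0.85, "Direct bilirubin": 0.82},
    {"CRP": 0.55, "Ferritin": 0.55},
]


def _base_correlation() -> np.ndarray:
    """Physiological baseline correlation shared by both groups."""
    return _factor_correlation(_CONTROL_FACTORS)


def _case_correlation() -> np.ndarray:
    """Case-group correlation: denser network with liver/lipid cross-talk."""
    return _factor_correlation(_CASE_FACTORS)


def default_study_config(seed: int = 0) -> CohortConfig:
    """Configuration encoding the study conditions (36 + 36 cohort)."""
    means = np.array([_LOG10_MEANS[m] for m in STUDY_MARKERS])
    sds = np.array([_LOG10_SDS[m] for m in STUDY_MARKERS])
    eff = np.array([_EFFECTS.get(m, 0.0) for m in STUDY_MARKERS])
    slope = np.array([_GRADE_SLOPES.get(m, 0.0) for m in STUDY_MARKERS])
    cov = CovariateModel(bmi_marker_coupling={"TGF-β": 0.3, "ALT": 0.3})
    return CohortConfig(
        n_control=36, n_case=36, grade_split=(18, 18),
        marker_names=list(STUDY_MARKERS),
        log10_means_control=means, log10_sds=sds,
        effect_log10=eff, grade_slope_log10=slope,
        corr_control=_base_correlation(), corr_case=_case_correlation(),
        covariates=cov, seed=seed,
    ).validate()


def null_study_config(seed: int = 0) -> CohortConfig:
    """Matched no-effect configuration: zero shifts, shared correlation,
    identical covariate distributions in both groups. Case and control
    marker data are then identical in law — the calibration scenario."""
    cfg = default_study_config(seed=seed)
    cfg.effect_log10 = np.zeros(cfg.n_markers)
    cfg.grade_slope_log10 = np.zeros(cfg.n_markers)
    cfg.corr_case = cfg.corr_control.copy()
    cfg.covariates = CovariateModel(
        age_mean=(12.5, 12.5), bmi_mean=(2.0, 2.0), bmi_grade_slope=0.0,
        waist_mean=(90.0, 90.0),
        bmi_marker_coupling=dict(cfg.covariates.bmi_marker_coupling),
    )
    return cfg.validate()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _psd_factor(corr: np.ndarray, label: str) -> np.ndarray:
    """Square-root factor F with F F' = corr, tolerant of semidefiniteness."""
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-8:
        raise ConfigurationError(
            f"{label} is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_cohort(config: CohortConfig, seed: int | None = None) -> BiomarkerPanel:
    """Draw one cohort from ``config``.

    log10(markers) per group g is multivariate normal with mean
    ``log10_means_control + steatosis*effect_log10 + grade*grade_slope_log10``,
    per-marker SD ``log10_sds`` and correlation ``corr_g``; concentrations are
    10**draws, hence strictly positive. Identical config and seed reproduce
    the panel bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = config.n_markers
    cov = config.covariates

    steatosis = np.concatenate([
        np.zeros(config.n_control, dtype=int), np.ones(config.n_case, dtype=int)])
    grade = np.concatenate([
        np.zeros(config.n_control, dtype=int),
        np.ones(config.grade_split[0], dtype=int),
        np.full(config.grade_split[1], 2, dtype=int)])
    n = len(steatosis)

    # covariates first (fixed draw order keeps the stream deterministic)
    age = np.clip(
        rng.normal(np.where(steatosis == 0, cov.age_mean[0], cov.age_mean[1]),
                   cov.age_sd),
        *cov.age_range)
    sex = rng.binomial(1, cov.sex_p_male, size=n)
    bmi_mu = np.where(steatosis == 0, cov.bmi_mean[0], cov.bmi_mean[1]) \
        + cov.bmi_grade_slope * grade
    bmi_z = rng.normal(bmi_mu, cov.bmi_sd)
    waist = rng.normal(
        np.where(steatosis == 0, cov.waist_mean[0], cov.waist_mean[1]),
        cov.waist_sd)

    mu = (config.log10_means_control[None, :]
          + steatosis[:, None] * config.effect_log10[None, :]
          + grade[:, None] * config.grade_slope_log10[None, :])
    log10x = np.empty((n, p))
    for g, corr in ((0, config.corr_control), (1, config.corr_case)):
        mask = steatosis == g
        factor = _psd_factor(corr, "corr_control" if g == 0 else "corr_case")
        z = rng.standard_normal((mask.sum(), p)) @ factor.T
        log10x[mask] = mu[mask] + z * config.log10_sds[None, :]

    # BMI coupling on the log scale (zero-mean within group by construction)
    if cov.bmi_marker_coupling:
        bmi_std = (bmi_z - bmi_mu) / cov.bmi_sd
        for marker, lam in cov.bmi_marker_coupling.items():
            j = config.marker_names.index(marker)
            log10x[:, j] += lam * config.log10_sds[j] * bmi_std

    data = pd.DataFrame({
        "sample_id": [f"S{i + 1:03d}" for i in range(n)],
        "steatosis": steatosis, "grade": grade, "sex": sex,
        "age": np.round(age, 6), "bmi_z": np.round(bmi_z, 6),
        "waist": np.round(waist, 6),
    })
    markers = pd.DataFrame(np.power(10.0, log10x), columns=config.marker_names)
    panel = BiomarkerPanel(pd.concat([data, markers], axis=1),
                           list(config.marker_names))
    return panel.validate(allow_missing=False)


# ---------------------------------------------------------------------------
# YAML config round trip
# ---------------------------------------------------------------------------

def config_to_yaml(config: CohortConfig, path) -> None:
    d = dataclasses.asdict(config)
    for k, v in list(d.items()):
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    d["grade_split"] = list(config.grade_split)
    cov = d["covariates"]
    for k, v in list(cov.items()):
        if isinstance(v, tuple):
            cov[k] = list(v)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, allow_unicode=True, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    cov = d.pop("covariates", None)
    covariates = CovariateModel(**{
        k: tuple(v) if isinstance(v, list) and k != "bmi_marker_coupling" else v
        for k, v in cov.items()}) if cov else CovariateModel()
    return CohortConfig(covariates=covariates, **d).validate()
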