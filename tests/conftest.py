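import numpy as np
import pandas as pd
import pytest

from bioperturb import (
    BiomarkerPanel,
    CohortConfig,
    default_study_config,
    generate_cohort,
    null_study_config,
)


@pytest.fixture(scope="session")
def study_config():
    return default_study_config()


@pytest.fixture(scope="session")
def null_config():
    return null_study_config()


@pytest.fixture(scope="session")
def panel(study_config):
    return generate_cohort(study_config, seed=11)


@pytest.fixture(scope="session")
def null_panel(null_config):
    return generate_cohort(null_config, seed=12)


def single_marker_config(effect=0.0, sd=0.5, n=36, corr01=0.0, n_markers=2,
                         grade_slope=0.0):
    """Minimal custom cohort: n+n samples, independent covariates, no coupling."""
    from bioperturb import CovariateModel

    p = n_markers
    corr = np.eye(p)
    if p >= 2:
        corr[0, 1] = corr[1, 0] = corr01
    eff = np.zeros(p)
    eff[0] = effect
    slope = np.zeros(p)
    slope[0] = grade_slope
    return CohortConfig(
        n_control=n, n_case=n, grade_split=(n // 2, n - n // 2),
        marker_names=[f"M{i}" for i in range(p)],
        log10_means_control=np.full(p, 1.0),
        log10_sds=np.full(p, sd),
        effect_log10=eff, grade_slope_log10=slope,
        corr_control=corr.copy(), corr_case=corr.copy(),
        covariates=CovariateModel(age_mean=(12.0, 12.0), bmi_mean=(2.0, 2.0),
                                  bmi_grade_slope=0.0, waist_mean=(90.0, 90.0)),
    ).validate()


def toy_panel(markers: dict, steatosis, grade=None) -> BiomarkerPanel:
    """Hand-built tiny panel from marker value lists."""
    steatosis = list(steatosis)
    n = len(steatosis)
    if grade is None:
        grade = steatosis
    data = pd.DataFrame({
        "sample_id": [f"T{i}" for i in range(n)],
        "steatosis": steatosis, "grade": list(grade),
        "sex": [0] * n, "age": [12.0] * n, "bmi_z": [2.0] * n,
        "waist": [90.0] * n,
    })
    for name, vals in markers.items():
        data[name] = vals
    return BiomarkerPanel(data, list(markers)).validate()
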