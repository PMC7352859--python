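"""Degree of Biochemical Perturbation (DBP).

An adaptation of the transcriptomic molecular-degree-of-perturbation score
to a clinical biomarker panel: each marker value (on the log10 scale) is
expressed as its signed deviation from the reference (no-steatosis) group
mean in reference-SD units; a sample's DBP score is the mean absolute
deviation across markers. Samples whose score exceeds the reference mean
score by more than two reference SDs are classified biochemically
perturbed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import BiomarkerPanel
from .univariate import holm_adjust, mann_whitney

logger = logging.getLogger(__name__)


@dataclass
class DBPResult:
    reference_group: str
    z_matrix: pd.DataFrame          # samples x markers signed deviations
    sample_score: pd.Series         # per-sample mean |z|
    marker_group_score: pd.DataFrame  # markers x groups mean |z|
    steatosis: pd.Series
    perturbed: pd.Series | None = None
    threshold: float | None = None

    @property
    def reference_mask(self) -> np.ndarray:
        return (self.steatosis == 0).to_numpy()


def dbp_scores(panel: BiomarkerPanel, reference: int = 0,
               log_scale: bool = True, aggregate: str = "mean_abs") -> DBPResult:
    """Compute per-marker deviations and per-sample DBP scores.

    z[s, m] = (x[s, m] - mean_ref(m)) / sd_ref(m) on log10-transformed
    concentrations (``log_scale=False`` uses the native scale). The
    reference SD is the sample (n-1) SD of the reference group only.
    Markers with zero reference SD are excluded with a warning. The sample
    score aggregates |z| by mean (``aggregate="signed_mean"`` keeps signs).
    """
    if aggregate not in ("mean_abs", "signed_mean"):
        raise ValueError("aggregate must be 'mean_abs' or 'signed_mean'")
    ref_mask = (panel.steatosis == reference).to_numpy()
    if ref_mask.sum() < 3:
        raise ValueError("reference group needs >= 3 samples")
    values = panel.markers.astype(float)
    if log_scale:
        if (values <= 0).any().any():
            raise ValueError("non-positive concentrations; log10 undefined")
        values = np.log10(values)
    ref = values.loc[ref_mask]
    mean_ref = ref.mean()
    sd_ref = ref.std(ddof=1)
    usable = sd_ref > 0
    if not usable.any():
        raise ValueError("reference SD is zero for every marker")
    if (~usable).any():
        logger.warning("excluding zero-reference-SD markers: %s",
                       list(usable[~usable].index))
    cols = list(usable[usable].index)
    z = (values[cols] - mean_ref[cols]) / sd_ref[cols]
    if aggregate == "mean_abs":
        score = z.abs().mean(axis=1)
    else:
        score = z.mean(axis=1)
    groups = {"reference": ref_mask, "non_reference": ~ref_mask}
    marker_group = pd.DataFrame({
        g: z.loc[m].abs().mean() for g, m in groups.items()
    })
    return DBPResult(
        reference_group=str(reference), z_matrix=z, sample_score=score,
        marker_group_score=marker_group, steatosis=panel.steatosis.copy(),
    )


def classify_perturbed(result: DBPResult) -> DBPResult:
    """Flag samples with DBP score above reference mean + 2 reference SD."""
    ref_scores = result.sample_score[result.reference_mask]
    sd = float(ref_scores.std(ddof=1))
    mean = float(ref_scores.mean())
    if sd == 0:
        logger.warning("reference DBP scores are constant; threshold = mean")
        threshold = mean
    else:
        threshold = mean + 2.0 * sd
    result.threshold = threshold
    result.perturbed = result.sample_score > threshold
    return result


def dbp_fold_table(result: DBPResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-marker |z| fold between groups with Holm-adjusted Mann-Whitney p.

    fold = mean |z| in the non-reference group / mean |z| in the reference
    group; the Mann-Whitney test compares the |z| distributions and the
    Holm family spans all markers.
    """
    ref_mask = result.reference_mask
    absz = result.z_matrix.abs()
    records = []
    for m in absz.columns:
        x = absz.loc[~ref_mask, m].to_numpy()
        y = absz.loc[ref_mask, m].to_numpy()
        res = mann_whitney(x, y)
        ref_mean = float(y.mean())
        fold = float(x.mean() / ref_mean) if ref_mean > 0 else float("nan")
        records.append({"marker": m, "mean_abs_z_case": float(x.mean()),
                        "mean_abs_z_control": ref_mean, "fold": fold,
                        "p_raw": res.p_raw})
    df = pd.DataFrame.from_records(records)
    df["p_adjusted"] = holm_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    return df
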