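"""Panel CSV input/output and the log10 + z-score transform.

The CSV schema is UTF-8, comma-separated, "." decimal, header required.
Required columns: ``sample_id``, ``steatosis`` (0/1), ``grade`` (0/1/2).
The remaining columns are clinical covariates if their name is reserved
(``sex``, ``age``, ``bmi_z``, ``waist``) and markers otherwise, in file
order. All multivariate stages operate on log10-transformed,
column-standardized concentrations produced by :func:`log10_zscore`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import RESERVED_COLUMNS, BiomarkerPanel, PanelValidationError

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Raised when a panel CSV lacks required structure."""


@dataclass
class TransformedPanel:
    """log10 + column-standardized view of a panel.

    ``values`` has one row per retained sample and one column per marker;
    each column has mean 0 and sample SD 1 (constant columns are all zeros
    and recorded with sd 0). The transform is invertible through
    ``means``/``sds``: raw = 10 ** (values * sd + mean).
    """

    source: BiomarkerPanel
    values: pd.DataFrame
    means: pd.Series  # per-marker mean of log10 values
    sds: pd.Series    # per-marker sample (n-1) SD of log10 values

    def inverse(self) -> pd.DataFrame:
        """Back-transform to native concentrations."""
        return 10.0 ** (self.values * self.sds + self.means)


def read_panel(path) -> BiomarkerPanel:
    """Read and validate a panel CSV.

    Unparseable marker cells become explicit missing values (NaN); rows are
    never silently dropped. Schema violations (missing required column,
    grade/steatosis mismatch, non-positive concentrations) raise.
    """
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    for col in ("sample_id", "steatosis", "grade"):
        if col not in df.columns:
            raise SchemaError(f"panel CSV is missing required column {col!r}")
    marker_names = [c for c in df.columns if c not in RESERVED_COLUMNS]
    for col in marker_names:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("steatosis", "grade"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    panel = BiomarkerPanel(df, marker_names)
    panel.validate(allow_missing=True)
    n_missing = int(panel.markers.isna().sum().sum())
    if n_missing:
        logger.warning("panel %s carries %d missing marker values", path, n_missing)
    return panel


def write_panel(panel: BiomarkerPanel, path):
    """Write a panel CSV round-trippable by :func:`read_panel`.

    Floats are serialized with 17 significant digits so write-then-read
    preserves every value bit-for-float.
    """
    panel.validate(allow_missing=True)
    panel.data.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")
    return path


def log10_zscore(panel: BiomarkerPanel, subset=None) -> TransformedPanel:
    """log10-transform then column-standardize marker concentrations.

    Standardization uses the sample (n-1) SD over the retained samples.
    A constant column yields all zeros (sd recorded as 0) with a warning
    rather than an error. Non-positive values raise, naming the sample and
    marker.
    """
    sub = panel if subset is None else panel.subset(subset)
    mk = sub.markers
    bad = mk.le(0)
    if bad.any().any():
        locs = [
            (sub.data["sample_id"].iloc[i], mk.columns[j])
            for i, j in zip(*np.nonzero(bad.to_numpy()))
        ]
        raise PanelValidationError(
            f"log10 undefined for non-positive values at (sample, marker): {locs}"
        )
    logged = np.log10(mk)
    means = logged.mean()
    sds = logged.std(ddof=1)
    constant = sds.fillna(0.0) == 0.0
    if constant.any():
        logger.warning(
            "constant marker column(s) standardized to zeros: %s",
            list(constant[constant].index),
        )
    safe_sds = sds.where(~constant, 1.0)
    values = (logged - means) / safe_sds
    values.loc[:, list(constant[constant].index)] = 0.0
    return TransformedPanel(
        source=sub, values=values, means=means, sds=sds.where(~constant, 0.0)
    )
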