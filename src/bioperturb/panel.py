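"""Biomarker panel container.

A panel is one row per participant: identifier, binary steatosis status,
ordinal steatosis grade (0 = none, 1 = mild, 2 = moderate/severe), basic
clinical covariates, and a block of strictly positive marker concentrations
in their native units. Every downstream stage (univariate screening,
clustering, networks, perturbation scores, discriminant and association
models) consumes this one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Metadata column names; every other column in a panel CSV is a marker.
RESERVED_COLUMNS = ("sample_id", "steatosis", "grade", "sex", "age", "bmi_z", "waist")

#: Covariates that may optionally be analysed alongside the markers
#: (clustering / trend / network stages), mirroring BMI and Homa-IR style
#: variables appearing next to the assayed markers.
OPTIONAL_ANALYSIS_COVARIATES = ("bmi_z", "waist")


class PanelValidationError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass
class BiomarkerPanel:
    """Participants x markers table with clinical metadata.

    Parameters
    ----------
    data:
        DataFrame holding the reserved metadata columns plus one numeric
        column per marker. Missing marker values are explicit NaN; they are
        permitted in read panels but never produced by the generator.
    marker_names:
        Marker columns in panel order.
    """

    data: pd.DataFrame
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.marker_names:
            self.marker_names = [
                c for c in self.data.columns if c not in RESERVED_COLUMNS
            ]

    # -- views -------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def markers(self) -> pd.DataFrame:
        """Marker concentration block (native units)."""
        return self.data[self.marker_names]

    @property
    def steatosis(self) -> pd.Series:
        return self.data["steatosis"]

    @property
    def grade(self) -> pd.Series:
        return self.data["grade"]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.data["steatosis"] == 1).to_numpy()

    @property
    def control_mask(self) -> np.ndarray:
        return (self.data["steatosis"] == 0).to_numpy()

    def subset(self, mask) -> "BiomarkerPanel":
        """Row-subset panel (mask is boolean array or index list)."""
        return BiomarkerPanel(
            self.data.loc[np.asarray(mask)].reset_index(drop=True)
            if np.asarray(mask).dtype == bool
            else self.data.iloc[list(mask)].reset_index(drop=True),
            list(self.marker_names),
        )

    def group_panel(self, steatosis_value: int) -> "BiomarkerPanel":
        return self.subset((self.data["steatosis"] == steatosis_value).to_numpy())

    def complete_rows(self) -> "BiomarkerPanel":
        """Listwise-complete panel (rows with no missing marker values)."""
        mask = ~self.markers.isna().any(axis=1).to_numpy()
        return self.subset(mask)

    # -- validation --------------------------------------------------------
    def validate(self, allow_missing: bool = True) -> "BiomarkerPanel":
        """Check structural invariants; raise ``PanelValidationError`` on failure.

        Invariants: required columns present; steatosis binary; grade in
        {0,1,2} with grade>0 only for cases (and grade 0 exactly for
        controls); all non-missing marker concentrations strictly positive.
        """
        for col in ("sample_id", "steatosis", "grade"):
            if col not in self.data.columns:
                raise PanelValidationError(f"missing required column {col!r}")
        if not self.data["steatosis"].isin([0, 1]).all():
            raise PanelValidationError("steatosis must be coded 0/1")
        if not self.data["grade"].isin([0, 1, 2]).all():
            raise PanelValidationError("grade must be coded 0/1/2")
        bad = self.data[
            ((self.data["grade"] > 0) & (self.data["steatosis"] == 0))
            | ((self.data["grade"] == 0) & (self.data["steatosis"] == 1))
        ]
        if len(bad):
            raise PanelValidationError(
                "grade/steatosis mismatch (grade>0 iff steatosis=1) in rows "
                f"{bad.index.tolist()} (sample_id {bad['sample_id'].tolist()})"
            )
        mk = self.markers
        if not allow_missing and mk.isna().any().any():
            raise PanelValidationError("missing marker values not allowed here")
        nonpos = (mk <= 0).any()
        if nonpos.any():
            offending = list(nonpos[nonpos].index)
            raise PanelValidationError(
                f"non-positive concentrations (log10 undefined) in markers {offending}"
            )
        return self
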