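"""Cohort table schema: implant design features, covariates and longitudinal
corticalization-index / marginal-bone-loss measurements.

One :class:`CohortRecord` describes one implant followed over up to three
radiographic timepoints (immediately before prosthetic loading, after five
years, after ten years of functional loading). Design-feature vocabularies
follow the catalogue of intraosseous implant characteristics (titanium
grade, immersion level, connection, neck micro-threads, body and apex
geometry) plus the prosthetic restoration placed on the implant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .io import TIMEPOINTS

#: Allowed values for every categorical column (missing is always allowed).
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "titanium_alloy": ("grade4", "grade5"),
    "level": ("bone", "tissue", "subcrestal"),
    "connection_type": ("internal", "custom"),
    "connection_shape": (
        "conical",
        "internal_hexagon",
        "internal_octagon",
        "one_piece_abutment",
    ),
    "neck_microthreads": ("yes", "no"),
    "body_shape": ("tapered", "straight"),
    "body_threads": ("buttress", "reverse_buttress", "v_shape", "square", "no_threads"),
    "apex_shape": ("cone", "dome", "flat"),
    "apex_hole": ("round", "no_hole"),
    "apex_groove": ("yes", "no"),
    "prosthetic": ("single_crown", "splinted_crowns", "bridge", "overdenture"),
    "platform_switching": ("yes", "no"),
    "sex": ("female", "male"),
    "smoking": ("yes", "no"),
    "jaw": ("maxilla", "mandible"),
    "arch_location": ("anterior", "posterior"),
    "augmented": ("yes", "no"),
    "augmentation_technique": ("none", "bone_chips", "bone_substitute", "sinus_lift"),
}

#: Intraosseous design-feature columns usable as grouping variables.
DESIGN_FEATURES = (
    "titanium_alloy",
    "level",
    "connection_type",
    "connection_shape",
    "neck_microthreads",
    "body_shape",
    "body_threads",
    "apex_shape",
    "apex_hole",
    "apex_groove",
)

#: Prosthetic-side grouping variables.
PROSTHETIC_FEATURES = ("prosthetic", "platform_switching")

#: Numeric patient covariates with their units.
NUMERIC_COVARIATES = (
    "age_y",
    "height_m",
    "weight_kg",
    "bmi",
    "tsh_mu_l",
    "calcium_mmol_dl",
    "triglycerides_mmol_l",
)

_MEASUREMENTS = tuple(f"ci_{t}" for t in TIMEPOINTS) + tuple(f"mbl_{t}" for t in TIMEPOINTS)

COHORT_COLUMNS = (
    ("implant_id",)
    + DESIGN_FEATURES
    + PROSTHETIC_FEATURES
    + tuple(CATEGORICAL_LEVELS)[12:]  # patient categoricals, declared order
    + NUMERIC_COVARIATES
    + _MEASUREMENTS
)


@dataclass
class CohortRecord:
    """One implant with design features, covariates and longitudinal data.

    CI values are unitless and non-negative; MBL values are millimetres of
    marginal bone loss and non-negative. ``None``/NaN marks missing data.
    """

    implant_id: str
    titanium_alloy: str | None = None
    level: str | None = None
    connection_type: str | None = None
    connection_shape: str | None = None
    neck_microthreads: str | None = None
    body_shape: str | None = None
    body_threads: str | None = None
    apex_shape: str | None = None
    apex_hole: str | None = None
    apex_groove: str | None = None
    prosthetic: str | None = None
    platform_switching: str | None = None
    sex: str | None = None
    smoking: str | None = None
    jaw: str | None = None
    arch_location: str | None = None
    augmented: str | None = None
    augmentation_technique: str | None = None
    age_y: float | None = None
    height_m: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None
    tsh_mu_l: float | None = None
    calcium_mmol_dl: float | None = None
    triglycerides_mmol_l: float | None = None
    ci_initial: float | None = None
    ci_y5: float | None = None
    ci_y10: float | None = None
    mbl_initial: float | None = None
    mbl_y5: float | None = None
    mbl_y10: float | None = None

    def __post_init__(self) -> None:
        for col in CATEGORICAL_LEVELS:
            val = getattr(self, col)
            if val is not None and val not in CATEGORICAL_LEVELS[col]:
                raise SchemaError(
                    f"implant {self.implant_id!r}, column {col!r}: value {val!r} not in "
                    f"{CATEGORICAL_LEVELS[col]}"
                )
        for col in _MEASUREMENTS:
            val = getattr(self, col)
            if val is not None and not np.isnan(val) and val < 0:
                raise SchemaError(
                    f"implant {self.implant_id!r}, column {col!r}: negative value {val}"
                )

    def ci(self, timepoint: str) -> float | None:
        return getattr(self, f"ci_{timepoint}")

    def mbl(self, timepoint: str) -> float | None:
        return getattr(self, f"mbl_{timepoint}")


def _is_missing(val) -> bool:
    if val is None:
        return True
    if isinstance(val, float) and np.isnan(val):
        return True
    return isinstance(val, str) and val == ""


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Read and validate a cohort CSV into a list of records.

    Unknown categorical values, negative MBL/CI and missing mandatory
    columns raise :class:`~periocort.errors.SchemaError` naming the
    offending row and column. Missing cells stay missing.
    """
    df = pd.read_csv(path, comment="#", dtype={"implant_id": str})
    missing_cols = {"implant_id"} - set(df.columns)
    if missing_cols:
        raise SchemaError(f"cohort table lacks mandatory columns: {sorted(missing_cols)}")
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if unknown:
        raise SchemaError(f"cohort table has unknown columns: {sorted(unknown)}")
    records = []
    valid_fields = {f.name for f in dc_fields(CohortRecord)}
    for i, row in df.iterrows():
        kwargs = {}
        for col in df.columns:
            if col not in valid_fields:
                continue
            val = row[col]
            if _is_missing(val):
                continue
            if col in NUMERIC_COVARIATES or col in _MEASUREMENTS:
                try:
                    val = float(val)
                except (TypeError, ValueError):
                    raise SchemaError(f"row {i}, column {col!r}: non-numeric value {val!r}")
            kwargs[col] = val
        try:
            records.append(CohortRecord(**kwargs))
        except SchemaError as exc:
            raise SchemaError(f"row {i}: {exc}") from None
    return records


def records_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with the canonical column order."""
    rows = []
    for rec in records:
        rows.append({f.name: getattr(rec, f.name) for f in dc_fields(CohortRecord)})
    df = pd.DataFrame(rows, columns=[f.name for f in dc_fields(CohortRecord)])
    return df


def write_cohort_table(
    records: Sequence[CohortRecord], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write records as CSV, with optional ``#`` metadata header lines."""
    df = records_to_frame(records)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
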