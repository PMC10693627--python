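"""Table readers/writers: ROI tables (long/wide), deviation matrices, clinical CSVs."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .normative import DeviationMatrix
from .utils import ROI_COLUMNS

__all__ = [
    "read_roi_table",
    "write_roi_table",
    "read_deviations",
    "write_deviations",
    "read_clinical",
    "write_clinical",
]

logger = logging.getLogger(__name__)

_META_COLUMNS = ["subject_id", "site_id", "sex", "age", "group", "role"]


def _validate_roi(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"ROI table missing required columns: {missing}")
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise ValidationError(f"invalid sex values at rows {df.index[bad_sex].tolist()[:10]}")
    bad = ~(df["thickness"] > 0)
    if bad.any():
        raise ValidationError(
            f"non-positive thickness at rows {df.index[bad].tolist()[:10]}"
        )
    bad_role = (df["role"] == "adaptation") & (df["group"] != "control")
    if bad_role.any():
        raise ValidationError("role='adaptation' is only valid for controls")
    counts = df.groupby("subject_id")["region_id"].count()
    if counts.nunique() > 1:
        raise ValidationError(
            f"unequal region counts per subject (range {counts.min()}-{counts.max()})"
        )
    return df[ROI_COLUMNS]


def read_roi_table(path: str | Path, layout: str = "long") -> pd.DataFrame:
    """Read a ROI thickness table from CSV.

    ``layout='long'`` expects one row per subject x region; ``'wide'``
    expects the metadata columns plus one column per region, and is
    melted to long form.
    """
    if layout not in ("long", "wide"):
        raise ValidationError(f"layout must be 'long' or 'wide', got {layout!r}")
    df = pd.read_csv(path)
    if layout == "wide":
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"wide ROI table missing columns: {missing}")
        region_cols = [c for c in df.columns if c not in _META_COLUMNS]
        if not region_cols:
            raise ValidationError("wide ROI table has no region columns")
        df = df.melt(
            id_vars=_META_COLUMNS, value_vars=region_cols,
            var_name="region_id", value_name="thickness",
        )
    df = _validate_roi(df)
    logger.info("read %d rows, %d regions from %s", len(df), df["region_id"].nunique(), path)
    return df


def write_roi_table(df: pd.DataFrame, path: str | Path) -> None:
    _validate_roi(df).to_csv(path, index=False)


def write_deviations(dev: DeviationMatrix, z_path: str | Path, covariates_path: str | Path) -> None:
    """Wide z-score CSV (one row per subject) plus a covariate sidecar CSV."""
    dev.z.to_csv(z_path, index=True, index_label="subject_id")
    dev.covariates.to_csv(covariates_path, index=True, index_label="subject_id")


def read_deviations(z_path: str | Path, covariates_path: str | Path) -> DeviationMatrix:
    z = pd.read_csv(z_path, index_col="subject_id")
    cov = pd.read_csv(covariates_path, index_col="subject_id")
    missing = [c for c in ("site_id", "sex", "age", "group") if c not in cov.columns]
    if missing:
        raise ValidationError(f"covariate sidecar missing columns: {missing}")
    if not z.index.equals(cov.index):
        raise ValidationError("z matrix and covariate sidecar index mismatch")
    return DeviationMatrix(z=z, covariates=cov)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "week" not in df.columns:
        raise ValidationError("clinical table must have subject_id and week columns")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
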