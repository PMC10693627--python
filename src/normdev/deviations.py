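"""Extreme-deviation masks, regional overlap and overall proportions.

A deviation is extreme when |z| >= threshold (boundary inclusive).
Regional overlap for a group/sign is the percentage of that group's
subjects flagged in a region; the overall proportion is the percentage
of flagged cells over subjects x regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .normative import DeviationMatrix

__all__ = ["ExtremeMask", "extreme_mask", "regional_overlap", "overall_proportion", "overlap_map"]

DEFAULT_THRESHOLD = 2.6


@dataclass
class ExtremeMask:
    """Boolean subject x region masks per sign, with covariates carried through."""

    negative: pd.DataFrame
    positive: pd.DataFrame
    covariates: pd.DataFrame
    threshold: float

    def frame(self, sign: str) -> pd.DataFrame:
        if sign not in ("negative", "positive"):
            raise ValidationError(f"sign must be 'negative' or 'positive', got {sign!r}")
        return self.negative if sign == "negative" else self.positive

    def group_index(self, group: str) -> pd.Index:
        idx = self.covariates.index[self.covariates["group"] == group]
        if len(idx) == 0:
            raise ValidationError(f"group {group!r} not present (or empty) in mask")
        return idx


def extreme_mask(z: DeviationMatrix, threshold: float = DEFAULT_THRESHOLD) -> ExtremeMask:
    """Threshold z-scores into mutually exclusive extreme negative/positive flags."""
    if not threshold > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    vals = z.z.to_numpy()
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))
        cells = [(z.z.index[i], z.z.columns[j]) for i, j in bad[:20]]
        raise ValidationError(f"non-finite z-scores at cells: {cells}")
    return ExtremeMask(
        negative=z.z <= -threshold,
        positive=z.z >= threshold,
        covariates=z.covariates.copy(),
        threshold=threshold,
    )


def regional_overlap(mask: ExtremeMask, group: str, sign: str = "negative") -> pd.Series:
    """Per-region overlap percent: 100 * flagged subjects / group size."""
    idx = mask.group_index(group)
    flags = mask.frame(sign).loc[idx]
    return 100.0 * flags.sum(axis=0) / len(idx)


def overall_proportion(mask: ExtremeMask, group: str, sign: str = "negative") -> float:
    """Overall percent of flagged cells: 100 * flags / (subjects * regions)."""
    idx = mask.group_index(group)
    flags = mask.frame(sign).loc[idx]
    return float(100.0 * flags.to_numpy().sum() / (len(idx) * flags.shape[1]))


def overlap_map(mask: ExtremeMask) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All (region, group, sign) overlaps plus the (group, sign) proportions.

    Returns ``(regional, summary)`` data frames ready for CSV export.
    """
    groups = sorted(mask.covariates["group"].unique())
    regional_rows = []
    summary_rows = []
    for group in groups:
        for sign in ("negative", "positive"):
            ov = regional_overlap(mask, group, sign)
            regional_rows.append(
                pd.DataFrame(
                    {
                        "region_id": ov.index,
                        "group": group,
                        "sign": sign,
                        "overlap_pct": ov.to_numpy(),
                    }
                )
            )
            summary_rows.append(
                {
                    "group": group,
                    "sign": sign,
                    "proportion_pct": overall_proportion(mask, group, sign),
                    "n_subjects": len(mask.group_index(group)),
                    "n_regions": mask.frame(sign).shape[1],
                }
            )
    return pd.concat(regional_rows, ignore_index=True), pd.DataFrame(summary_rows)
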