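"""Synthetic multi-site cohorts with known ground truth.

Generates reference and clinical regional-thickness tables under a
linear age/sex model with per-site offset and noise-scale effects,
injects sparse extreme negative deviations plus a diffuse shift into
patients, and produces longitudinal PANSS-like item tables whose
negative-domain trajectory depends on baseline deviation z-scores.
Every generator is deterministic given (config, seed) and emits the
injected ground truth needed by downstream recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .utils import ROI_COLUMNS, region_names, rng_for

__all__ = [
    "SiteSpec",
    "PatientDeviationSpec",
    "OutcomeModelSpec",
    "CohortConfig",
    "generate_reference",
    "generate_clinical_sites",
    "generate_longitudinal_outcomes",
]


@dataclass
class SiteSpec:
    """One scanning site: sample sizes and scanner effects."""

    site_id: str
    n_controls: int = 0
    n_patients: int = 0
    offset_mm: float = 0.0
    scale_factor: float = 1.0

    def validate(self) -> None:
        if self.n_controls < 0:
            raise ConfigError(f"site {self.site_id!r}: n_controls must be >= 0")
        if self.n_patients < 0:
            raise ConfigError(f"site {self.site_id!r}: n_patients must be >= 0")
        if not self.scale_factor > 0:
            raise ConfigError(f"site {self.site_id!r}: scale_factor must be > 0")


@dataclass
class PatientDeviationSpec:
    """Patient-specific atypicality: sparse extreme insertions + diffuse shift.

    Magnitudes are in units of the residual SD; extreme insertions must be
    negative (thinner than expected).
    """

    n_extreme_regions_mean: float = 5.0
    magnitude_sd_units: float = -4.0
    diffuse_shift_sd_units: float = 0.0

    def validate(self, n_regions: int) -> None:
        if self.n_extreme_regions_mean < 0:
            raise ConfigError("patient_deviation.n_extreme_regions_mean must be >= 0")
        if self.n_extreme_regions_mean > n_regions:
            raise ConfigError(
                "patient_deviation.n_extreme_regions_mean exceeds n_regions "
                f"({self.n_extreme_regions_mean} > {n_regions})"
            )
        if self.n_extreme_regions_mean > 0 and self.magnitude_sd_units >= 0:
            raise ConfigError("patient_deviation.magnitude_sd_units must be negative")


@dataclass
class OutcomeModelSpec:
    """Generative mixed model for longitudinal symptom scores.

    Negative-domain score at visit v of subject i:
        intercept + (time_slope + b1_i) * week_v + z_coefficient * zbar_i
        + b0_i + eps,
    with b0_i ~ N(0, intercept_sd^2), b1_i ~ N(0, slope_sd^2),
    eps ~ N(0, residual_sd^2).  Item-level scores are derived so that the
    integer domain sums match the generated values after rounding/clipping.
    """

    intercept: float = 16.0
    time_slope: float = -0.116
    z_coefficient: float = -0.154
    intercept_sd: float = 3.0
    slope_sd: float = 0.03
    residual_sd: float = 2.0
    n_visits: int = 4
    visit_weeks: Sequence[float] = (0.0, 12.0, 52.0, 95.0)
    positive_intercept: float = 17.0
    general_intercept: float = 33.0
    dropout_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_visits < 1:
            raise ConfigError("outcome_model.n_visits must be >= 1")
        if len(self.visit_weeks) < self.n_visits:
            raise ConfigError("outcome_model.visit_weeks shorter than n_visits")
        weeks = list(self.visit_weeks)[: self.n_visits]
        if any(w < 0 or w > 95 for w in weeks):
            raise ConfigError("outcome_model.visit_weeks must lie within 0-95")
        for name in ("intercept_sd", "slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"outcome_model.{name} must be >= 0")
        if not 0 <= self.dropout_fraction < 1:
            raise ConfigError("outcome_model.dropout_fraction must be in [0, 1)")


@dataclass
class CohortConfig:
    """Full generative configuration for one synthetic study."""

    sites: list[SiteSpec] = field(default_factory=list)
    n_regions: int = 148
    age_range: tuple[float, float] = (18.0, 40.0)
    reference_age_range: tuple[float, float] = (6.0, 100.0)
    intercept_mm: float = 2.5
    sex_effect_mm: float = -0.04
    age_slope_mm_per_year: float = -0.005
    residual_sd_mm: float = 0.12
    patient_deviation: PatientDeviationSpec = field(default_factory=PatientDeviationSpec)
    outcome_model: OutcomeModelSpec = field(default_factory=OutcomeModelSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if not self.residual_sd_mm > 0:
            raise ConfigError("residual_sd_mm must be > 0")
        for rng_name in ("age_range", "reference_age_range"):
            lo, hi = getattr(self, rng_name)
            if not lo < hi:
                raise ConfigError(f"{rng_name} must satisfy lo < hi")
        if not self.sites:
            raise ConfigError("sites must be non-empty")
        seen = set()
        for site in self.sites:
            site.validate()
            if site.site_id in seen:
                raise ConfigError(f"duplicate site_id {site.site_id!r}")
            seen.add(site.site_id)
        if any(s.n_patients > 0 for s in self.sites):
            self.patient_deviation.validate(self.n_regions)
        self.outcome_model.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["sites"] = [SiteSpec(**s) if not isinstance(s, SiteSpec) else s for s in d.get("sites", [])]
        if "patient_deviation" in d and not isinstance(d["patient_deviation"], PatientDeviationSpec):
            d["patient_deviation"] = PatientDeviationSpec(**d["patient_deviation"])
        if "outcome_model" in d and not isinstance(d["outcome_model"], OutcomeModelSpec):
            d["outcome_model"] = OutcomeModelSpec(**d["outcome_model"])
        for key in ("age_range", "reference_age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _subject_frame(
    config: CohortConfig,
    rng: np.random.Generator,
    site: SiteSpec,
    n: int,
    group: str,
    prefix: str,
    age_range: tuple[float, float],
    start_index: int,
) -> pd.DataFrame:
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    male = rng.integers(0, 2, size=n)
    return pd.DataFrame(
        {
            "subject_id": [f"{prefix}{start_index + i:05d}" for i in range(n)],
            "site_id": site.site_id,
            "sex": np.where(male == 1, "M", "F"),
            "age": ages,
            "group": group,
            "role": "test",
        }
    )


def _thickness_matrix(
    config: CohortConfig, rng: np.random.Generator, subjects: pd.DataFrame, site: SiteSpec
) -> np.ndarray:
    """Subject x region thickness under the generative law."""
    male = (subjects["sex"] == "M").to_numpy(dtype=float)
    mean = (
        config.intercept_mm
        + config.age_slope_mm_per_year * subjects["age"].to_numpy()
        + config.sex_effect_mm * male
        + site.offset_mm
    )
    eps = rng.normal(0.0, config.residual_sd_mm, size=(len(subjects), config.n_regions))
    return mean[:, None] + site.scale_factor * eps


def _to_long(subjects: pd.DataFrame, thickness: np.ndarray, regions: list[str]) -> pd.DataFrame:
    n, r = thickness.shape
    long = subjects.loc[subjects.index.repeat(r)].reset_index(drop=True)
    long["region_id"] = np.tile(regions, n)
    long["thickness"] = thickness.reshape(-1)
    return long[ROI_COLUMNS]


def generate_reference(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a multi-site reference (all-control) ROI table.

    Thickness follows intercept + age_slope*age + sex_effect*1[M]
    + site_offset + site_scale * N(0, residual_sd) independently per region.
    """
    config.validate()
    if len(config.sites) < 2:
        raise ConfigError("reference generation requires >= 2 sites")
    for site in config.sites:
        if site.n_controls < 2:
            raise ConfigError(f"site {site.site_id!r}: reference sites need n_controls >= 2")
    seed = config.seed if seed is None else seed
    regions = region_names(config.n_regions)
    frames = []
    for site in config.sites:
        rng = rng_for(seed, f"reference/{site.site_id}")
        subjects = _subject_frame(
            config, rng, site, site.n_controls, "control", f"ref_{site.site_id}_",
            config.reference_age_range, 0,
        )
        frames.append(_to_long(subjects, _thickness_matrix(config, rng, subjects, site), regions))
    return pd.concat(frames, ignore_index=True)


def generate_clinical_sites(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate clinical-site controls and patients.

    Returns ``(roi_table, injections)``.  ``injections`` is the
    machine-readable ground truth with one row per injected extreme cell:
    columns subject_id, region_id, injected_magnitude (mm, negative), plus
    the per-patient diffuse shift is applied to all regions and recorded in
    the ``diffuse_shift_mm`` column (constant within subject).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    regions = region_names(config.n_regions)
    dev = config.patient_deviation
    frames = []
    injected_rows = []
    for site in config.sites:
        rng = rng_for(seed, f"clinical/{site.site_id}")
        if site.n_controls:
            subjects = _subject_frame(
                config, rng, site, site.n_controls, "control", f"con_{site.site_id}_",
                config.age_range, 0,
            )
            frames.append(_to_long(subjects, _thickness_matrix(config, rng, subjects, site), regions))
        if site.n_patients:
            subjects = _subject_frame(
                config, rng, site, site.n_patients, "patient", f"pat_{site.site_id}_",
                config.age_range, 0,
            )
            thick = _thickness_matrix(config, rng, subjects, site)
            diffuse_mm = dev.diffuse_shift_sd_units * config.residual_sd_mm
            thick += diffuse_mm
            magnitude_mm = dev.magnitude_sd_units * config.residual_sd_mm
            for i, sid in enumerate(subjects["subject_id"]):
                k = int(min(rng.poisson(dev.n_extreme_regions_mean), config.n_regions))
                if k > 0:
                    idx = rng.choice(config.n_regions, size=k, replace=False)
                    thick[i, idx] += magnitude_mm
                    for j in idx:
                        injected_rows.append(
                            (sid, regions[j], magnitude_mm, diffuse_mm)
                        )
            frames.append(_to_long(subjects, thick, regions))
    table = pd.concat(frames, ignore_index=True)
    injections = pd.DataFrame(
        injected_rows,
        columns=["subject_id", "region_id", "injected_magnitude", "diffuse_shift_mm"],
    )
    return table, injections


def _distribute_items(total: int, n_items: int, rng: np.random.Generator) -> np.ndarray:
    """Split an integer domain sum into n_items integers in 1..7.

    Starts every item at 1 and spreads the surplus by a seeded multinomial,
    re-drawing any overflow past the cap of 7 until exhausted.
    """
    total = int(np.clip(total, n_items, 7 * n_items))
    items = np.ones(n_items, dtype=int)
    surplus = total - n_items
    while surplus > 0:
        headroom = 7 - items
        open_idx = np.flatnonzero(headroom)
        add = rng.multinomial(surplus, np.full(len(open_idx), 1.0 / len(open_idx)))
        add = np.minimum(add, headroom[open_idx])
        items[open_idx] += add
        surplus = total - items.sum()
    return items


_P_ITEMS = [f"P{i}" for i in range(1, 8)]
_N_ITEMS = [f"N{i}" for i in range(1, 8)]
_G_ITEMS = [f"G{i}" for i in range(1, 17)]


def generate_longitudinal_outcomes(
    z_baseline, config: CohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """Generate longitudinal PANSS item tables for every patient in ``z_baseline``.

    ``z_baseline`` is a :class:`~normdev.normative.DeviationMatrix` (or any
    object with ``z`` and ``covariates`` data frames).  The negative-domain
    sum follows the generative mixed model of :class:`OutcomeModelSpec`
    driven by each patient's mean regional z-score; positive and general
    domains follow the same time trend without a deviation effect.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    om = config.outcome_model
    cov = z_baseline.covariates
    patients = cov.index[cov["group"] == "patient"]
    if len(patients) == 0:
        raise ValidationError("no patients present in z_baseline")
    missing = [s for s in patients if s not in z_baseline.z.index]
    if missing:
        raise ValidationError(f"patients missing from z matrix: {missing}")

    rng = rng_for(seed, "outcomes")
    weeks = np.asarray(list(om.visit_weeks)[: om.n_visits], dtype=float)
    zbar = z_baseline.z.loc[patients].mean(axis=1).to_numpy()
    b0 = rng.normal(0.0, om.intercept_sd, size=len(patients))
    b1 = rng.normal(0.0, om.slope_sd, size=len(patients))

    rows = []
    for i, sid in enumerate(patients):
        keep = np.ones(len(weeks), dtype=bool)
        if om.dropout_fraction > 0:
            drop = rng.random(len(weeks)) < om.dropout_fraction
            drop[0] = False  # baseline always observed
            keep = ~drop
        for v, week in enumerate(weeks):
            if not keep[v]:
                continue
            eps = rng.normal(0.0, om.residual_sd)
            neg = om.intercept + (om.time_slope + b1[i]) * week + om.z_coefficient * zbar[i] + b0[i] + eps
            pos = om.positive_intercept + om.time_slope * week + rng.normal(0.0, om.residual_sd)
            gen = om.general_intercept + om.time_slope * week + rng.normal(0.0, om.residual_sd)
            record = {"subject_id": sid, "week": float(week)}
            record.update(zip(_N_ITEMS, _distribute_items(round(neg), 7, rng)))
            record.update(zip(_P_ITEMS, _distribute_items(round(pos), 7, rng)))
            record.update(zip(_G_ITEMS, _distribute_items(round(gen), 16, rng)))
            rows.append(record)
    out = pd.DataFrame(rows, columns=["subject_id", "week"] + _P_ITEMS + _N_ITEMS + _G_ITEMS)
    return out
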