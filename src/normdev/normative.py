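"""Hierarchical Gaussian normative model of regional thickness.

Per region the model is

    y = mu(age, sex) + delta_site + gamma_site * sigma * eps,   eps ~ N(0, 1)

with mu a spline (or linear) function of age plus a sex term, site offsets
treated as shrunken random effects with hyperprior N(0, tau_offset^2), and
site noise scales with a log-normal hyperprior of SD tau_scale.  Unseen
sites are adapted from held-out controls via closed-form shrinkage
(offset) and a one-dimensional MAP solve (scale); the adaptation subjects
are then discarded and deviation z-scores are computed for test subjects
only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import brentq

from .errors import ConfigError, FitError, ValidationError
from .utils import ROI_COLUMNS, rng_for

__all__ = [
    "AgeBasis",
    "RegionParams",
    "NormativeModel",
    "SiteAdaptation",
    "DeviationMatrix",
    "fit_reference",
    "split_adaptation",
    "adapt_site",
    "compute_zscores",
]

SCHEMA_VERSION = 1


@dataclass
class AgeBasis:
    """Age design basis: clamped cubic B-spline or plain linear term."""

    kind: str = "bspline"  # "bspline" | "linear"
    lo: float = 6.0
    hi: float = 100.0
    n_interior_knots: int = 5
    degree: int = 3

    def __post_init__(self):
        if self.kind not in ("bspline", "linear"):
            raise ConfigError(f"unknown age basis kind {self.kind!r}")
        if not self.lo < self.hi:
            raise ConfigError("age basis requires lo < hi")

    @property
    def knots(self) -> np.ndarray:
        interior = np.linspace(self.lo, self.hi, self.n_interior_knots + 2)[1:-1]
        return np.r_[[self.lo] * (self.degree + 1), interior, [self.hi] * (self.degree + 1)]

    def design(self, age: np.ndarray) -> np.ndarray:
        """Design columns for age (constant column excluded)."""
        age = np.clip(np.asarray(age, dtype=float), self.lo, self.hi)
        if self.kind == "linear":
            return age[:, None]
        D = BSpline.design_matrix(age, self.knots, self.degree).toarray()
        # drop the first basis function: the remaining columns plus an
        # explicit intercept span the same space without collinearity
        return D[:, 1:]

    def n_columns(self) -> int:
        if self.kind == "linear":
            return 1
        return self.n_interior_knots + self.degree

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "lo": self.lo,
            "hi": self.hi,
            "n_interior_knots": self.n_interior_knots,
            "degree": self.degree,
        }


@dataclass
class RegionParams:
    """Fitted normative parameters for a single region."""

    intercept: float
    age_coefs: np.ndarray
    sex_coef: float
    sigma: float
    tau_offset: float
    tau_scale: float


@dataclass
class NormativeModel:
    """Serializable multi-site normative model (one fit per region)."""

    basis: AgeBasis
    regions: list[str]
    params: dict[str, RegionParams]
    # reference sites keep their own offset/scale for reference-site test data
    site_offsets: dict[str, dict[str, float]]
    site_scales: dict[str, dict[str, float]]
    excluded_regions: list[str] = field(default_factory=list)

    @property
    def sites(self) -> list[str]:
        return sorted(self.site_offsets)

    def predict_mean(self, region: str, age: np.ndarray, male: np.ndarray) -> np.ndarray:
        p = self.params[region]
        X = self.basis.design(np.asarray(age, dtype=float))
        return p.intercept + X @ p.age_coefs + p.sex_coef * np.asarray(male, dtype=float)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "basis": self.basis.to_dict(),
            "regions": self.regions,
            "excluded_regions": self.excluded_regions,
            "params": {
                r: {
                    "intercept": p.intercept,
                    "age_coefs": list(p.age_coefs),
                    "sex_coef": p.sex_coef,
                    "sigma": p.sigma,
                    "tau_offset": p.tau_offset,
                    "tau_scale": p.tau_scale,
                }
                for r, p in self.params.items()
            },
            "site_offsets": self.site_offsets,
            "site_scales": self.site_scales,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValidationError(f"unsupported model schema version {d.get('schema_version')!r}")
        params = {
            r: RegionParams(
                intercept=p["intercept"],
                age_coefs=np.asarray(p["age_coefs"], dtype=float),
                sex_coef=p["sex_coef"],
                sigma=p["sigma"],
                tau_offset=p["tau_offset"],
                tau_scale=p["tau_scale"],
            )
            for r, p in d["params"].items()
        }
        return cls(
            basis=AgeBasis(**d["basis"]),
            regions=list(d["regions"]),
            params=params,
            site_offsets={s: dict(v) for s, v in d["site_offsets"].items()},
            site_scales={s: dict(v) for s, v in d["site_scales"].items()},
            excluded_regions=list(d.get("excluded_regions", [])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "NormativeModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class SiteAdaptation:
    """Per-(site, region) offset/scale estimates for unseen sites.

    ``table`` columns: site_id, region_id, offset, scale.
    """

    table: pd.DataFrame
    n_controls: dict[str, int]
    flagged_sites: list[str]
    min_controls: int = 10

    def lookup(self) -> tuple[dict, dict]:
        offsets: dict[str, dict[str, float]] = {}
        scales: dict[str, dict[str, float]] = {}
        for row in self.table.itertuples(index=False):
            offsets.setdefault(row.site_id, {})[row.region_id] = row.offset
            scales.setdefault(row.site_id, {})[row.region_id] = row.scale
        return offsets, scales

    @property
    def sites(self) -> list[str]:
        return sorted(self.table["site_id"].unique())


@dataclass
class DeviationMatrix:
    """Subject x region deviation z-scores plus subject covariates.

    ``z`` is indexed by subject_id with one column per region;
    ``covariates`` is indexed by subject_id with columns
    site_id, sex, age, group.
    """

    z: pd.DataFrame
    covariates: pd.DataFrame
    threshold_default: float = 2.6

    def __post_init__(self):
        if not self.z.index.equals(self.covariates.index):
            self.covariates = self.covariates.loc[self.z.index]

    def subjects(self, group: str | None = None) -> pd.Index:
        if group is None:
            return self.z.index
        return self.covariates.index[self.covariates["group"] == group]


def _check_roi_table(table: pd.DataFrame) -> None:
    missing = [c for c in ROI_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"ROI table missing columns: {missing}")


def fit_reference(
    reference: pd.DataFrame,
    basis: AgeBasis | None = None,
    ridge: float = 1e-9,
) -> NormativeModel:
    """Fit the per-region normative model on a multi-site reference table.

    Least squares with per-site intercepts; the grand intercept is the
    unweighted mean of site intercepts, site offsets are shrunk towards
    zero under their estimated hyperprior, and tau hyperparameters come
    from the between-site spread of the raw offsets / log residual SDs.
    """
    _check_roi_table(reference)
    subjects = reference.drop_duplicates("subject_id")
    sites = sorted(reference["site_id"].unique())
    if len(sites) < 2:
        warnings.warn("fitting reference with a single site; tau_offset set to 0", stacklevel=2)
    if len(subjects) < 20:
        warnings.warn(f"reference has only {len(subjects)} subjects (< 20)", stacklevel=2)

    ages = subjects["age"].to_numpy(dtype=float)
    if basis is None:
        basis = AgeBasis(lo=float(ages.min()), hi=float(ages.max()))
    if ages.min() < basis.lo - 1e-9 or ages.max() > basis.hi + 1e-9:
        warnings.warn("ages outside basis range are clamped", stacklevel=2)

    regions = sorted(reference["region_id"].unique())
    wide = reference.pivot(index="subject_id", columns="region_id", values="thickness")
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValidationError(f"incomplete subject x region coverage in regions {bad}")
    meta = subjects.set_index("subject_id").loc[wide.index]
    age = meta["age"].to_numpy(dtype=float)
    male = (meta["sex"] == "M").to_numpy(dtype=float)
    site_of = meta["site_id"].to_numpy()

    S = len(sites)
    site_idx = {s: i for i, s in enumerate(sites)}
    D_site = np.zeros((len(wide), S))
    D_site[np.arange(len(wide)), [site_idx[s] for s in site_of]] = 1.0
    B = basis.design(age)
    k = B.shape[1]
    X = np.hstack([D_site, B, male[:, None]])
    if np.linalg.matrix_rank(np.hstack([np.ones((len(B), 1)), B])) < k + 1:
        raise FitError(f"rank-deficient age basis ({basis.kind})")

    # ridge on spline columns only, for stability at sparse age coverage
    penalty = np.zeros(X.shape[1])
    if basis.kind == "bspline":
        penalty[S : S + k] = ridge
    XtX = X.T @ X + np.diag(penalty)
    n_per_site = D_site.sum(axis=0)

    params: dict[str, RegionParams] = {}
    site_offsets: dict[str, dict[str, float]] = {s: {} for s in sites}
    site_scales: dict[str, dict[str, float]] = {s: {} for s in sites}
    excluded: list[str] = []

    for region in regions:
        y = wide[region].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"region {region!r} has zero variance; excluded", stacklevel=2)
            excluded.append(region)
            continue
        beta = np.linalg.solve(XtX, X.T @ y)
        site_int = beta[:S]
        age_coefs = beta[S : S + k]
        sex_coef = beta[S + k]
        grand = float(site_int.mean())
        raw_offsets = site_int - grand

        resid = y - X @ beta
        # pooled sigma with dof correction; per-site SDs set the scale ratios
        p_eff = S + k + 1
        dof = max(len(y) - p_eff, 1)
        sigma = float(np.sqrt(np.sum(resid**2) / dof)) or 1e-12
        sig_site = np.array(
            [max(resid[site_of == s].std(ddof=1), 1e-12) if n_per_site[site_idx[s]] > 1 else np.nan
             for s in sites]
        )
        with np.errstate(invalid="ignore"):
            log_ratio = np.log(sig_site / sigma)
        ok = np.isfinite(log_ratio)
        tau_scale = float(np.std(log_ratio[ok], ddof=1)) if ok.sum() >= 2 else 0.0

        if S >= 2:
            var_raw = float(np.var(raw_offsets, ddof=1))
            noise = float(np.mean(sigma**2 / n_per_site))
            tau_offset = float(np.sqrt(max(var_raw - noise, 0.0)))
        else:
            tau_offset = 0.0
        if tau_offset > 0:
            shrink = tau_offset**2 / (tau_offset**2 + sigma**2 / n_per_site)
        else:
            shrink = np.zeros(S)
        offsets = raw_offsets * shrink

        params[region] = RegionParams(
            intercept=grand,
            age_coefs=age_coefs,
            sex_coef=float(sex_coef),
            sigma=sigma,
            tau_offset=tau_offset,
            tau_scale=tau_scale,
        )
        for i, s in enumerate(sites):
            site_offsets[s][region] = float(offsets[i])
            site_scales[s][region] = float(sig_site[i] / sigma) if np.isfinite(sig_site[i]) else 1.0

    if not params:
        raise FitError("no region could be fitted")
    kept = [r for r in regions if r not in excluded]
    return NormativeModel(
        basis=basis,
        regions=kept,
        params=params,
        site_offsets=site_offsets,
        site_scales=site_scales,
        excluded_regions=excluded,
    )


def split_adaptation(
    controls: pd.DataFrame,
    fraction: float = 0.5,
    seed: int = 0,
    stratify_by_age: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split controls per site into adaptation and test subsets by subject.

    All rows of a subject move together; the two outputs are a disjoint
    cover of the input.  With ``stratify_by_age`` subjects are binned into
    per-site age quartiles and split within each bin, improving the age
    balance of the two halves.
    """
    _check_roi_table(controls)
    if not 0 < fraction < 1:
        raise ConfigError(f"adaptation fraction must be in (0, 1), got {fraction}")
    if (controls["group"] != "control").any():
        raise ValidationError("split_adaptation expects a controls-only table")
    rng = rng_for(seed, "split_adaptation")
    adapt_ids: list[str] = []
    subjects = controls.drop_duplicates("subject_id")[["subject_id", "site_id", "age"]]
    for site in sorted(subjects["site_id"].unique()):
        sub = subjects[subjects["site_id"] == site]
        if len(sub) < 2:
            raise ValidationError(f"site {site!r} has fewer than 2 controls; cannot split")
        if stratify_by_age:
            q = np.quantile(sub["age"], [0.25, 0.5, 0.75])
            bins = np.searchsorted(q, sub["age"].to_numpy())
        else:
            bins = np.zeros(len(sub), dtype=int)
        ids = sub["subject_id"].to_numpy()
        order = rng.permutation(len(ids))
        shuffled = ids[order]
        target_total = int(round(len(ids) * fraction))
        target_total = min(max(target_total, 1), len(ids) - 1)
        chosen: list[str] = []
        for b in np.unique(bins):
            bin_ids = shuffled[bins[order] == b]
            n_b = int(round(len(bin_ids) * fraction))
            chosen.extend(bin_ids[:n_b])
        # reconcile per-bin rounding with the per-site target
        if len(chosen) > target_total:
            chosen = chosen[:target_total]
        elif len(chosen) < target_total:
            chosen_set = set(chosen)
            for sid in shuffled:
                if len(chosen) == target_total:
                    break
                if sid not in chosen_set:
                    chosen.append(sid)
                    chosen_set.add(sid)
        adapt_ids.extend(chosen)
    in_adapt = controls["subject_id"].isin(adapt_ids)
    adaptation = controls[in_adapt].copy()
    test = controls[~in_adapt].copy()
    adaptation["role"] = "adaptation"
    test["role"] = "test"
    return adaptation.reset_index(drop=True), test.reset_index(drop=True)


def _map_log_scale(sq_sum_ratio: float, n: int, tau_scale: float) -> float:
    """MAP of t = log(gamma) under  -n*t - (A/2)e^{-2t} - t^2/(2 tau^2)."""
    if tau_scale < 1e-8:
        return 0.0
    A = sq_sum_ratio

    def grad(t):
        return A * np.exp(-2.0 * t) - n - t / tau_scale**2

    lo, hi = -20.0, 20.0
    if grad(lo) < 0:  # A == 0: solution is t = -n * tau^2
        return -n * tau_scale**2
    return float(brentq(grad, lo, hi, xtol=1e-12))


def adapt_site(
    model: NormativeModel,
    adaptation_controls: pd.DataFrame,
    min_controls: int = 10,
    scale_floor: float = 0.2,
    adapt_scale: bool = True,
) -> SiteAdaptation:
    """Estimate offset/scale for every unseen site in the adaptation table.

    Offsets use the closed-form posterior mean under N(0, tau_offset^2);
    scales use a MAP solve under the log-normal hyperprior, floored at
    ``scale_floor``.  Sites with fewer than ``min_controls`` subjects are
    flagged (not dropped).
    """
    _check_roi_table(adaptation_controls)
    if len(adaptation_controls) == 0:
        raise ValidationError("empty adaptation set")
    overlap = set(adaptation_controls["site_id"]) & set(model.site_offsets)
    if overlap:
        raise ValidationError(f"sites already in the reference model: {sorted(overlap)}")

    rows = []
    n_controls: dict[str, int] = {}
    flagged: list[str] = []
    for site, site_df in adaptation_controls.groupby("site_id", sort=True):
        wide = site_df.pivot(index="subject_id", columns="region_id", values="thickness")
        missing = [r for r in model.regions if r not in wide.columns]
        if missing:
            raise ValidationError(f"site {site!r} adaptation data missing regions {missing}")
        meta = site_df.drop_duplicates("subject_id").set_index("subject_id").loc[wide.index]
        age = meta["age"].to_numpy(dtype=float)
        male = (meta["sex"] == "M").to_numpy(dtype=float)
        n = len(wide)
        n_controls[str(site)] = n
        if n < min_controls:
            flagged.append(str(site))
            warnings.warn(
                f"site {site!r} has {n} adaptation controls (< {min_controls})", stacklevel=2
            )
        for region in model.regions:
            p = model.params[region]
            r = wide[region].to_numpy(dtype=float) - model.predict_mean(region, age, male)
            tau2 = p.tau_offset**2
            delta = float(r.mean() * tau2 / (tau2 + p.sigma**2 / n)) if tau2 > 0 else 0.0
            if not adapt_scale or n < 2:
                gamma = 1.0
            else:
                e = r - delta
                A = float(np.sum(e**2) / p.sigma**2)
                gamma = max(np.exp(_map_log_scale(A, n, p.tau_scale)), scale_floor)
            rows.append((str(site), region, delta, gamma))
        if n < 2:
            warnings.warn(f"site {site!r}: single control, scale forced to 1", stacklevel=2)
    table = pd.DataFrame(rows, columns=["site_id", "region_id", "offset", "scale"])
    return SiteAdaptation(table=table, n_controls=n_controls, flagged_sites=flagged,
                          min_controls=min_controls)


def compute_zscores(
    test: pd.DataFrame,
    model: NormativeModel,
    adaptations: SiteAdaptation | None = None,
) -> DeviationMatrix:
    """Deviation z-scores for test subjects: (y - mu - delta) / (gamma sigma).

    Sites present in the reference model use their fitted offsets/scales;
    all other sites must appear in ``adaptations``.
    """
    _check_roi_table(test)
    if (test["role"] == "adaptation").any():
        raise ValidationError("adaptation-role rows present in test table; discard them first")
    offsets = {s: dict(v) for s, v in model.site_offsets.items()}
    scales = {s: dict(v) for s, v in model.site_scales.items()}
    if adaptations is not None:
        a_off, a_sc = adaptations.lookup()
        offsets.update(a_off)
        scales.update(a_sc)
    missing_sites = sorted(set(test["site_id"]) - set(offsets))
    if missing_sites:
        raise ValidationError(f"no adaptation available for sites: {missing_sites}")

    wide = test.pivot(index="subject_id", columns="region_id", values="thickness")
    missing = [r for r in model.regions if r not in wide.columns]
    if missing:
        raise ValidationError(f"test table missing regions {missing}")
    wide = wide[model.regions]
    meta = (
        test.drop_duplicates("subject_id")
        .set_index("subject_id")
        .loc[wide.index, ["site_id", "sex", "age", "group"]]
    )
    age = meta["age"].to_numpy(dtype=float)
    male = (meta["sex"] == "M").to_numpy(dtype=float)

    Z = np.empty(wide.shape)
    delta = np.array(
        [[offsets[s][r] for r in model.regions] for s in meta["site_id"]], dtype=float
    )
    gamma = np.array(
        [[scales[s][r] for r in model.regions] for s in meta["site_id"]], dtype=float
    )
    for j, region in enumerate(model.regions):
        p = model.params[region]
        mu = model.predict_mean(region, age, male)
        Z[:, j] = (wide[region].to_numpy(dtype=float) - mu - delta[:, j]) / (gamma[:, j] * p.sigma)
    if not np.all(np.isfinite(Z)):
        raise ValidationError("non-finite z-scores produced")
    zdf = pd.DataFrame(Z, index=wide.index, columns=model.regions)
    return DeviationMatrix(z=zdf, covariates=meta)
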