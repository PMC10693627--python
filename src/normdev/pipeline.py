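"""End-to-end pipeline driver: simulate/load -> fit -> adapt -> deviate ->
overlap -> group tests -> outcome models, with a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as ndio
from .clinical import score_panss
from .deviations import extreme_mask, overlap_map
from .errors import ConfigError, ValidationError
from .lme import run_regionwise
from .normative import AgeBasis, adapt_site, compute_zscores, fit_reference, split_adaptation
from .simulate import (
    CohortConfig,
    generate_clinical_sites,
    generate_longitudinal_outcomes,
    generate_reference,
)
from .stats import compare_regions, proportion_chisq

__all__ = ["PipelineConfig", "run_pipeline", "default_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed for one deterministic end-to-end run."""

    seed: int = 0
    adaptation_fraction: float = 0.5
    threshold: float = 2.6
    alpha: float = 0.05
    min_controls: int = 10
    strict_site_exclusion: bool = False
    stratify_by_age: bool = False
    basis_kind: str = "bspline"
    outcomes: list[str] = field(default_factory=lambda: ["negative"])
    outcome_predictor: str = "regional"
    run_outcome_models: bool = True
    # either file paths ...
    reference_path: str | None = None
    clinical_path: str | None = None
    clinical_scores_path: str | None = None
    # ... or inline simulation configs (dicts in CohortConfig layout)
    simulate_reference: dict | None = None
    simulate_clinical: dict | None = None
    simulate_outcomes: bool = False

    def validate(self) -> None:
        if not self.threshold > 0:
            raise ConfigError("threshold must be > 0")
        if not 0 < self.adaptation_fraction < 1:
            raise ConfigError("adaptation_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_controls < 1:
            raise ConfigError("min_controls must be >= 1")
        if self.reference_path is None and self.simulate_reference is None:
            raise ConfigError("either reference_path or simulate_reference is required")
        if self.clinical_path is None and self.simulate_clinical is None:
            raise ConfigError("either clinical_path or simulate_clinical is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(seed: int = 0) -> PipelineConfig:
    """Small fully-synthetic configuration used for smoke runs and demos."""
    reference = {
        "n_regions": 30,
        "sites": [
            {"site_id": f"ref{i}", "n_controls": 60, "offset_mm": off, "scale_factor": sc}
            for i, (off, sc) in enumerate(
                [(0.15, 1.0), (-0.15, 1.05), (0.25, 0.95), (-0.25, 1.0)]
            )
        ],
        "seed": seed,
    }
    clinical = {
        "n_regions": 30,
        "sites": [
            {"site_id": "clinA", "n_controls": 30, "n_patients": 30, "offset_mm": 0.1},
            {"site_id": "clinB", "n_controls": 24, "n_patients": 24, "offset_mm": -0.1,
             "scale_factor": 1.1},
        ],
        "patient_deviation": {
            "n_extreme_regions_mean": 3.0,
            "magnitude_sd_units": -4.0,
            "diffuse_shift_sd_units": -0.3,
        },
        "seed": seed,
    }
    return PipelineConfig(
        seed=seed,
        simulate_reference=reference,
        simulate_clinical=clinical,
        simulate_outcomes=True,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages, write every output CSV plus manifest.json.

    Returns the manifest dictionary.  Any stage failure is re-raised with
    the stage name prepended.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "excluded_sites": [],
        "excluded_subjects": [],
    }

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                manifest["stages"].setdefault(name, {})
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                manifest["stages"].setdefault(name, {})["seconds"] = round(dt, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, dt)

        return _Stage()

    with stage("inputs"):
        if config.simulate_reference is not None:
            ref_cfg = CohortConfig.from_dict(config.simulate_reference)
            reference = generate_reference(ref_cfg, seed=config.seed)
        else:
            reference = ndio.read_roi_table(config.reference_path)
        if config.simulate_clinical is not None:
            clin_cfg = CohortConfig.from_dict(config.simulate_clinical)
            clinical, injections = generate_clinical_sites(clin_cfg, seed=config.seed)
            injections.to_csv(out / "injections.csv", index=False)
        else:
            clinical = ndio.read_roi_table(config.clinical_path)
            injections = None
        ndio.write_roi_table(reference, out / "reference.csv")
        ndio.write_roi_table(clinical, out / "clinical.csv")
        manifest["stages"]["inputs"].update(
            n_reference_rows=len(reference), n_clinical_rows=len(clinical)
        )

    with stage("fit_reference"):
        ages = reference["age"]
        basis = AgeBasis(kind=config.basis_kind, lo=float(ages.min()), hi=float(ages.max()))
        model = fit_reference(reference, basis=basis)
        model.save(out / "normative_model.json")
        manifest["stages"]["fit_reference"].update(
            n_regions=len(model.regions), excluded_regions=model.excluded_regions
        )

    with stage("split_adaptation"):
        controls = clinical[clinical["group"] == "control"]
        patients = clinical[clinical["group"] == "patient"]
        adaptation, test_controls = split_adaptation(
            controls, fraction=config.adaptation_fraction, seed=config.seed,
            stratify_by_age=config.stratify_by_age,
        )
        manifest["stages"]["split_adaptation"].update(
            n_adaptation_subjects=adaptation["subject_id"].nunique(),
            n_test_control_subjects=test_controls["subject_id"].nunique(),
        )

    with stage("adapt"):
        adaptations = adapt_site(model, adaptation, min_controls=config.min_controls)
        adaptations.table.to_csv(out / "site_adaptation.csv", index=False)
        manifest["stages"]["adapt"].update(
            n_controls=adaptations.n_controls, flagged_sites=adaptations.flagged_sites
        )

    with stage("zscores"):
        test = pd.concat([test_controls, patients], ignore_index=True)
        if config.strict_site_exclusion and adaptations.flagged_sites:
            excl = test["site_id"].isin(adaptations.flagged_sites)
            manifest["excluded_sites"] = sorted(adaptations.flagged_sites)
            manifest["excluded_subjects"] = sorted(test.loc[excl, "subject_id"].unique())
            test = test[~excl]
        dev = compute_zscores(test, model, adaptations)
        ndio.write_deviations(dev, out / "zscores.csv", out / "zscore_covariates.csv")
        manifest["stages"]["zscores"].update(n_test_subjects=len(dev.z))

    with stage("overlap"):
        mask = extreme_mask(dev, threshold=config.threshold)
        regional, summary = overlap_map(mask)
        regional.to_csv(out / "overlap_regional.csv", index=False)
        summary.to_csv(out / "overlap_summary.csv", index=False)
        manifest["stages"]["overlap"].update(
            proportions={f"{r.group}/{r.sign}": r.proportion_pct for r in summary.itertuples()}
        )

    with stage("group_tests"):
        results = compare_regions(dev, alpha=config.alpha)
        results.to_csv(out / "group_tests.csv", index=False)
        # sensitivity-style proportion test on extreme negative cell counts
        pat = mask.group_index("patient") if "patient" in set(mask.covariates["group"]) else []
        con = mask.group_index("control") if "control" in set(mask.covariates["group"]) else []
        if len(pat) and len(con):
            n_regions = mask.negative.shape[1]
            chi = proportion_chisq(
                int(mask.negative.loc[pat].to_numpy().sum()), len(pat) * n_regions,
                int(mask.negative.loc[con].to_numpy().sum()), len(con) * n_regions,
            )
            manifest["stages"]["group_tests"].update(
                chisq=chi.statistic, chisq_p=chi.pvalue,
                n_significant=int(results["significant"].sum()),
            )

    with stage("outcomes"):
        scores = None
        if config.clinical_scores_path is not None:
            scores = score_panss(ndio.read_clinical(config.clinical_scores_path))
        elif config.simulate_outcomes and config.simulate_clinical is not None:
            panss = generate_longitudinal_outcomes(dev, clin_cfg, seed=config.seed)
            scores = score_panss(panss)
            ndio.write_clinical(scores, out / "clinical_scores.csv")
        if scores is not None and config.run_outcome_models:
            for outcome in config.outcomes:
                res = run_regionwise(
                    dev, scores, outcome=outcome, alpha=config.alpha,
                    predictor=config.outcome_predictor,
                )
                res.to_csv(out / f"outcome_{outcome}.csv", index=False)
                manifest["stages"]["outcomes"][f"{outcome}_n_significant"] = int(
                    res["significant"].sum()
                )
        manifest["stages"]["outcomes"]["ran"] = bool(
            scores is not None and config.run_outcome_models
        )

    # manifest cross-check: adaptation and test subjects must be disjoint
    overlap_ids = set(adaptation["subject_id"]) & set(dev.z.index)
    if overlap_ids:
        raise RuntimeError(f"adaptation subjects leaked into test outputs: {sorted(overlap_ids)}")
    manifest["n_test_subjects"] = int(len(dev.z))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True),
                                       encoding="utf-8")
    return manifest
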