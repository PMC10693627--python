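"""Shared fixtures: small synthetic cohorts and fitted models (session-scoped)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import normdev as nd
from normdev.normative import AgeBasis


def make_reference_config(n_regions=12, n_per_site=80, seed=0):
    return nd.CohortConfig(
        n_regions=n_regions,
        sites=[
            nd.SiteSpec("refA", n_per_site, 0, 0.20, 1.0),
            nd.SiteSpec("refB", n_per_site, 0, -0.20, 1.05),
            nd.SiteSpec("refC", n_per_site, 0, 0.10, 0.95),
            nd.SiteSpec("refD", n_per_site, 0, -0.10, 1.0),
        ],
        seed=seed,
    )


def make_clinical_config(n_regions=12, n_controls=30, n_patients=30, seed=0, **dev_kwargs):
    dev = dict(n_extreme_regions_mean=3.0, magnitude_sd_units=-4.0, diffuse_shift_sd_units=-0.3)
    dev.update(dev_kwargs)
    return nd.CohortConfig(
        n_regions=n_regions,
        sites=[
            nd.SiteSpec("clinA", n_controls, n_patients, 0.12, 1.0),
            nd.SiteSpec("clinB", n_controls, n_patients, -0.12, 1.1),
        ],
        patient_deviation=nd.PatientDeviationSpec(**dev),
        seed=seed,
    )


@pytest.fixture(scope="session")
def reference_table():
    return nd.generate_reference(make_reference_config(), seed=11)


@pytest.fixture(scope="session")
def reference_model(reference_table):
    ages = reference_table["age"]
    basis = AgeBasis(lo=float(ages.min()), hi=float(ages.max()))
    return nd.fit_reference(reference_table, basis=basis)


@pytest.fixture(scope="session")
def clinical_tables():
    table, injections = nd.generate_clinical_sites(make_clinical_config(), seed=12)
    return table, injections


@pytest.fixture(scope="session")
def deviation_matrix(reference_model, clinical_tables):
    table, _ = clinical_tables
    controls = table[table["group"] == "control"]
    patients = table[table["group"] == "patient"]
    adaptation, test_controls = nd.split_adaptation(controls, 0.5, seed=13)
    adaptations = nd.adapt_site(reference_model, adaptation)
    test = pd.concat([test_controls, patients], ignore_index=True)
    return nd.compute_zscores(test, reference_model, adaptations)


@pytest.fixture()
def toy_deviations():
    """Hand-sized deviation matrix for mask/overlap arithmetic."""
    rng = np.random.default_rng(5)
    subjects = [f"s{i}" for i in range(8)]
    regions = [f"region_{i:03d}" for i in range(1, 5)]
    z = pd.DataFrame(rng.normal(size=(8, 4)), index=subjects, columns=regions)
    cov = pd.DataFrame(
        {
            "site_id": "x",
            "sex": ["F", "M"] * 4,
            "age": 30.0,
            "group": ["patient"] * 4 + ["control"] * 4,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    return nd.DeviationMatrix(z=z, covariates=cov)
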