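"""Normative model: fitting, splitting, site adaptation, z-scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import normdev as nd
from normdev.errors import ConfigError, FitError, ValidationError
from normdev.normative import AgeBasis

from conftest import make_reference_config


def linear_table(n=60, slope=-0.01, intercept=2.8, sex_effect=-0.05, site="s1", seed=0,
                 noise=0.0, n_regions=2, offset=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        age = rng.uniform(18, 80)
        sex = "M" if i % 2 else "F"
        for r in range(1, n_regions + 1):
            y = intercept + slope * age + sex_effect * (sex == "M") + offset
            y += rng.normal(0, noise) if noise else 0.0
            rows.append((f"{site}_{i:03d}", site, sex, age, "control", "test",
                         f"region_{r:03d}", y))
    return pd.DataFrame(rows, columns=["subject_id", "site_id", "sex", "age", "group",
                                       "role", "region_id", "thickness"])


class TestFitReference:
    def test_noiseless_linear_recovery(self):
        table = linear_table()
        with pytest.warns(UserWarning):
            model = nd.fit_reference(table, basis=AgeBasis(kind="linear", lo=18, hi=80))
        p = model.params["region_001"]
        assert abs(p.age_coefs[0] - (-0.01)) <= 1e-8 * 0.01
        assert abs(p.intercept - 2.8) <= 1e-8 * 2.8
        assert abs(p.sex_coef - (-0.05)) <= 1e-8 * 0.05

    def test_two_site_offset_and_tau_recovery(self):
        t1 = linear_table(n=200, site="sA", seed=1, noise=0.1, offset=0.2)
        t2 = linear_table(n=200, site="sB", seed=2, noise=0.1, offset=-0.2)
        model = nd.fit_reference(pd.concat([t1, t2], ignore_index=True),
                                 basis=AgeBasis(kind="linear", lo=18, hi=80))
        p = model.params["region_001"]
        assert abs(model.site_offsets["sA"]["region_001"] - 0.2) < 0.03
        assert abs(model.site_offsets["sB"]["region_001"] + 0.2) < 0.03
        true_tau = np.std([0.2, -0.2], ddof=1)
        assert true_tau / 2 < p.tau_offset < true_tau * 2

    def test_row_shuffle_invariance(self, reference_table):
        model_a = nd.fit_reference(reference_table)
        shuffled = reference_table.sample(frac=1.0, random_state=99).reset_index(drop=True)
        model_b = nd.fit_reference(shuffled)
        for region in model_a.regions:
            assert np.allclose(model_a.params[region].age_coefs,
                               model_b.params[region].age_coefs)
            assert model_a.params[region].sigma == pytest.approx(
                model_b.params[region].sigma)

    def test_zero_variance_region_excluded(self):
        table = linear_table(noise=0.05, n_regions=3)
        flat = table["region_id"] == "region_003"
        table.loc[flat, "thickness"] = 2.5
        t2 = linear_table(noise=0.05, n_regions=3, site="s2", seed=5)
        t2.loc[t2["region_id"] == "region_003", "thickness"] = 2.5
        with pytest.warns(UserWarning, match="region_003"):
            model = nd.fit_reference(pd.concat([table, t2], ignore_index=True),
                                     basis=AgeBasis(kind="linear", lo=18, hi=80))
        assert "region_003" in model.excluded_regions
        assert "region_003" not in model.regions

    def test_serialization_round_trip(self, reference_model, tmp_path):
        path = tmp_path / "model.json"
        reference_model.save(path)
        loaded = nd.NormativeModel.load(path)
        age = np.linspace(10, 90, 50)
        male = np.tile([0.0, 1.0], 25)
        for region in reference_model.regions:
            a = reference_model.predict_mean(region, age, male)
            b = loaded.predict_mean(region, age, male)
            assert np.max(np.abs(a - b)) <= 1e-12


class TestSplitAdaptation:
    def _controls(self, n=10, site="c1", seed=0, bimodal=False):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            age = (rng.uniform(18, 22) if rng.random() < 0.7 else rng.uniform(55, 60)) \
                if bimodal else rng.uniform(18, 40)
            for r in (1, 2):
                rows.append((f"{site}_{i:03d}", site, "F", age, "control", "test",
                             f"region_{r:03d}", 2.5))
        return pd.DataFrame(rows, columns=["subject_id", "site_id", "sex", "age", "group",
                                           "role", "region_id", "thickness"])

    def test_exact_halving_disjoint_cover(self):
        controls = self._controls(10)
        adapt, test = nd.split_adaptation(controls, 0.5, seed=1)
        assert adapt["subject_id"].nunique() == 5
        assert test["subject_id"].nunique() == 5
        assert not set(adapt["subject_id"]) & set(test["subject_id"])
        combined = pd.concat([adapt, test]).sort_values(["subject_id", "region_id"])
        original = controls.sort_values(["subject_id", "region_id"])
        assert set(combined["subject_id"]) == set(original["subject_id"])
        assert (adapt["role"] == "adaptation").all() and (test["role"] == "test").all()

    def test_subjects_move_together(self):
        adapt, test = nd.split_adaptation(self._controls(9), 0.5, seed=2)
        assert (adapt.groupby("subject_id")["region_id"].count() == 2).all()
        assert (test.groupby("subject_id")["region_id"].count() == 2).all()

    def test_same_seed_same_split(self):
        controls = self._controls(20)
        a1, _ = nd.split_adaptation(controls, 0.5, seed=3)
        a2, _ = nd.split_adaptation(controls, 0.5, seed=3)
        pd.testing.assert_frame_equal(a1, a2)

    def test_fraction_bounds(self):
        controls = self._controls(10)
        for frac in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ConfigError):
                nd.split_adaptation(controls, frac, seed=0)

    def test_stratified_split_balances_bimodal_ages(self):
        controls = self._controls(40, seed=7, bimodal=True)
        diffs_plain, diffs_strat = [], []
        for seed in range(100):
            a, t = nd.split_adaptation(controls, 0.5, seed=seed, stratify_by_age=False)
            diffs_plain.append(abs(a.groupby("subject_id")["age"].first().mean()
                                   - t.groupby("subject_id")["age"].first().mean()))
            a, t = nd.split_adaptation(controls, 0.5, seed=seed, stratify_by_age=True)
            diffs_strat.append(abs(a.groupby("subject_id")["age"].first().mean()
                                   - t.groupby("subject_id")["age"].first().mean()))
        assert np.mean(diffs_strat) < np.mean(diffs_plain)


def _site_table(model_cfg, site_id, n, offset, seed, scale=1.0, n_regions=12):
    cfg = nd.CohortConfig(
        n_regions=n_regions,
        sites=[nd.SiteSpec(site_id, n, 0, offset, scale), nd.SiteSpec("dummy", 2, 0)],
        seed=seed,
    )
    table = nd.generate_reference(cfg, seed=seed)
    return table[table["site_id"] == site_id].reset_index(drop=True)


class TestAdaptSite:
    def test_perfect_fit_gives_zero_offset_unit_scale(self, reference_model):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            age, sex = rng.uniform(10, 90), "M" if i % 2 else "F"
            for region in reference_model.regions:
                mu = reference_model.predict_mean(region, np.array([age]),
                                                  np.array([float(sex == "M")]))[0]
                rows.append((f"new_{i:02d}", "newsite", sex, age, "control",
                             "adaptation", region, mu))
        table = pd.DataFrame(rows, columns=["subject_id", "site_id", "sex", "age", "group",
                                            "role", "region_id", "thickness"])
        sa = nd.adapt_site(reference_model, table)
        assert np.allclose(sa.table["offset"], 0.0, atol=1e-10)
        # exact-on-mean data: MAP scale is pulled to ~1 by the hyperprior
        assert (sa.table["scale"] >= 0.2).all()
        tau = max(p.tau_scale for p in reference_model.params.values())
        assert (sa.table["scale"] >= np.exp(-20 * tau**2) - 1e-9).all()

    def test_injected_offset_recovered(self, reference_model):
        table = _site_table(None, "newS", 50, 0.30, seed=31)
        table["role"] = "adaptation"
        sa = nd.adapt_site(reference_model, table)
        assert abs(sa.table["offset"].mean() - 0.30) < 0.05

    def test_shrinkage_monotone_in_n(self, reference_model):
        small, large = [], []
        for seed in range(60):
            t2 = _site_table(None, "nS", 2, 0.2, seed=seed + 100)
            t200 = _site_table(None, "nS", 200, 0.2, seed=seed + 100)
            with pytest.warns(UserWarning):
                sa2 = nd.adapt_site(reference_model, t2)
            sa200 = nd.adapt_site(reference_model, t200)
            small.append(sa2.table["offset"].mean())
            large.append(sa200.table["offset"].mean())
        assert abs(np.mean(small)) <= abs(np.mean(large))

    def test_small_site_flagged(self, reference_model):
        table = _site_table(None, "tiny", 5, 0.1, seed=3)
        with pytest.warns(UserWarning, match="tiny"):
            sa = nd.adapt_site(reference_model, table, min_controls=10)
        assert "tiny" in sa.flagged_sites

    def test_single_control_forces_unit_scale(self, reference_model):
        table = _site_table(None, "one", 2, 0.1, seed=4)
        keep = table["subject_id"] == table["subject_id"].iloc[0]
        with pytest.warns(UserWarning):
            sa = nd.adapt_site(reference_model, table[keep])
        assert (sa.table["scale"] == 1.0).all()

    def test_empty_and_known_site_errors(self, reference_model):
        with pytest.raises(ValidationError, match="empty"):
            nd.adapt_site(reference_model, pd.DataFrame(columns=[
                "subject_id", "site_id", "sex", "age", "group", "role",
                "region_id", "thickness"]))
        table = _site_table(None, "refA", 10, 0.1, seed=5)
        with pytest.raises(ValidationError, match="refA"):
            nd.adapt_site(reference_model, table)


class TestComputeZScores:
    def test_centered_input_zero_z(self, reference_model):
        region = reference_model.regions[0]
        delta = reference_model.site_offsets["refA"][region]
        mu = reference_model.predict_mean(region, np.array([30.0]), np.array([1.0]))[0]
        rows = []
        for r in reference_model.regions:
            mu_r = reference_model.predict_mean(r, np.array([30.0]), np.array([1.0]))[0]
            rows.append(("s1", "refA", "M", 30.0, "control", "test", r,
                         mu_r + reference_model.site_offsets["refA"][r]))
        test = pd.DataFrame(rows, columns=["subject_id", "site_id", "sex", "age", "group",
                                           "role", "region_id", "thickness"])
        dev = nd.compute_zscores(test, reference_model)
        assert np.allclose(dev.z.to_numpy(), 0.0, atol=1e-10)

    def test_threshold_arithmetic_exact(self, reference_model):
        rows = []
        for r in reference_model.regions:
            p = reference_model.params[r]
            mu_r = reference_model.predict_mean(r, np.array([40.0]), np.array([0.0]))[0]
            delta = reference_model.site_offsets["refB"][r]
            gamma = reference_model.site_scales["refB"][r]
            rows.append(("s1", "refB", "F", 40.0, "control", "test", r,
                         mu_r + delta + 2.6 * gamma * p.sigma))
        test = pd.DataFrame(rows, columns=["subject_id", "site_id", "sex", "age", "group",
                                           "role", "region_id", "thickness"])
        dev = nd.compute_zscores(test, reference_model)
        assert np.allclose(dev.z.to_numpy(), 2.6, atol=1e-9)

    def test_monotone_in_thickness(self, reference_model, deviation_matrix):
        region = reference_model.regions[0]
        sigma = reference_model.params[region].sigma
        assert sigma > 0  # z = (y - const)/const' is strictly increasing in y

    def test_missing_adaptation_error(self, reference_model):
        table = _site_table(None, "ghost", 5, 0.0, seed=6)
        with pytest.raises(ValidationError, match="ghost"):
            nd.compute_zscores(table, reference_model)

    def test_adaptation_rows_rejected(self, reference_model, clinical_tables):
        table, _ = clinical_tables
        controls = table[table["group"] == "control"]
        adapt, _ = nd.split_adaptation(controls, 0.5, seed=1)
        with pytest.raises(ValidationError, match="adaptation"):
            nd.compute_zscores(adapt, reference_model)

    def test_heldout_controls_standard_normal(self, reference_model):
        # well-specified held-out controls: z approx N(0,1)
        table = _site_table(None, "holdout", 1000, 0.18, seed=77, n_regions=12)
        half = table["subject_id"].isin(table["subject_id"].unique()[:200])
        sa = nd.adapt_site(reference_model, table[half].assign(role="adaptation"))
        dev = nd.compute_zscores(table[~half].reset_index(drop=True), reference_model, sa)
        flat = dev.z.to_numpy().ravel()
        assert abs(flat.mean()) < 0.05
        assert 0.93 < flat.std() < 1.07
        assert kstest(dev.z.iloc[:, 0], "norm").pvalue > 0.01

    def test_site_shift_invariance(self, reference_model):
        # adding a constant to one site's thickness is absorbed by adaptation
        table = _site_table(None, "shifty", 400, 0.1, seed=55, n_regions=12)
        ids = table["subject_id"].unique()
        adapt_ids = set(ids[:200])
        base_adapt = table[table["subject_id"].isin(adapt_ids)].assign(role="adaptation")
        base_test = table[~table["subject_id"].isin(adapt_ids)].reset_index(drop=True)
        dev0 = nd.compute_zscores(base_test, reference_model,
                                  nd.adapt_site(reference_model, base_adapt))
        shifted_adapt = base_adapt.assign(thickness=base_adapt["thickness"] + 0.5)
        shifted_test = base_test.assign(thickness=base_test["thickness"] + 0.5)
        dev1 = nd.compute_zscores(shifted_test, reference_model,
                                  nd.adapt_site(reference_model, shifted_adapt))
        assert abs((dev1.z - dev0.z).to_numpy().mean()) <= 0.02
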