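"""Design assembly, the Bayesian bivariate fit, K-fold IC, envfit and friends.

MCMC-dependent tests run at deliberately light sampler settings; the deeper
statistical calibration checks (bias, coverage, model selection) live in the
acceptance suite.
"""

import numpy as np
import pytest

from fightdyn import (
    SimScenario,
    bayes_r2,
    build_design,
    correlogram,
    envfit_vectors,
    fit_linkage,
    kfold_ic,
    marginal_effects,
    pca,
    pcoa,
    pairwise_dissimilarity,
    simulate_dataset,
    simulate_design,
)
from fightdyn.errors import ParameterError, ValidationError
from fightdyn.metrics import metrics_matrix
from tests.conftest import make_dataset_from_actvsum

LIGHT = dict(chains=2, warmup=300, draws=300)


@pytest.fixture(scope="module")
def hp_y_setup():
    dataset, _ = simulate_dataset(SimScenario(seed=42))
    ordination = pcoa(pairwise_dissimilarity(dataset, "highpass", "Y"))
    design = build_design(dataset, ordination)
    fit = fit_linkage(design, seed=7, **LIGHT)
    return dataset, ordination, design, fit


class TestBuildDesign:
    def test_summary_pipeline_has_seven_predictors(self, default_dataset):
        dataset, _ = default_dataset
        ordination = pca(metrics_matrix(dataset))
        design = build_design(dataset, ordination, include_duration=True)
        assert design.p == 7
        assert design.predictor_names[-1] == "fight_duration"

    def test_dtw_pipeline_has_six_predictors(self, hp_y_setup):
        _, _, design, _ = hp_y_setup
        assert design.p == 6
        assert "fight_duration" not in design.predictor_names

    def test_missing_physiology_names_fish(self, default_dataset):
        dataset, _ = default_dataset
        import copy

        ds = copy.deepcopy(dataset)
        some_id = ds.fish_ids[3]
        ds.records[some_id].lactate = None
        ordination = pcoa(pairwise_dissimilarity(ds, "raw", "X"))
        with pytest.raises(ValidationError, match=some_id):
            build_design(ds, ordination)

    def test_species_indicator_reference_chinook(self, hp_y_setup):
        dataset, _, design, _ = hp_y_setup
        j = design.predictor_names.index("species_coho")
        coho = {fid for fid, r in dataset.records.items() if r.species == "coho"}
        for i, fid in enumerate(design.ids):
            assert design.X[i, j] == (1.0 if fid in coho else 0.0)


class TestFit:
    def test_seed_determinism(self, hp_y_setup):
        _, _, design, fit = hp_y_setup
        fit2 = fit_linkage(design, seed=7, **LIGHT)
        np.testing.assert_array_equal(fit.beta_draws, fit2.beta_draws)
        np.testing.assert_array_equal(fit.rho_draws, fit2.rho_draws)

    def test_ci_significance_consistency(self, hp_y_setup):
        _, _, _, fit = hp_y_setup
        for pname, row in fit.summary.iterrows():
            flagged = pname in fit.significant_dims or pname in fit.significant_covariates
            excludes_zero = row["ci_2.5"] > 0 or row["ci_97.5"] < 0
            is_candidate = pname.split(":")[0].startswith("Dim") or pname.split(":")[0] in (
                "species_coho", "body_mass", "water_temp", "fight_duration",
            )
            assert flagged == (excludes_zero and is_candidate)

    def test_rho_in_open_interval(self, hp_y_setup):
        _, _, _, fit = hp_y_setup
        assert np.all(np.abs(fit.rho_draws) < 1.0)

    def test_diagnostics_present(self, hp_y_setup):
        _, _, _, fit = hp_y_setup
        assert {"rhat", "ess_ratio"} <= set(fit.summary.columns)
        assert (fit.summary["ess_ratio"] > 0).all()


class TestBayesR2:
    def test_bounds(self, hp_y_setup):
        _, _, _, fit = hp_y_setup
        r2 = bayes_r2(fit)
        assert 0 <= r2["blood_ph"] <= 1 and 0 <= r2["lactate"] <= 1
        assert r2["mean"] == pytest.approx((r2["blood_ph"] + r2["lactate"]) / 2)

    def test_near_noiseless_limit(self):
        design, _ = simulate_design(n=120, sigma=0.01, seed=5)
        fit = fit_linkage(design, seed=5, **LIGHT)
        assert bayes_r2(fit)["mean"] > 0.99


class TestKfold:
    def test_partition_covers_each_row_once(self, hp_y_setup):
        _, _, design, _ = hp_y_setup
        ic, assignment = kfold_ic(design, folds=7, seed=3, **LIGHT)
        assert len(assignment) == design.n
        counts = np.bincount(assignment, minlength=7)
        assert counts.max() - counts.min() <= 1
        assert np.isfinite(ic)

    def test_seed_reproducible(self, hp_y_setup):
        _, _, design, _ = hp_y_setup
        a, _ = kfold_ic(design, folds=5, seed=11, **LIGHT)
        b, _ = kfold_ic(design, folds=5, seed=11, **LIGHT)
        assert a == b

    def test_too_many_folds(self, hp_y_setup):
        _, _, design, _ = hp_y_setup
        with pytest.raises(ParameterError, match="fold"):
            kfold_ic(design, folds=design.n + 1, seed=0, **LIGHT)


class TestEnvfit:
    def test_perfect_alignment_with_dim1(self, hp_y_setup):
        _, ordination, _, _ = hp_y_setup
        v = ordination.scores[:, 0].copy()
        res = envfit_vectors(ordination, {"v": v}, permutations=199, seed=0)["v"]
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert abs(res.direction[0]) == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1 / 200)

    def test_null_variable_large_p(self, hp_y_setup):
        _, ordination, _, _ = hp_y_setup
        rng = np.random.default_rng(1)
        # residualize random noise against the scores so r2 is ~0 by construction
        v = rng.standard_normal(len(ordination.ids))
        X = np.column_stack([np.ones(len(v)), ordination.scores])
        v -= X @ np.linalg.lstsq(X, v, rcond=None)[0]
        res = envfit_vectors(ordination, {"v": v}, permutations=199, seed=2)["v"]
        assert res.r2 < 1e-9
        assert res.p_value > 0.5

    def test_p_floor(self, hp_y_setup):
        _, ordination, _, _ = hp_y_setup
        res = envfit_vectors(
            ordination, {"v": ordination.scores[:, 1]}, permutations=999, seed=3
        )["v"]
        assert res.p_value >= 1 / 1000


class TestMarginalEffects:
    def test_curve_structure_and_band(self, hp_y_setup):
        _, _, design, fit = hp_y_setup
        curve = marginal_effects(fit, "Dim1", grid_size=20)
        assert set(curve["response"]) == {"blood_ph", "lactate"}
        assert ((curve["ci_2.5"] <= curve["median"]) & (curve["median"] <= curve["ci_97.5"])).all()

    def test_positive_coefficient_monotone_curve(self):
        design, _ = simulate_design(n=150, beta_dim=(1.5, 0.0, 0.0), sigma=0.2, seed=9)
        fit = fit_linkage(design, seed=9, **LIGHT)
        curve = marginal_effects(fit, "Dim1", grid_size=15)
        med = curve[curve["response"] == "lactate"]["median"].to_numpy()
        assert np.all(np.diff(med) > 0)

    def test_unknown_predictor(self, hp_y_setup):
        _, _, _, fit = hp_y_setup
        with pytest.raises(ParameterError):
            marginal_effects(fit, "Dim9")


class TestCorrelogram:
    def test_shape_and_symmetry(self, default_dataset):
        dataset, _ = default_dataset
        cg = correlogram(dataset)
        assert cg.shape == (8, 8)
        np.testing.assert_allclose(np.diag(cg), 1.0)
        np.testing.assert_allclose(cg.values, cg.values.T, atol=1e-15)

    def test_near_constant_actvsum_effort_tracks_duration(self):
        # effort = cumulative ActVSum, so at a (near-)flat per-sample level the
        # effort/duration correlation is driven to 1; small spike counts break
        # the degeneracy of the other columns without disturbing linearity
        rng = np.random.default_rng(2)
        from fightdyn import FishRecord

        act = {}
        for i, n in enumerate([10, 20, 30, 40, 55]):
            a = np.full(n, 0.9)
            a[0 : 2 * (i + 1) : 2] = 1.3  # i+1 isolated burst samples
            a[-1] += 1e-5 * (i + 1)
            act[f"f{i}"] = a
        recs = {}
        for i, fid in enumerate(act):
            recs[fid] = FishRecord(
                fish_id=fid, species="chinook", fork_length=70 + i, girth=35.0 + i,
                water_temp=13.0 + i, blood_ph=7.6 + 0.01 * rng.standard_normal(),
                lactate=15.0 + rng.standard_normal(),
            )
        ds = make_dataset_from_actvsum(act, records=recs)
        cg = correlogram(ds)
        assert cg.loc["total_effort", "fight_duration"] == pytest.approx(1.0, abs=1e-3)
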