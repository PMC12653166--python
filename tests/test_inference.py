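import numpy as np
import pandas as pd
import pytest

from oslm.design import ComponentSpec, TestDesign, build_practice_matrix
from oslm.inference import (
    PosteriorDraws,
    SamplerConfig,
    classify_individuals,
    fit,
    posterior_probability,
    summarize,
    trajectories,
)
from oslm.models import ModelSpec, ResponseData
from oslm.simulate import generate_persons, simulate_responses

from conftest import scaled_generating_parameters


def make_fake_draws(param_draws: dict, n: int = 3, J: int = 2) -> PosteriorDraws:
    """Hand-built PosteriorDraws for summary-level unit tests."""
    names = ["r1", "r2"]
    W = np.ones((J, 2))
    design = TestDesign([ComponentSpec(x) for x in names], W)
    some = next(iter(param_draws.values()))
    chains, ndraws = some.shape[:2]
    return PosteriorDraws(
        spec=ModelSpec.rwoslm(names),
        design=design,
        practice=build_practice_matrix(design),
        data=ResponseData(X=np.zeros((n, J), dtype=int)),
        config=SamplerConfig.fast(),
        draws=param_draws,
        log_lik=np.zeros((chains, ndraws, n, J), dtype=np.float32),
        labels={"delta": names},
    )


class TestSamplerConfig:
    def test_defaults_mirror_reference_settings(self):
        cfg = SamplerConfig()
        assert cfg.chains == 4
        assert cfg.iterations == 5000
        assert cfg.n_warmup == 2500
        assert cfg.n_draws == 2500

    def test_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(chains=0)
        with pytest.raises(ValueError):
            SamplerConfig(iterations=999)
        with pytest.raises(ValueError):
            SamplerConfig(warmup_fraction=0.0)


class TestSummarize:
    def test_eap_is_mean(self):
        d = make_fake_draws({"mu_delta": np.array([1.0, 2, 3, 4]).reshape(1, 4, 1)})
        s = summarize(d)
        assert s.loc["mu_delta[r1]", "EAP"] == pytest.approx(2.5)

    def test_constant_draws(self):
        d = make_fake_draws({"mu_delta": np.full((2, 10, 1), 1.7)})
        with pytest.warns(UserWarning, match="constant"):
            s = summarize(d)
        row = s.loc["mu_delta[r1]"]
        assert row["SD"] == 0.0
        assert row["2.5%"] == row["97.5%"] == 1.7
        assert np.isnan(row["Rhat"])

    def test_quantiles_match_sort_oracle(self, rng):
        x = rng.standard_normal((2, 400, 1))
        d = make_fake_draws({"mu_delta": x})
        s = summarize(d)
        flat = np.sort(x.reshape(-1))
        assert s.loc["mu_delta[r1]", "2.5%"] == pytest.approx(
            np.quantile(flat, 0.025), abs=1e-12
        )
        assert s.loc["mu_delta[r1]", "97.5%"] == pytest.approx(
            np.quantile(flat, 0.975), abs=1e-12
        )
        assert s.loc["mu_delta[r1]", "2.5%"] <= s.loc["mu_delta[r1]", "EAP"]
        assert s.loc["mu_delta[r1]", "EAP"] <= s.loc["mu_delta[r1]", "97.5%"]

    def test_chain_order_invariance(self, rng):
        x = rng.standard_normal((4, 100, 1))
        a = summarize(make_fake_draws({"mu_delta": x}))
        b = summarize(make_fake_draws({"mu_delta": x[::-1]}))
        pd.testing.assert_frame_equal(a, b)

    def test_rhat_warns_on_disagreeing_chains(self, rng):
        x = rng.standard_normal((2, 200, 1)) * 0.1
        x[1] += 5.0
        with pytest.warns(UserWarning, match="R-hat"):
            s = summarize(make_fake_draws({"mu_delta": x}))
        assert s.loc["mu_delta[r1]", "Rhat"] > 1.5


class TestPosteriorProbability:
    def test_two_draws(self):
        d = make_fake_draws({"mu_delta": np.array([-1.0, 1.0]).reshape(1, 2, 1)})
        assert posterior_probability(d, "mu_delta[r1]", ">") == 0.5

    def test_all_negative(self):
        d = make_fake_draws({"mu_delta": -np.ones((1, 50, 1))})
        assert posterior_probability(d, "mu_delta[r1]", ">") == 0.0
        assert posterior_probability(d, "mu_delta[r1]", "<") == 1.0

    def test_counting_oracle(self, rng):
        x = rng.standard_normal((2, 500, 1))
        d = make_fake_draws({"mu_delta": x})
        expected = float(np.sum(x > 0)) / x.size
        assert posterior_probability(d, "mu_delta[r1]", ">") == pytest.approx(expected)

    def test_unknown_parameter(self):
        d = make_fake_draws({"mu_delta": np.zeros((1, 4, 1))})
        with pytest.raises(KeyError):
            posterior_probability(d, "mu_beta[r1]")
        with pytest.raises(ValueError):
            posterior_probability(d, "mu_delta[r1]", direction="!=")


class TestClassifyIndividuals:
    def test_direct_count(self):
        # person EAPs 0.1, -0.2, 0.3 -> proportion 2/3
        delta = np.tile(np.array([0.1, -0.2, 0.3]).reshape(1, 1, 3, 1), (1, 5, 1, 1))
        delta = np.concatenate([delta, np.zeros_like(delta)], axis=-1)
        d = make_fake_draws({"delta": delta})
        table, prop = classify_individuals(d, "r1")
        assert prop == pytest.approx(2 / 3)
        np.testing.assert_allclose(table["eap_delta"], [0.1, -0.2, 0.3])

    def test_all_negative(self):
        delta = -np.abs(np.random.default_rng(0).standard_normal((2, 20, 3, 2)))
        d = make_fake_draws({"delta": delta})
        _, prop = classify_individuals(d, "r2")
        assert prop == 0.0

    def test_non_random_component_rejected(self):
        d = make_fake_draws({"delta": np.zeros((1, 4, 3, 2))})
        with pytest.raises(ValueError, match="random"):
            classify_individuals(d, "not_a_component")


class TestFit:
    def test_prior_only_fit_recovers_hyperprior(self):
        """With zero persons the posterior of mu_delta is its N(0,1) prior."""
        gen = scaled_generating_parameters()
        from oslm.simulate import generate_design
        from conftest import scaled_components

        design = generate_design(J=20, components=scaled_components(), seed=5, generating=gen)
        data = ResponseData(X=np.zeros((0, 20), dtype=int))
        draws = fit(
            gen.model_spec(), design, None, data,
            SamplerConfig.fast(seed=3, chains=2, iterations=3000),
        )
        mu = draws.stacked("mu_delta")
        assert abs(mu.mean()) < 0.12
        assert abs(mu.std() - 1.0) < 0.12

    def test_lltm_parameter_recovery(self, rng):
        """eta EAPs within 3 posterior SDs of generating values."""
        J, M, n = 10, 3, 300
        names = [f"c{m}" for m in range(M)]
        while True:
            W = rng.integers(0, 3, size=(J, M)).astype(float)
            W[0, W.sum(axis=0) == 0] = 1
            if np.linalg.matrix_rank(W) == M:
                break
        design = TestDesign([ComponentSpec(x) for x in names], W)
        eta_true = np.array([-1.0, 0.3, 0.8])
        theta = rng.standard_normal(n)
        logits = theta[:, None] - np.tile(eta_true @ W.T, (n, 1))
        X = (rng.random((n, J)) < 1 / (1 + np.exp(-logits))).astype(int)
        draws = fit(
            ModelSpec.lltm(names), design, None, ResponseData(X=X),
            SamplerConfig.fast(seed=9, chains=2, iterations=600),
        )
        s = summarize(draws)
        for m, name in enumerate(names):
            row = s.loc[f"alpha[{name}]"]
            assert abs(row["EAP"] - eta_true[m]) < 3 * row["SD"]

    def test_seed_reproducibility(self, scaled_design, scaled_gen):
        persons = generate_persons(20, scaled_gen, seed=1)
        practice = build_practice_matrix(scaled_design)
        data = simulate_responses(scaled_design, practice, persons, scaled_gen, seed=2)
        cfg = SamplerConfig.fast(seed=77, chains=2, iterations=200)
        spec = ModelSpec.lltm(scaled_design.component_names)
        a = fit(spec, scaled_design, practice, data, cfg)
        b = fit(spec, scaled_design, practice, data, cfg)
        for key in a.draws:
            np.testing.assert_array_equal(a.draws[key], b.draws[key])
        np.testing.assert_array_equal(a.log_lik, b.log_lik)

    def test_identification_failure_raises(self):
        W = np.column_stack([np.ones(6), np.ones(6)])
        design = TestDesign([ComponentSpec("a"), ComponentSpec("b")], W)
        data = ResponseData(X=np.zeros((4, 6), dtype=int))
        with pytest.raises(ValueError, match="identification"):
            fit(ModelSpec.lltm(["a", "b"]), design, None, data)

    def test_fit_quality_and_convergence(self, rwoslm_fit):
        s = summarize(rwoslm_fit)
        assert (s["Rhat"].dropna() < 1.05).all()
        assert sum(rwoslm_fit.diagnostics["divergences"]) == 0

    def test_save_load_round_trip(self, rwoslm_fit, tmp_path):
        rwoslm_fit.save(tmp_path / "fit")
        back = PosteriorDraws.load(tmp_path / "fit")
        assert back.spec == rwoslm_fit.spec
        np.testing.assert_allclose(
            back.stacked("mu_delta"), rwoslm_fit.stacked("mu_delta")
        )
        np.testing.assert_allclose(
            back.stacked_log_lik(), rwoslm_fit.stacked_log_lik(), rtol=1e-6
        )


class TestTrajectories:
    def test_shapes_and_invariants(self, rwoslm_fit):
        traj = trajectories(rwoslm_fit, persons=[1, 2], components=["CR", "A/S"])
        J = rwoslm_fit.design.J
        # fixed component: one shared curve
        cr = traj[traj.component == "CR"]
        assert len(cr) == J
        assert cr["person"].isna().all()
        # random component: one curve per person
        as_ = traj[traj.component == "A/S"]
        assert len(as_) == 2 * J
        # item 1 equals the initial difficulty EAP for everyone
        s = summarize(rwoslm_fit)
        a_cr = s.loc["alpha[CR]", "EAP"]
        assert cr[cr.item == 1]["difficulty"].iloc[0] == pytest.approx(a_cr)
        a_as = s.loc["alpha[A/S]", "EAP"]
        np.testing.assert_allclose(as_[as_.item == 1]["difficulty"], a_as)

    def test_slope_sign_matches_delta(self, rwoslm_fit):
        traj = trajectories(rwoslm_fit, persons=[1], components=["A/S"])
        tab, _ = classify_individuals(rwoslm_fit, "A/S")
        d1 = float(tab.loc[tab.person == 1, "eap_delta"].iloc[0])
        t = traj[traj.person == 1].sort_values("item")
        dw = np.diff(t["accumulated_weight"])
        dd = np.diff(t["difficulty"])
        mask = dw > 0
        # finite-difference slope in accumulated-practice coordinates = -delta
        np.testing.assert_allclose(dd[mask] / dw[mask], -d1, rtol=1e-8)
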