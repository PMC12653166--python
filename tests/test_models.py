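import numpy as np
import pytest
from scipy.special import expit

from oslm.design import ComponentSpec, TestDesign, build_practice_matrix
from oslm.models import (
    ModelSpec,
    ParameterSet,
    PracticeHyperparameters,
    ResponseData,
    lkj_logpdf,
    log_likelihood,
    log_prior,
    rule_difficulty_trajectory,
    success_logit,
)

NAMES2 = ["r1", "r2"]


@pytest.fixture
def design2():
    W = np.array([[1.0, 1.0], [2.0, 0.0], [1.0, 1.0], [0.0, 2.0]])
    return TestDesign([ComponentSpec(n) for n in NAMES2], W)


class TestModelSpec:
    def test_variant_consistency_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec("LLTM", {"a": "fixed"}, {"a": "fixed"})
        with pytest.raises(ValueError):
            ModelSpec("RWOSLM", {"a": "random"}, {"a": "random"})

    def test_named_constructors(self):
        comps = ["CR", "PP", "A/S", "distortion"]
        assert ModelSpec.lltm(comps).variant == "LLTM"
        assert ModelSpec.rwlltm(comps).random_difficulty == comps
        assert ModelSpec.oslm(comps).fixed_practice == comps
        assert ModelSpec.rwoslm(comps).random_practice == comps
        const = ModelSpec.rwoslm_const(comps)
        assert const.random_practice == ["A/S", "distortion"]
        assert set(const.fixed_practice) == {"CR", "PP"}

    def test_from_name(self):
        assert ModelSpec.from_name("rwoslm-const", ["A/S", "x"]).variant == "RWOSLM_const"
        with pytest.raises(ValueError):
            ModelSpec.from_name("rasch2pl", ["a"])

    def test_const_requires_a_random_component(self):
        with pytest.raises(ValueError):
            ModelSpec.rwoslm_const(["a", "b"], random=["zz"])


class TestSuccessLogit:
    def test_null_model(self):
        spec = ModelSpec.oslm(NAMES2)
        logit = success_logit(
            0.0, [1, 1], [0, 0], spec,
            alpha={"r1": 0.0, "r2": 0.0},
            delta_fixed={"r1": 0.0, "r2": 0.0},
        )
        assert logit == 0.0
        assert expit(logit) == 0.5

    def test_reference_magnitude_arithmetic(self):
        # alpha=(-1.585, 1.017), person deltas (-0.090, 0.095), w=(1,1), v=(2,1)
        spec = ModelSpec.rwoslm(NAMES2)
        logit = success_logit(
            0.0, [1, 1], [2, 1], spec,
            alpha={"r1": -1.585, "r2": 1.017},
            delta_i={"r1": -0.090, "r2": 0.095},
        )
        assert logit == pytest.approx(0.483, abs=1e-12)

    def test_dimension_mismatch(self):
        spec = ModelSpec.lltm(NAMES2)
        with pytest.raises(ValueError):
            success_logit(0.0, [1.0], [0.0], spec, alpha={"r1": 0, "r2": 0})

    def test_matches_trajectory_reformulation(self, rng, design2):
        """logit = theta - sum_m w_jm * alpha_ijm with the per-item
        trajectory difficulty must reproduce the direct formulation."""
        spec = ModelSpec.rwoslm(NAMES2)
        practice = build_practice_matrix(design2)
        for _ in range(200):
            theta = rng.standard_normal()
            alpha = dict(zip(NAMES2, rng.standard_normal(2)))
            delta = dict(zip(NAMES2, 0.2 * rng.standard_normal(2)))
            j = int(rng.integers(1, design2.J + 1))
            direct = success_logit(
                theta, design2.W[j - 1], practice.V[j - 1], spec,
                alpha=alpha, delta_i=delta,
            )
            via_traj = theta - sum(
                design2.W[j - 1, m]
                * rule_difficulty_trajectory(
                    alpha[name], delta[name], design2.W[:, m], j
                )
                for m, name in enumerate(NAMES2)
            )
            assert direct == pytest.approx(via_traj, abs=1e-10)


class TestTrajectory:
    def test_no_prior_practice_at_item_1(self):
        assert rule_difficulty_trajectory(1.3, 0.5, np.array([2.0, 1.0]), 1) == 1.3

    def test_learning_direction(self):
        # alpha 1.017, delta 0.095, accumulated weight 3 -> 0.732
        col = np.array([1.0, 2.0, 0.0, 1.0])  # cumsum before item 3 = 3
        assert rule_difficulty_trajectory(1.017, 0.095, col, 3) == pytest.approx(0.732)

    def test_fatigue_direction(self):
        col = np.array([2.0, 1.0, 1.0])  # cumsum before item 2 = 2
        assert rule_difficulty_trajectory(-1.585, -0.090, col, 2) == pytest.approx(-1.405)

    def test_item_bounds(self):
        with pytest.raises(ValueError):
            rule_difficulty_trajectory(0.0, 0.0, np.array([1.0]), 2)


class TestLogLikelihood:
    def test_single_cell_values(self, design2):
        spec = ModelSpec.lltm(NAMES2)
        practice = build_practice_matrix(design2)
        params = ParameterSet(
            theta=np.zeros(1), difficulty={"r1": 0.0, "r2": 0.0}
        )
        data = ResponseData(X=np.ones((1, 4), dtype=int))
        ll, total = log_likelihood(data, params, design2, practice, spec)
        np.testing.assert_allclose(ll, np.log(0.5))
        assert total == pytest.approx(4 * np.log(0.5))

    def test_saturation_no_overflow(self, design2):
        spec = ModelSpec.lltm(NAMES2)
        practice = build_practice_matrix(design2)
        params = ParameterSet(theta=np.array([30.0]), difficulty={"r1": 0.0, "r2": 0.0})
        data = ResponseData(X=np.ones((1, 4), dtype=int))
        ll, _ = log_likelihood(data, params, design2, practice, spec)
        assert np.all(np.isfinite(ll))
        assert np.all(ll > -1e-10)

    def test_brute_force_toy(self, rng):
        """3 persons x 4 items against an explicit scalar-loop oracle."""
        W = np.array([[1.0], [1.0], [2.0], [1.0]])
        design = TestDesign([ComponentSpec("r")], W)
        practice = build_practice_matrix(design)
        spec = ModelSpec.oslm(["r"])
        theta = rng.standard_normal(3)
        a, d = 0.4, -0.1
        params = ParameterSet(
            theta=theta, difficulty={"r": a}, practice={"r": d}
        )
        X = rng.integers(0, 2, size=(3, 4))
        ll, total = log_likelihood(ResponseData(X=X), params, design, practice, spec)
        expected = 0.0
        for i in range(3):
            for j in range(4):
                logit = theta[i] - W[j, 0] * a + practice.V[j, 0] * d
                p = 1.0 / (1.0 + np.exp(-logit))
                expected += np.log(p) if X[i, j] == 1 else np.log(1 - p)
        assert total == pytest.approx(expected, abs=1e-10)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ResponseData(X=np.array([[0, 2]]))
        with pytest.raises(ValueError, match="missing"):
            ResponseData(X=np.array([[0.0, np.nan]]))


class TestNesting:
    """Model-family nesting identities on a shared random design."""

    @pytest.fixture
    def setup(self, rng, design2):
        practice = build_practice_matrix(design2)
        theta = rng.standard_normal(6)
        alpha = dict(zip(NAMES2, rng.standard_normal(2)))
        X = rng.integers(0, 2, size=(6, 4))
        return design2, practice, theta, alpha, ResponseData(X=X)

    def test_zero_practice_collapses_to_lltm(self, setup):
        design, practice, theta, alpha, data = setup
        lltm = ModelSpec.lltm(NAMES2)
        oslm = ModelSpec.oslm(NAMES2)
        rwoslm = ModelSpec.rwoslm(NAMES2)
        ll_lltm, _ = log_likelihood(
            data, ParameterSet(theta=theta, difficulty=alpha), design, practice, lltm
        )
        ll_oslm, _ = log_likelihood(
            data,
            ParameterSet(theta=theta, difficulty=alpha, practice={n: 0.0 for n in NAMES2}),
            design, practice, oslm,
        )
        ll_rw, _ = log_likelihood(
            data,
            ParameterSet(
                theta=theta, difficulty=alpha,
                practice={n: np.zeros(6) for n in NAMES2},
            ),
            design, practice, rwoslm,
        )
        np.testing.assert_allclose(ll_oslm, ll_lltm, atol=1e-12)
        np.testing.assert_allclose(ll_rw, ll_lltm, atol=1e-12)

    def test_shared_delta_collapses_to_oslm(self, setup, rng):
        design, practice, theta, alpha, data = setup
        delta = dict(zip(NAMES2, 0.3 * rng.standard_normal(2)))
        ll_oslm, _ = log_likelihood(
            data,
            ParameterSet(theta=theta, difficulty=alpha, practice=delta),
            design, practice, ModelSpec.oslm(NAMES2),
        )
        ll_rw, _ = log_likelihood(
            data,
            ParameterSet(
                theta=theta, difficulty=alpha,
                practice={n: np.full(6, delta[n]) for n in NAMES2},
            ),
            design, practice, ModelSpec.rwoslm(NAMES2),
        )
        np.testing.assert_allclose(ll_rw, ll_oslm, atol=1e-12)

    def test_monotonicity(self, setup):
        design, practice, theta, alpha, data = setup
        spec = ModelSpec.oslm(NAMES2)

        def p11(theta0, delta0):
            params = ParameterSet(
                theta=np.array([theta0]), difficulty=alpha,
                practice={"r1": delta0, "r2": 0.0},
            )
            ll, _ = log_likelihood(
                ResponseData(X=np.ones((1, 4), dtype=int)), params, design, practice, spec
            )
            return np.exp(ll)

        base = p11(0.0, 0.0)
        assert np.all(p11(0.5, 0.0) > base)  # ability strictly increases P
        up = p11(0.0, 0.4)
        v = practice.V[:, 0]
        assert np.all(up[0, v > 0] > base[0, v > 0])
        np.testing.assert_allclose(up[0, v == 0], base[0, v == 0])


class TestPriors:
    def test_lkj_identity_2x2_equals_normalizer(self):
        # density of LKJ(2) at the 2x2 identity is 1/(2^3 B(2,2)) = 3/4
        assert lkj_logpdf(np.eye(2), eta=2.0) == pytest.approx(np.log(0.75), abs=1e-12)

    def test_lkj_eta1_is_uniform_volume(self):
        # eta = 1: density is constant = 1 / volume; 2x2 volume is 2
        assert lkj_logpdf(np.eye(2), eta=1.0) == pytest.approx(np.log(0.5), abs=1e-12)
        r = 0.6
        Om = np.array([[1.0, r], [r, 1.0]])
        assert lkj_logpdf(Om, eta=1.0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_lkj_mc_normalization_3x3(self, rng):
        """The exact normalizer makes the density integrate to 1 (checked by
        Monte Carlo over uniformly sampled 3x3 correlation matrices)."""
        # sample r12, r13, r23 ~ U(-1,1), keep PD ones; volume of the cube is 8
        S = 40_000
        r = rng.uniform(-1, 1, size=(S, 3))
        vals = np.zeros(S)
        kept = 0
        total_volume = 8.0
        for i in range(S):
            Om = np.array(
                [
                    [1.0, r[i, 0], r[i, 1]],
                    [r[i, 0], 1.0, r[i, 2]],
                    [r[i, 1], r[i, 2], 1.0],
                ]
            )
            if np.all(np.linalg.eigvalsh(Om) > 0):
                vals[kept] = np.exp(lkj_logpdf(Om, eta=2.0))
                kept += 1
        integral = total_volume * vals[:kept].sum() / S
        assert integral == pytest.approx(1.0, rel=0.05)

    def test_hyper_invariants(self):
        with pytest.raises(ValueError, match="positive"):
            PracticeHyperparameters(mu=[0.0], sigma=[0.0], Omega=[[1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            PracticeHyperparameters(
                mu=[0, 0], sigma=[1, 1], Omega=[[1.0, 0.5], [0.2, 1.0]]
            )
        with pytest.raises(ValueError, match="positive definite"):
            PracticeHyperparameters(
                mu=[0, 0], sigma=[1, 1], Omega=[[1.0, 1.2], [1.2, 1.0]]
            )
        hyper = PracticeHyperparameters(
            mu=[0.0, 0.1], sigma=[0.5, 2.0], Omega=[[1.0, 0.3], [0.3, 1.0]]
        )
        Sigma = hyper.Sigma
        np.testing.assert_allclose(Sigma, Sigma.T)
        np.linalg.cholesky(Sigma)  # PD
        np.testing.assert_allclose(np.diag(Sigma), [0.25, 4.0])

    def test_log_prior_gaussian_pieces(self, rng):
        spec = ModelSpec.oslm(NAMES2)
        theta = rng.standard_normal(5)
        params = ParameterSet(
            theta=theta,
            difficulty={"r1": 0.5, "r2": -0.3},
            practice={"r1": 0.1, "r2": 0.0},
        )
        lp = log_prior(params, spec)
        from scipy.stats import norm

        expected = norm.logpdf(theta).sum() + norm.logpdf(
            [0.5, -0.3, 0.1, 0.0], scale=10.0
        ).sum()
        assert lp == pytest.approx(expected, abs=1e-9)

    def test_log_prior_random_block(self, rng):
        spec = ModelSpec.rwoslm(NAMES2)
        hyper = PracticeHyperparameters(
            mu=[0.0, -0.1], sigma=[0.3, 0.6], Omega=[[1.0, 0.2], [0.2, 1.0]]
        )
        deltas = rng.standard_normal((4, 2)) * 0.3
        params = ParameterSet(
            theta=rng.standard_normal(4),
            difficulty={"r1": 0.2, "r2": 0.1},
            practice={"r1": deltas[:, 0], "r2": deltas[:, 1]},
        )
        lp = log_prior(params, spec, hyper=hyper)
        from scipy.stats import cauchy, multivariate_normal, norm

        expected = (
            norm.logpdf(params.theta).sum()
            + norm.logpdf([0.2, 0.1], scale=10.0).sum()
            + multivariate_normal.logpdf(deltas, mean=hyper.mu, cov=hyper.Sigma).sum()
            + norm.logpdf(hyper.mu).sum()
            + (np.log(2) + cauchy.logpdf(hyper.sigma, scale=5.0)).sum()
            + lkj_logpdf(hyper.Omega, 2.0)
        )
        assert lp == pytest.approx(expected, abs=1e-9)

    def test_missing_hyper_raises(self, rng):
        spec = ModelSpec.rwoslm(NAMES2)
        params = ParameterSet(
            theta=np.zeros(2),
            difficulty={"r1": 0.0, "r2": 0.0},
            practice={"r1": np.zeros(2), "r2": np.zeros(2)},
        )
        with pytest.raises(ValueError, match="hyper"):
            log_prior(params, spec)


class TestResponseDataIO:
    def test_wide_round_trip(self, tmp_path, rng):
        data = ResponseData(X=rng.integers(0, 2, size=(5, 3)))
        p = tmp_path / "resp.csv"
        data.to_frame().to_csv(p, index=False)
        back = ResponseData.from_csv(p)
        np.testing.assert_array_equal(back.X, data.X)
        np.testing.assert_array_equal(back.person_ids, data.person_ids)

    def test_long_format(self, tmp_path):
        rows = ["person,item,response,latency"]
        for i in (1, 2):
            for j in (1, 2, 3):
                rows.append(f"{i},{j},{(i + j) % 2},{2.5}")
        p = tmp_path / "long.csv"
        p.write_text("\n".join(rows) + "\n")
        data = ResponseData.from_csv(p)
        assert data.X.shape == (2, 3)
        assert data.latencies.shape == (2, 3)
        np.testing.assert_array_equal(data.X[0], [0, 1, 0])
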