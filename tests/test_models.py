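"""Model registry M1-M9, linear predictors, likelihood and priors."""

import math

import numpy as np
import pytest
from scipy import stats

import biduomap as bm
from biduomap.models import ModelParams, PriorConfig, log_prior, observation_index
from biduomap.spatial import BivariateAreaData

EXPECTED_FLAGS = {
    "M1": "Uk Vk",
    "M2": "Uk U Vk",
    "M3": "Uk U V",
    "M4": "U Vk V",
    "M5": "Uk Vk V",
    "M6": "U V",
    "M7": "Uk U Vk V",
    "M8": "U Vk",
    "M9": "Uk V",
}


class TestRegistry:
    @pytest.mark.parametrize("name,desc", sorted(EXPECTED_FLAGS.items()))
    def test_component_sets(self, name, desc):
        assert bm.model_registry(name).description == desc

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            bm.model_registry("M10")


def _m7_params(n, delta=1.0, omega=1.0, **fields):
    zeros = np.zeros(n)
    return ModelParams(
        alpha={"P": fields.get("alpha_P", 0.0), "O": fields.get("alpha_O", 0.0)},
        shared_clustering=fields.get("u", zeros.copy()),
        specific_clustering={
            "P": fields.get("u_P", zeros.copy()),
            "O": fields.get("u_O", zeros.copy()),
        },
        shared_heterogeneity=fields.get("v", zeros.copy()),
        specific_heterogeneity={
            "P": fields.get("v_P", zeros.copy()),
            "O": fields.get("v_O", zeros.copy()),
        },
        delta=delta,
        omega=omega,
        prec_shared_clustering=1.0,
        prec_specific_clustering={"P": 1.0, "O": 1.0},
        prec_shared_heterogeneity=1.0,
        prec_specific_heterogeneity={"P": 1.0, "O": 1.0},
    )


class TestLinearPredictor:
    def test_intercept_only(self):
        spec = bm.model_registry("M7")
        p = _m7_params(3, alpha_P=0.4, alpha_O=-0.2)
        assert bm.linear_predictor(spec, p, "P", 0) == pytest.approx(0.4)
        assert bm.linear_predictor(spec, p, "O", 2) == pytest.approx(-0.2)

    def test_unit_scaling_shared_only_symmetry(self):
        spec = bm.model_registry("M6")
        n = 4
        p = ModelParams(
            alpha={"P": 0.1, "O": 0.1},
            shared_clustering=np.array([0.3, -0.1, 0.0, 0.2]),
            shared_heterogeneity=np.array([0.05, 0.0, -0.2, 0.1]),
            delta=1.0,
            omega=1.0,
            prec_shared_clustering=1.0,
            prec_shared_heterogeneity=1.0,
        )
        np.testing.assert_allclose(
            bm.linear_predictor(spec, p, "P"), bm.linear_predictor(spec, p, "O")
        )

    def test_m7_direct_evaluation(self):
        """alpha_P=0, u=0.2, delta=0.5, u_P=0.1, v terms 0, v_P=-0.05 -> 0.15."""
        spec = bm.model_registry("M7")
        p = _m7_params(
            1,
            delta=0.5,
            u=np.array([0.2]),
            u_P=np.array([0.1]),
            v_P=np.array([-0.05]),
        )
        assert bm.linear_predictor(spec, p, "P", 0) == pytest.approx(0.2 * 0.5 + 0.1 - 0.05)

    def test_asymmetric_scaling_directions(self):
        """Shared clustering enters P times delta and O divided by delta."""
        spec = bm.model_registry("M6")
        p = ModelParams(
            alpha={"P": 0.0, "O": 0.0},
            shared_clustering=np.array([1.0]),
            shared_heterogeneity=np.array([0.0]),
            delta=0.5,
            omega=2.0,
            prec_shared_clustering=1.0,
            prec_shared_heterogeneity=1.0,
        )
        assert bm.linear_predictor(spec, p, "P", 0) == pytest.approx(0.5)
        assert bm.linear_predictor(spec, p, "O", 0) == pytest.approx(2.0)

    def test_invalid_delta_rejected(self):
        spec = bm.model_registry("M6")
        p = ModelParams(
            alpha={"P": 0.0, "O": 0.0},
            shared_clustering=np.zeros(1),
            shared_heterogeneity=np.zeros(1),
            delta=-1.0,
            omega=1.0,
        )
        with pytest.raises(ValueError):
            bm.linear_predictor(spec, p, "P", 0)

    def test_clustering_shift_absorbed_by_intercept(self, path3_graph):
        """Adding c to a clustering field and subtracting the scaled amount from
        the intercept leaves every predictor unchanged (the flat direction the
        sampler must constrain)."""
        spec = bm.model_registry("M7")
        rng = np.random.default_rng(1)
        p = _m7_params(
            3,
            delta=0.7,
            u=rng.normal(size=3),
            u_P=rng.normal(size=3),
            v_P=rng.normal(size=3),
        )
        base = {k: bm.linear_predictor(spec, p, k) for k in ("P", "O")}
        c = 0.37
        p.shared_clustering = p.shared_clustering + c
        p.alpha["P"] -= c * p.delta
        p.alpha["O"] -= c / p.delta
        for k in ("P", "O"):
            np.testing.assert_allclose(bm.linear_predictor(spec, p, k), base[k], atol=1e-12)


class TestPointwiseLoglik:
    def _data(self, o, e):
        ids = tuple(f"a{i}" for i in range(len(o)))
        arr = lambda x: np.asarray(x, dtype=float)
        return BivariateAreaData(ids, {"P": arr(o), "O": arr(o)}, {"P": arr(e), "O": arr(e)})

    def test_poisson_pmf_values(self):
        spec = bm.model_registry("M7")
        p = _m7_params(2)
        ll = bm.pointwise_loglik(spec, p, self._data([0, 2], [1.0, 1.0]))
        assert ll[0] == pytest.approx(-1.0)  # Poisson(1) at 0
        assert ll[1] == pytest.approx(-1.0 - math.log(2.0))  # log(e^-1 / 2)

    def test_mean_invariance(self):
        """Scaling E by c and theta by 1/c leaves the pmf unchanged."""
        spec = bm.model_registry("M1")
        n = 3
        rng = np.random.default_rng(2)
        fields = {k: rng.normal(size=n) for k in ("P", "O")}
        p1 = ModelParams(
            alpha={"P": 0.2, "O": -0.1},
            specific_clustering={k: fields[k].copy() for k in ("P", "O")},
            specific_heterogeneity={k: np.zeros(n) for k in ("P", "O")},
            prec_specific_clustering={"P": 1.0, "O": 1.0},
            prec_specific_heterogeneity={"P": 1.0, "O": 1.0},
        )
        c = 3.0
        p2 = ModelParams(
            alpha={"P": 0.2 - math.log(c), "O": -0.1 - math.log(c)},
            specific_clustering={k: fields[k].copy() for k in ("P", "O")},
            specific_heterogeneity={k: np.zeros(n) for k in ("P", "O")},
            prec_specific_clustering={"P": 1.0, "O": 1.0},
            prec_specific_heterogeneity={"P": 1.0, "O": 1.0},
        )
        d1 = self._data([2, 0, 5], [1.0, 2.0, 3.0])
        d2 = self._data([2, 0, 5], [float(c), 2.0 * c, 3.0 * c])
        np.testing.assert_allclose(
            bm.pointwise_loglik(spec, p1, d1), bm.pointwise_loglik(spec, p2, d2), atol=1e-12
        )

    def test_zero_expected_excluded_and_observation_order(self):
        d = self._data([2, 0], [1.0, 0.0])
        idx = observation_index(d)
        assert idx == [("a0", "P"), ("a0", "O")]
        spec = bm.model_registry("M7")
        assert bm.pointwise_loglik(spec, _m7_params(2), d).shape == (2,)

    def test_non_integer_observed_rejected(self):
        spec = bm.model_registry("M7")
        with pytest.raises(ValueError):
            bm.pointwise_loglik(spec, _m7_params(1), self._data([2.5], [1.0]))


class TestLogPrior:
    def test_constant_clustering_field_contributes_zero_penalty(self, path3_graph):
        spec = bm.model_registry("M9")  # Uk V
        base = ModelParams(
            alpha={"P": 0.0, "O": 0.0},
            specific_clustering={"P": np.zeros(3), "O": np.zeros(3)},
            shared_heterogeneity=np.zeros(3),
            omega=1.0,
            prec_specific_clustering={"P": 2.0, "O": 2.0},
            prec_shared_heterogeneity=1.0,
        )
        shifted = ModelParams(
            alpha={"P": 0.0, "O": 0.0},
            specific_clustering={"P": np.full(3, 5.0), "O": np.zeros(3)},
            shared_heterogeneity=np.zeros(3),
            omega=1.0,
            prec_specific_clustering={"P": 2.0, "O": 2.0},
            prec_shared_heterogeneity=1.0,
        )
        assert log_prior(spec, base, path3_graph) == pytest.approx(
            log_prior(spec, shifted, path3_graph)
        )

    def test_pairwise_penalty_linear_in_precision(self, path3_graph):
        spec = bm.model_registry("M9")

        def lp(lam, u):
            p = ModelParams(
                alpha={"P": 0.0, "O": 0.0},
                specific_clustering={"P": u, "O": np.zeros(3)},
                shared_heterogeneity=np.zeros(3),
                omega=1.0,
                prec_specific_clustering={"P": lam, "O": lam},
                prec_shared_heterogeneity=1.0,
            )
            return log_prior(spec, p, path3_graph)

        u = np.array([0.0, 1.0, 3.0])
        pen1 = lp(1.0, np.zeros(3)) - lp(1.0, u)
        pen2 = lp(2.0, np.zeros(3)) - lp(2.0, u)
        assert pen2 == pytest.approx(2.0 * pen1)
        # pairwise form on the path: (u0-u1)^2 + (u1-u2)^2 = 1 + 4
        assert pen1 == pytest.approx(0.5 * 5.0)

    def test_hand_computed_total_on_path(self, path3_graph):
        """Full log prior on a 3-area path against a term-by-term hand formula."""
        spec = bm.model_registry("M9")
        u = np.array([0.1, -0.2, 0.4])
        v = np.array([0.3, 0.0, -0.1])
        lam_u, lam_v, omega = 2.0, 4.0, 0.8
        p = ModelParams(
            alpha={"P": 0.0, "O": 0.0},
            specific_clustering={"P": u, "O": np.zeros(3)},
            shared_heterogeneity=v,
            omega=omega,
            prec_specific_clustering={"P": lam_u, "O": lam_u},
            prec_shared_heterogeneity=lam_v,
        )
        pri = PriorConfig()
        expected = 0.0
        for lam in (lam_u, lam_u, lam_v):  # two clustering fields + one heterogeneity
            expected += stats.gamma.logpdf(lam, 0.5, scale=1 / 0.0005)
        for field_vals, lam in ((u, lam_u), (np.zeros(3), lam_u)):
            pairwise = (field_vals[0] - field_vals[1]) ** 2 + (field_vals[1] - field_vals[2]) ** 2
            expected += 0.5 * 2 * np.log(lam) - 0.5 * lam * pairwise  # rank n-1 = 2
        expected += stats.norm.logpdf(v, 0.0, 1 / math.sqrt(lam_v)).sum()
        expected += stats.norm.logpdf(math.log(omega), 0.0, math.sqrt(0.17))
        assert log_prior(spec, p, path3_graph, pri) == pytest.approx(expected)

    def test_icar_conditional_is_neighbour_mean_normal(self, path3_graph):
        """Varying one site of the clustering field, the prior conditional is
        Normal(mean of neighbours, 1/(lambda * n_i)) — checked by completing
        the square on the pairwise form."""
        spec = bm.model_registry("M9")
        lam = 3.0
        others = np.array([0.5, math.nan, -0.3])  # vary the middle site (2 neighbours)

        def lp(x):
            u = others.copy()
            u[1] = x
            p = ModelParams(
                alpha={"P": 0.0, "O": 0.0},
                specific_clustering={"P": u, "O": np.zeros(3)},
                shared_heterogeneity=np.zeros(3),
                omega=1.0,
                prec_specific_clustering={"P": lam, "O": lam},
                prec_shared_heterogeneity=1.0,
            )
            return log_prior(spec, p, path3_graph)

        mean = (0.5 - 0.3) / 2
        sd = 1.0 / math.sqrt(lam * 2)
        xs = [-0.5, 0.0, 0.4, 1.1]
        diffs = [lp(x) - lp(0.0) for x in xs]
        ref = [stats.norm.logpdf(x, mean, sd) - stats.norm.logpdf(0.0, mean, sd) for x in xs]
        np.testing.assert_allclose(diffs, ref, atol=1e-10)

    def test_invalid_precision_rejected(self, path3_graph):
        spec = bm.model_registry("M9")
        p = ModelParams(
            alpha={"P": 0.0, "O": 0.0},
            specific_clustering={"P": np.zeros(3), "O": np.zeros(3)},
            shared_heterogeneity=np.zeros(3),
            omega=1.0,
            prec_specific_clustering={"P": -1.0, "O": 1.0},
            prec_shared_heterogeneity=1.0,
        )
        with pytest.raises(ValueError):
            log_prior(spec, p, path3_graph)

    def test_params_structurally_checked(self, path3_graph):
        spec = bm.model_registry("M1")
        p = ModelParams(alpha={"P": 0.0, "O": 0.0})  # missing required components
        with pytest.raises(ValueError):
            log_prior(spec, p, path3_graph)
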