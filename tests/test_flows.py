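import numpy as np
import pytest

from molflow.flows import (
    DEFAULT_ETA,
    ConditionalPair,
    conditional_vf,
    cross_entropy_rows,
    endpoint_vf,
    interpolate,
    training_loss,
)
from molflow.ot_align import permute_graph
from molflow.schedules import InterpolantSchedule, ScheduleSet

from conftest import random_graph


@pytest.fixture
def pair(codebook, rng):
    return ConditionalPair(g0=random_graph(5, codebook, rng), g1=random_graph(5, codebook, rng))


@pytest.fixture
def schedules():
    return ScheduleSet.from_nus()


class TestInterpolate:
    def test_endpoints_exact(self, pair, schedules):
        g0 = interpolate(pair, schedules, 0.0)
        g1 = interpolate(pair, schedules, 1.0)
        assert np.array_equal(g0.positions, pair.g0.positions)
        assert np.array_equal(g0.bonds, pair.g0.bonds)
        assert np.allclose(g1.atom_types, pair.g1.atom_types, atol=1e-15)
        assert np.allclose(g1.positions, pair.g1.positions, atol=1e-15)

    def test_midpoint_onehot(self, codebook, rng, schedules):
        p = ConditionalPair(
            g0=random_graph(2, codebook, rng, simplex=False),
            g1=random_graph(2, codebook, rng, simplex=False),
        )
        p.g0.atom_types[0] = [1, 0, 0, 0, 0]
        p.g1.atom_types[0] = [0, 1, 0, 0, 0]
        g = interpolate(p, schedules, 0.5)  # alpha = 0.5 for nu = 1
        assert np.allclose(g.atom_types[0], [0.5, 0.5, 0, 0, 0])

    def test_position_quarter(self, codebook, rng):
        p = ConditionalPair(g0=random_graph(2, codebook, rng), g1=random_graph(2, codebook, rng))
        p.g0.positions[0] = [0, 0, 0]
        p.g1.positions[0] = [2, 0, 0]
        s = InterpolantSchedule(nu=1.0)
        t = 2.0 / np.pi * np.arcsin(np.sqrt(0.25))  # alpha = 0.25
        g = interpolate(p, ScheduleSet(s, s, s, s), t)
        assert np.allclose(g.positions[0], [0.5, 0, 0], atol=1e-12)

    def test_shape_mismatch(self, codebook, rng):
        with pytest.raises(ValueError):
            ConditionalPair(g0=random_graph(3, codebook, rng), g1=random_graph(4, codebook, rng))


class TestConditionalVF:
    def test_scalar_example(self, codebook, rng, schedules):
        p = ConditionalPair(g0=random_graph(2, codebook, rng), g1=random_graph(2, codebook, rng))
        p.g0.positions[:] = 0.0
        p.g1.positions[:] = 1.0
        u = conditional_vf(p, schedules, 0.5)
        assert np.allclose(u["x"], np.pi / 2, atol=1e-12)  # alpha'(0.5) = pi/2

    def test_identical_endpoints_zero(self, codebook, rng, schedules):
        g = random_graph(4, codebook, rng)
        p = ConditionalPair(g0=g.copy(), g1=g.copy())
        for t in (0.0, 0.3, 0.9):
            u = conditional_vf(p, schedules, t)
            assert all(np.allclose(u[m], 0.0) for m in u)

    def test_two_forms_agree(self, codebook, rng):
        """alpha'(g1-g0) == (alpha'/(1-alpha))(g1-g_t) along the interpolant."""
        schedules = ScheduleSet.from_nus(1.0, 2.0, 0.5, 3.0)
        for _ in range(20):
            p = ConditionalPair(
                g0=random_graph(4, codebook, rng), g1=random_graph(4, codebook, rng)
            )
            t = float(rng.uniform(0.0, 0.99))
            g_t = interpolate(p, schedules, t)
            u9 = conditional_vf(p, schedules, t)
            u10 = endpoint_vf(g_t, p.g1, schedules, t)
            for m in ("x", "a", "c", "e"):
                assert np.allclose(u9[m], u10[m], atol=1e-8)


class TestEndpointVF:
    def test_zero_when_at_prediction(self, codebook, rng, schedules):
        g = random_graph(3, codebook, rng)
        u = endpoint_vf(g, g, schedules, 0.4)
        assert all(np.allclose(u[m], 0.0) for m in u)

    def test_scalar_formula(self, codebook, rng):
        s = InterpolantSchedule(nu=1.0)
        schedules = ScheduleSet(s, s, s, s)
        g_t = random_graph(2, codebook, rng)
        g_hat = g_t.copy()
        g_t.positions[0] = [0.5, 0, 0]
        g_hat.positions[0] = [1.0, 0, 0]
        u = endpoint_vf(g_t, g_hat, schedules, 0.5)
        # (alpha'/(1-alpha)) * gap = (pi/2 / 0.5) * 0.5 = pi/2
        assert u["x"][0, 0] == pytest.approx(np.pi / 2, abs=1e-10)

    def test_linear_in_gap(self, codebook, rng, schedules):
        g_t = random_graph(3, codebook, rng)
        g1 = random_graph(3, codebook, rng)
        g2 = g_t.copy()
        g2.positions = g_t.positions + 2 * (g1.positions - g_t.positions)
        u1 = endpoint_vf(g_t, g1, schedules, 0.3)
        u2 = endpoint_vf(g_t, g2, schedules, 0.3)
        assert np.allclose(u2["x"], 2 * u1["x"], atol=1e-10)

    def test_alpha_one_raises(self, codebook, rng, schedules):
        g = random_graph(2, codebook, rng)
        with pytest.raises(ValueError):
            endpoint_vf(g, g, schedules, 1.0)

    def test_consistency_along_trajectories(self, codebook, rng):
        """Plugging the true g1 into the endpoint field reproduces the
        conditional field along interpolant trajectories (t <= 0.99)."""
        schedules = ScheduleSet.from_nus(2.0, 1.0, 1.0, 0.5)
        p = ConditionalPair(g0=random_graph(5, codebook, rng), g1=random_graph(5, codebook, rng))
        for t in np.linspace(0.0, 0.99, 25):
            g_t = interpolate(p, schedules, float(t))
            u_ep = endpoint_vf(g_t, p.g1, schedules, float(t))
            u_cond = conditional_vf(p, schedules, float(t))
            for m in ("x", "a", "c", "e"):
                assert np.allclose(u_ep[m], u_cond[m], atol=1e-6)


class TestTrainingLoss:
    def _perfect_endpoint_pred(self, pair):
        g1 = pair.g1
        return {"x": g1.positions.copy(), "a": g1.atom_types.copy(),
                "c": g1.charges.copy(), "e": g1.bonds.copy()}

    def test_perfect_prediction(self, codebook, rng, schedules):
        pair = ConditionalPair(
            g0=random_graph(3, codebook, rng), g1=random_graph(3, codebook, rng, simplex=False)
        )
        pred = self._perfect_endpoint_pred(pair)
        loss = training_loss([pair], [pred], schedules, np.array([0.5]), "endpoint")
        # position term is exactly 0; one-hot targets make CE hit its minimum 0
        eta_x_only = training_loss([pair], [pred], schedules, np.array([0.5]), "endpoint",
                                   eta=(1.0, 0, 0, 0))
        assert eta_x_only == 0.0
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_eta_selects_position_term(self, pair, schedules):
        pred = self._perfect_endpoint_pred(pair)
        pred["x"] = pred["x"] + 1.0
        loss = training_loss([pair], [pred], schedules, np.array([0.5]), "endpoint",
                             eta=(1.0, 0.0, 0.0, 0.0))
        # squared error 3 per atom (1 per axis), weight w(0.5) = 1
        assert loss == pytest.approx(3.0, abs=1e-9)

    def test_hand_computed_example(self, codebook, rng, schedules):
        pair = ConditionalPair(
            g0=random_graph(1, codebook, rng), g1=random_graph(1, codebook, rng)
        )
        pair.g1.positions[0] = [0.0, 0.0, 0.0]
        pred = self._perfect_endpoint_pred(pair)
        pred["x"] = np.array([[1.0, 0.0, 0.0]])
        loss = training_loss([pair], [pred], schedules, np.array([0.5]), "endpoint",
                             eta=(3.0, 0.0, 0.0, 0.0))
        # ||(1,0,0)||^2 = 1, w(0.5) = 1, eta_x = 3 -> 3.0
        assert loss == pytest.approx(3.0, abs=1e-9)

    def test_vector_field_objective(self, pair, schedules, rng):
        target = conditional_vf(pair, schedules, 0.3)
        loss0 = training_loss([pair], [target], schedules, np.array([0.3]), "vector_field")
        assert loss0 == pytest.approx(0.0, abs=1e-12)
        off = {m: target[m] + 1.0 for m in target}
        loss1 = training_loss([pair], [off], schedules, np.array([0.3]), "vector_field")
        assert loss1 > 0

    def test_permutation_covariance(self, codebook, rng, schedules):
        pair = ConditionalPair(
            g0=random_graph(5, codebook, rng), g1=random_graph(5, codebook, rng, simplex=False)
        )
        pred = {"x": rng.normal(size=(5, 3)), "a": rng.dirichlet(np.ones(5), size=5),
                "c": rng.dirichlet(np.ones(3), size=5), "e": rng.dirichlet(np.ones(5), size=10)}
        loss = training_loss([pair], [pred], schedules, np.array([0.4]), "endpoint")
        perm = rng.permutation(5)
        from molflow.mol_types import MoleculeGraph

        pg = permute_graph(
            MoleculeGraph(pred["x"], pred["a"], pred["c"], pred["e"], codebook=codebook), perm
        )
        pair_p = ConditionalPair(g0=permute_graph(pair.g0, perm), g1=permute_graph(pair.g1, perm))
        pred_p = {"x": pg.positions, "a": pg.atom_types, "c": pg.charges, "e": pg.bonds}
        loss_p = training_loss([pair_p], [pred_p], schedules, np.array([0.4]), "endpoint")
        assert loss_p == pytest.approx(loss, abs=1e-6)

    def test_bad_objective(self, pair, schedules):
        with pytest.raises(ValueError):
            training_loss([pair], [{}], schedules, np.array([0.5]), "diffusion")

    def test_shape_mismatch(self, pair, schedules):
        pred = self._perfect_endpoint_pred(pair)
        pred["a"] = pred["a"][:, :2]
        with pytest.raises(ValueError):
            training_loss([pair], [pred], schedules, np.array([0.5]), "endpoint")


def test_cross_entropy_min_at_target():
    t = np.array([[0.0, 1.0, 0.0]])
    assert cross_entropy_rows(t, t) == pytest.approx(0.0, abs=1e-9)
    assert cross_entropy_rows(np.array([[0.5, 0.25, 0.25]]), t) == pytest.approx(
        -np.log(0.25), abs=1e-12
    )


def test_default_eta_matches_documented():
    assert DEFAULT_ETA == (3.0, 0.4, 1.0, 2.0)
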