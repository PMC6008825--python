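"""Fluence-map optimization: objective, gradient, projected-CG solver."""

import numpy as np
import pytest
import scipy.optimize
import scipy.sparse as sp

from imrtbao.fmo import (
    FmoSolverParams,
    ObjectiveTerm,
    Prescription,
    get_prescription,
    objective_gradient,
    objective_value,
    solve_fmo,
)


def simple_rx(d_pres=30.0, p_t=1000.0, d_max=None, p_o=100.0):
    terms = [ObjectiveTerm("PTV", "square_deviation", p_t, d_pres)]
    if d_max is not None:
        terms.append(ObjectiveTerm("OAR", "square_overdosing", p_o, d_max))
    return Prescription(tuple(terms))


def random_instance(rng, n_target=None, n_oar=None, n_beamlets=None,
                    line_phantom_factory=None):
    """Random small planning instance with a dense nonnegative matrix."""
    n_target = n_target or int(rng.integers(2, 12))
    n_oar = n_oar or int(rng.integers(1, 9))
    n_beamlets = n_beamlets or int(rng.integers(2, 9))
    ph = line_phantom_factory(n_target, n_oar)
    K = rng.random((n_target + n_oar, n_beamlets))
    K[rng.random(K.shape) < 0.3] = 0.0
    K[:n_target] += 0.2  # make the target reachable
    rx = simple_rx(d_pres=float(rng.uniform(20, 60)),
                   d_max=float(rng.uniform(10, 40)),
                   p_t=float(rng.uniform(100, 2000)),
                   p_o=float(rng.uniform(50, 500)))
    return ph, rx, sp.csr_matrix(K)


def lbfgsb_oracle(K, rx, ph):
    """Independent nonnegative-QP solve via L-BFGS-B with bound constraints."""
    Kd = K.toarray()

    def fun(x):
        d = Kd @ x
        f = objective_value(d, rx, ph)
        g = np.concatenate(objective_gradient([x], [sp.csr_matrix(Kd)], rx, ph))
        return f, g

    n = Kd.shape[1]
    best = None
    for x0 in (np.zeros(n), np.full(n, 10.0)):
        res = scipy.optimize.minimize(
            fun, x0, jac=True, method="L-BFGS-B",
            bounds=[(0, None)] * n,
            options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
        )
        if best is None or res.fun < best:
            best = res.fun
    return best


class TestObjectiveValue:
    def test_single_target_voxel_quadratic(self, line_phantom_factory):
        ph = line_phantom_factory(1)
        f = objective_value(np.array([28.0]), simple_rx(30.0, 1000.0), ph)
        assert f == pytest.approx(1000.0 * 4.0)

    def test_satisfied_overdose_constraint_contributes_nothing(self,
                                                               line_phantom_factory):
        ph = line_phantom_factory(1, 1)
        rx = simple_rx(30.0, 1000.0, d_max=30.0, p_o=300.0)
        f = objective_value(np.array([30.0, 25.0]), rx, ph)
        assert f == 0.0

    def test_exact_match_scores_zero(self, line_phantom_factory):
        ph = line_phantom_factory(3, 2)
        rx = simple_rx(30.0, d_max=20.0)
        dose = np.array([30.0, 30.0, 30.0, 20.0, 5.0])
        assert objective_value(dose, rx, ph) == 0.0

    def test_missing_structure_raises(self, line_phantom_factory):
        ph = line_phantom_factory(1)
        rx = Prescription((ObjectiveTerm("nope", "square_deviation", 1.0, 30.0),))
        with pytest.raises(KeyError):
            objective_value(np.array([0.0]), rx, ph)


class TestObjectiveGradient:
    def test_zero_at_exact_match(self, line_phantom_factory):
        ph = line_phantom_factory(2)
        K = sp.identity(2, format="csr")
        g = objective_gradient([np.array([30.0, 30.0])], [K], simple_rx(30.0), ph)
        assert np.allclose(g[0], 0.0)

    def test_hand_worked_single_voxel(self, line_phantom_factory):
        # K=1, x=0, D_pres=30, p=1000 -> dF/dx = 2*1000*(0-30) = -60000
        ph = line_phantom_factory(1)
        K = sp.csr_matrix(np.array([[1.0]]))
        g = objective_gradient([np.zeros(1)], [K], simple_rx(30.0, 1000.0), ph)
        assert g[0][0] == pytest.approx(-60000.0)

    def test_matches_finite_differences(self, line_phantom_factory):
        rng = np.random.default_rng(42)
        ph, rx, K = random_instance(rng, 3, 2, 3,
                                    line_phantom_factory=line_phantom_factory)
        x = rng.random(K.shape[1]) * 30
        g = np.concatenate(objective_gradient([x], [K], rx, ph))
        h = 1e-4
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = h
            fd = (objective_value(K @ (x + e), rx, ph)
                  - objective_value(K @ (x - e), rx, ph)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestSolveFmo:
    def test_identity_system_reaches_exact_prescription(self, line_phantom_factory):
        ph = line_phantom_factory(2)
        K = sp.identity(2, format="csr")
        res = solve_fmo([K], simple_rx(30.0), ph)
        assert np.allclose(res.fluence_maps[0], 30.0, atol=1e-3)
        assert res.objective == pytest.approx(0.0, abs=1e-4)

    def test_competing_target_and_oar_reach_stationary_point(self,
                                                             line_phantom_factory):
        # min 1000(x-30)^2 + 100 max(x-20,0)^2 -> x* = 32000/1100
        ph = line_phantom_factory(1, 1)
        K = sp.csr_matrix(np.array([[1.0], [1.0]]))
        rx = simple_rx(30.0, 1000.0, d_max=20.0, p_o=100.0)
        res = solve_fmo([K], rx, ph, FmoSolverParams(max_iters=500, rel_tol=1e-12))
        x_star = (1000.0 * 30.0 + 100.0 * 20.0) / 1100.0
        assert res.fluence_maps[0][0] == pytest.approx(x_star, rel=1e-6)
        # brute-force line scan confirms the optimum
        xs = np.linspace(25, 32, 7001)
        fs = 1000 * (xs - 30) ** 2 + 100 * np.maximum(xs - 20, 0) ** 2
        assert res.objective <= fs.min() + 1e-6 * fs.min()

    def test_starting_at_optimum_is_fixed_point(self, line_phantom_factory):
        ph = line_phantom_factory(2)
        K = sp.identity(2, format="csr")
        res = solve_fmo([K], simple_rx(30.0), ph, x0=np.array([30.0, 30.0]))
        assert res.objective == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.fluence_maps[0], 30.0)

    def test_trace_monotone_and_fluence_nonnegative(self, line_phantom_factory):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ph, rx, K = random_instance(rng,
                                        line_phantom_factory=line_phantom_factory)
            res = solve_fmo([K], rx, ph)
            assert (np.diff(res.trace) <= 1e-9 * max(1.0, res.trace[0])).all()
            assert (res.fluence_maps[0] >= 0).all()

    def test_matches_bound_constrained_oracle(self, line_phantom_factory):
        rng = np.random.default_rng(11)
        params = FmoSolverParams(max_iters=3000, rel_tol=1e-14)
        for _ in range(10):
            ph, rx, K = random_instance(rng,
                                        line_phantom_factory=line_phantom_factory)
            res = solve_fmo([K], rx, ph, params)
            oracle = lbfgsb_oracle(K, rx, ph)
            assert res.objective == pytest.approx(oracle, rel=1e-6, abs=1e-6)

    def test_convexity_same_optimum_from_random_starts(self, line_phantom_factory):
        rng = np.random.default_rng(3)
        ph, rx, K = random_instance(rng, 5, 3, 4,
                                    line_phantom_factory=line_phantom_factory)
        params = FmoSolverParams(max_iters=3000, rel_tol=1e-14)
        values = [
            solve_fmo([K], rx, ph, params, x0=rng.random(K.shape[1]) * 50).objective
            for _ in range(4)
        ]
        assert np.ptp(values) <= 1e-5 * max(values)

    def test_zero_matrix_raises_cannot_irradiate(self, line_phantom_factory):
        ph = line_phantom_factory(2)
        K = sp.csr_matrix((2, 3))
        with pytest.raises(ValueError, match="cannot irradiate"):
            solve_fmo([K], simple_rx(30.0), ph)

    def test_multibeam_split_matches_concatenated(self, line_phantom_factory):
        rng = np.random.default_rng(5)
        ph = line_phantom_factory(4, 2)
        K1 = sp.csr_matrix(rng.random((6, 3)))
        K2 = sp.csr_matrix(rng.random((6, 2)))
        rx = simple_rx(40.0, d_max=25.0)
        res = solve_fmo([K1, K2], rx, ph)
        assert [len(m) for m in res.fluence_maps] == [3, 2]
        dose = K1 @ res.fluence_maps[0] + K2 @ res.fluence_maps[1]
        assert res.objective == pytest.approx(objective_value(dose, rx, ph),
                                              rel=1e-12)


class TestPresets:
    def test_preset_prescriptions_validate_on_their_phantoms(self):
        from imrtbao.phantoms import make_preset

        for name in ("box", "tg119", "prostate"):
            get_prescription(name).validate(make_preset(name))

    def test_prostate_preset_mirrors_planning_table(self):
        rx = get_prescription("prostate")
        by_name = {t.structure: t for t in rx.terms}
        assert by_name["PTV 56"].dose_gy == 56.0
        assert by_name["PTV 68"].dose_gy == 68.0
        assert by_name["Bladder"].kind == "square_overdosing"
        assert by_name["Bladder"].dose_gy == 45.0
        assert by_name["Body"].dose_gy == 70.0
        assert by_name["PTV 56"].penalty == 1000.0
        assert by_name["Rectum"].penalty == 300.0
        assert by_name["Body"].penalty == 100.0
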