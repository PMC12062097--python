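import warnings

import numpy as np
import pytest

from aggdiff.errors import InstabilityError
from aggdiff.kernels import LaplaceKernel, TopHatKernel
from aggdiff.landscape import SingleClumpEnvironment
from aggdiff.pde import (
    Grid,
    SimState,
    SolverConfig,
    _Workspace,
    _advance,
    dimensionalise,
    make_initial_condition,
    nondimensionalise,
    run_to_steady,
    step,
    total_mass,
)


@pytest.fixture
def coarse_grid():
    return Grid(dx=0.02)


@pytest.fixture
def flat_env():
    return SingleClumpEnvironment(n=1, amplitude=0.0)


def _local4_config(env, dt=4e-7, max_time=1e-3, tol=1e-14, **kw):
    return SolverConfig(scheme="quadratic_local4", gamma=2.0, sigma=0.1,
                        env=env, dt=dt, tol=tol, max_time=max_time, **kw)


class TestGrid:
    def test_defaults(self):
        g = Grid()
        assert g.n_cells == 200
        assert g.centers[0] == pytest.approx(-0.995)
        assert g.centers[-1] == pytest.approx(0.995)

    def test_non_integer_cell_count_rejected(self):
        with pytest.raises(ValueError):
            Grid(dx=0.013)

    def test_uniform_spacing(self):
        g = Grid(dx=0.025)
        np.testing.assert_allclose(np.diff(g.centers), 0.025, atol=1e-15)


class TestNondimensionalise:
    def test_identity_map(self):
        out = nondimensionalise(D=1.0, L=1.0, gamma=4.0, sigma=0.2, m=10.0)
        assert out == {"gamma": 4.0, "sigma": 0.2, "m": 10.0}

    def test_gamma_scaling(self):
        assert nondimensionalise(D=2.0, L=1.0, gamma=4.0)["gamma"] == pytest.approx(2.0)

    def test_round_trip(self):
        fwd = nondimensionalise(D=3.0, L=2.0, gamma=4.0, sigma=0.2, a=1.5,
                                t=0.7, u=0.9, m=5.0, x=0.3)
        back = dimensionalise(D=3.0, L=2.0, **fwd)
        expected = dict(gamma=4.0, sigma=0.2, a=1.5, t=0.7, u=0.9, m=5.0, x=0.3)
        for key, val in expected.items():
            assert back[key] == pytest.approx(val, rel=1e-14)

    def test_bad_scales(self):
        with pytest.raises(ValueError):
            nondimensionalise(D=0.0, L=1.0, gamma=1.0)
        with pytest.raises(ValueError):
            nondimensionalise(D=1.0, L=-1.0, gamma=1.0)

    def test_unknown_quantity(self):
        with pytest.raises(ValueError):
            nondimensionalise(D=1.0, L=1.0, bogus=1.0)


class TestTotalMass:
    def test_eq30_mass(self, coarse_grid):
        u = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        assert total_mass(u, coarse_grid.dx) == pytest.approx(1.0, abs=1e-10)

    def test_zero(self, coarse_grid):
        assert total_mass(np.zeros(coarse_grid.n_cells), coarse_grid.dx) == 0.0

    def test_linearity(self, coarse_grid):
        u = make_initial_condition("eq41", coarse_grid, p=1.0)
        assert total_mass(2 * u, coarse_grid.dx) == pytest.approx(
            2 * total_mass(u, coarse_grid.dx), rel=1e-14
        )


class TestInitialConditions:
    def test_eq30_support(self, coarse_grid):
        u = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        x = coarse_grid.centers
        assert np.all(u[np.abs(x) > 0.3142] == 0.0)
        assert np.all(u[np.abs(x) < 0.31] > 0.0)

    def test_eq41_three_maxima(self, coarse_grid):
        from aggdiff.metrics import peak_stats

        u = make_initial_condition("eq41", coarse_grid, p=1.0)
        pk = peak_stats(u, coarse_grid.centers)
        assert pk.count == 3
        np.testing.assert_allclose(sorted(pk.locations), [-1 / 3, 0.0, 1 / 3], atol=0.02)

    def test_eq40_two_maxima(self, coarse_grid):
        from aggdiff.metrics import peak_stats

        u = make_initial_condition("eq40", coarse_grid, p=1.0)
        assert peak_stats(u, coarse_grid.centers).count == 2

    def test_gaussian_peak_location(self, coarse_grid):
        u = make_initial_condition("gaussian", coarse_grid, p=1.0)
        assert coarse_grid.centers[np.argmax(u)] == pytest.approx(0.5, abs=0.02)

    def test_unknown_kind(self, coarse_grid):
        with pytest.raises(ValueError):
            make_initial_condition("bogus", coarse_grid)

    @pytest.mark.parametrize("kind,kw", [
        ("eq30", {"gamma": 2.0, "sigma": 0.1}), ("gaussian", {}), ("eq40", {}), ("eq41", {}),
    ])
    def test_normalised_to_p(self, coarse_grid, kind, kw):
        u = make_initial_condition(kind, coarse_grid, p=2.5, **kw)
        assert total_mass(u, coarse_grid.dx) == pytest.approx(2.5, rel=1e-12)


class TestStep:
    def test_zero_fixed_point(self, coarse_grid, flat_env):
        cfg = _local4_config(flat_env)
        state = SimState(u=np.zeros(coarse_grid.n_cells), t=0.0, grid=coarse_grid)
        out = step(state, cfg)
        np.testing.assert_array_equal(out.u, 0.0)

    def test_mass_conserved_each_step(self, coarse_grid):
        env = SingleClumpEnvironment(n=1, amplitude=1.0)
        cfg = _local4_config(env)
        u = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        state = SimState(u=u, t=0.0, grid=coarse_grid)
        ws = _Workspace(cfg, coarse_grid)
        for _ in range(50):
            new = step(state, cfg, ws)
            assert new.mass == pytest.approx(state.mass, abs=1e-12)
            state = new

    def test_near_fixed_point_from_analytic_minimiser(self, coarse_grid, flat_env):
        # Eq-30 lobe on a flat landscape: residual change limited by discretisation
        cfg = _local4_config(flat_env, dt=1e-7)
        u = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        out = step(SimState(u=u, t=0.0, grid=coarse_grid), cfg)
        assert np.abs(out.u - u).max() < 1e-6

    def test_instability_raises(self, coarse_grid):
        env = SingleClumpEnvironment(n=1, amplitude=1.0)
        cfg = _local4_config(env, dt=1e-3, max_time=0.5)
        u = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(InstabilityError):
                run_to_steady(SimState(u=u, t=0.0, grid=coarse_grid), cfg)

    def test_cfl_warning(self, coarse_grid):
        env = SingleClumpEnvironment(n=1, amplitude=1.0)
        cfg = _local4_config(env, dt=1e-3)
        u = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        with pytest.warns(RuntimeWarning, match="stability"):
            step(SimState(u=u, t=0.0, grid=coarse_grid), cfg)


class TestNumbaParity:
    def test_fast_path_matches_numpy(self, coarse_grid):
        pytest.importorskip("numba")
        env = SingleClumpEnvironment(n=1, amplitude=1.0)
        dt = 4e-7
        cfg = _local4_config(env, dt=dt, max_time=200 * dt, tol=1e-30)
        u0 = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fast, _ = run_to_steady(SimState(u=u0.copy(), t=0.0, grid=coarse_grid), cfg)
        ws = _Workspace(cfg, coarse_grid)
        u = u0.copy()
        for _ in range(200):
            u, _c = _advance(u, ws, dt)
        np.testing.assert_allclose(fast.u, u, atol=1e-14)


class TestRunToSteady:
    def test_flat_landscape_stays_near_eq30(self, flat_env):
        # the analytic minimiser is a discrete near-fixed-point; the residual
        # drift is the first-order scheme's O(dx) discretisation error
        g = Grid(dx=0.01)
        u0 = make_initial_condition("eq30", g, p=1.0, gamma=2.0, sigma=0.1)
        cfg = _local4_config(flat_env, dt=2e-8, max_time=0.05, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, diag = run_to_steady(SimState(u=u0.copy(), t=0.0, grid=g), cfg)
        assert diag.converged
        assert np.abs(final.u - u0).max() < 2e-3

    def test_diagnostics_contracts(self, coarse_grid):
        env = SingleClumpEnvironment(n=1, amplitude=1.0)
        u0 = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        cfg = _local4_config(env, dt=4e-7, max_time=0.004, tol=1e-14, record_every=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, diag = run_to_steady(SimState(u=u0, t=0.0, grid=coarse_grid), cfg)
        masses = np.array(diag.masses)
        assert np.abs(masses - 1.0).max() < 1e-12
        assert float(final.u.min()) >= -1e-12
        dE = np.diff(np.array(diag.energies))
        assert dE.max() <= 1e-10 * cfg.record_every
        assert diag.reason in ("steady", "max_time")

    def test_not_converged_flag(self, coarse_grid):
        env = SingleClumpEnvironment(n=1, amplitude=1.0)
        u0 = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        cfg = _local4_config(env, dt=4e-7, max_time=20 * 4e-7, tol=1e-16)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, diag = run_to_steady(SimState(u=u0, t=0.0, grid=coarse_grid), cfg)
        assert not diag.converged
        assert diag.reason == "max_time"


class TestOtherSchemes:
    @pytest.mark.parametrize("scheme,kernel,dt", [
        ("quadratic_nonlocal", LaplaceKernel(10.0), 2e-6),
        ("quadratic_nonlocal", TopHatKernel(0.1), 2e-6),
        ("linear_nonlocal", TopHatKernel(0.1), 1e-5),
    ])
    def test_contracts_short_run(self, coarse_grid, scheme, kernel, dt):
        env = SingleClumpEnvironment(n=1, amplitude=1.0)
        u0 = make_initial_condition("eq30", coarse_grid, p=1.0, gamma=2.0, sigma=0.1)
        cfg = SolverConfig(scheme=scheme, gamma=2.0, kernel=kernel, env=env,
                           dt=dt, tol=1e-14, max_time=4000 * dt, record_every=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, diag = run_to_steady(SimState(u=u0, t=0.0, grid=coarse_grid), cfg)
        masses = np.array(diag.masses)
        assert np.abs(masses - 1.0).max() < 1e-12
        if scheme.startswith("quadratic"):
            assert float(final.u.min()) >= -1e-12
        dE = np.diff(np.array(diag.energies))
        assert dE.max() <= 1e-10 * cfg.record_every

    def test_solver_config_validation(self):
        env = SingleClumpEnvironment(n=1, amplitude=0.0)
        with pytest.raises(ValueError):
            SolverConfig(scheme="quadratic_local4", gamma=2.0, env=env)  # sigma missing
        with pytest.raises(ValueError):
            SolverConfig(scheme="quadratic_nonlocal", gamma=2.0, env=env)  # kernel missing
        with pytest.raises(ValueError):
            SolverConfig(scheme="bogus", gamma=2.0, env=env)
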