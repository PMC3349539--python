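"""Unit and property tests for the two-ODE circuit model."""

import numpy as np
import pytest
import sympy

from fflscape import (
    ParameterSet,
    SystemState,
    derivative,
    get_motif,
    integrate,
    sample_parameters,
    steady_state,
)


def make_params(**overrides):
    base = dict(
        gamma_y=1.0, gamma_z=2.0,
        omega_yx=0.5, omega_zx=0.3, omega_zy=0.7, omega_zxy=0.2,
        alpha_x=5.0, beta_x=4.0, beta_y=3.0, beta_xy=6.0,
        delta_y=1.0, delta_z=0.5,
        n=2, m=1, x_active=1.5,
    )
    base.update(overrides)
    return ParameterSet(**base)


class TestDerivative:
    def test_no_regulation_reduces_to_basal_production(self):
        p = make_params(omega_yx=0.0, omega_zx=0.0, omega_zy=0.0, omega_zxy=0.0)
        dy, dz = derivative(SystemState(y=0.0, z=0.0, x=0.0), p)
        assert dy == pytest.approx(p.gamma_y)
        assert dz == pytest.approx(p.gamma_z)

    def test_steady_state_by_construction_has_zero_rates(self):
        p = make_params()
        y_star = p.gamma_y / p.delta_y
        # Z chosen so dZ/dt = 0 at X = 0
        num = 1 + p.beta_y * p.omega_zy * y_star**p.m
        den = 1 + p.omega_zy * y_star**p.m
        z_star = p.gamma_z / p.delta_z * num / den
        dy, dz = derivative(SystemState(y=y_star, z=z_star, x=0.0), p)
        assert dy == pytest.approx(0.0, abs=1e-12)
        assert dz == pytest.approx(0.0, abs=1e-12)

    def test_matches_symbolic_expression(self):
        """Dual route: hand-built sympy rhs vs the implementation, X > 0."""
        syms = sympy.symbols(
            "gamma_y gamma_z omega_yx omega_zx omega_zy omega_zxy "
            "alpha_x beta_x beta_y beta_xy delta_y delta_z n m x y z",
            positive=True,
        )
        (gy, gz, wyx, wzx, wzy, wzxy, ax, bx, by, bxy, dy_, dz_, n, m, x, y, z) = syms
        dy_expr = gy * (1 + ax * wyx * x**n) / (1 + wyx * x**n) - dy_ * y
        dz_expr = (
            gz
            * (1 + bx * wzx * x**n + by * wzy * y**m + bxy * wzxy * x**n * y**m)
            / (1 + wzx * x**n + wzy * y**m + wzxy * x**n * y**m)
            - dz_ * z
        )
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = make_params(
                gamma_y=rng.uniform(0.1, 5), gamma_z=rng.uniform(0.1, 5),
                omega_yx=rng.uniform(0.01, 10), omega_zx=rng.uniform(0.01, 10),
                omega_zy=rng.uniform(0.01, 10), omega_zxy=rng.uniform(0.01, 10),
                alpha_x=rng.uniform(1.1, 40), beta_x=rng.uniform(1.1, 40),
                beta_y=rng.uniform(1.1, 40), beta_xy=rng.uniform(1.1, 40),
                delta_y=rng.uniform(0.1, 5), delta_z=rng.uniform(0.1, 5),
                n=int(rng.integers(1, 5)), m=int(rng.integers(1, 5)),
                x_active=rng.uniform(0.1, 5),
            )
            state = SystemState(y=rng.uniform(0, 5), z=rng.uniform(0, 5), x=p.x_active)
            subs = dict(
                zip(
                    syms,
                    [p.gamma_y, p.gamma_z, p.omega_yx, p.omega_zx, p.omega_zy,
                     p.omega_zxy, p.alpha_x, p.beta_x, p.beta_y, p.beta_xy,
                     p.delta_y, p.delta_z, p.n, p.m, state.x, state.y, state.z],
                )
            )
            expected = (float(dy_expr.subs(subs)), float(dz_expr.subs(subs)))
            got = derivative(state, p)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_non_finite_state_rejected(self):
        with pytest.raises(ValueError):
            derivative(SystemState(y=np.inf, z=0.0, x=0.0), make_params())


class TestSteadyState:
    def test_input_off_y_closed_form(self):
        p = make_params()
        ss = steady_state(p, input_on=False)
        assert ss.x == 0.0
        assert ss.y == pytest.approx(p.gamma_y / p.delta_y, rel=1e-14)

    def test_input_off_no_binding_gives_basal_levels(self):
        p = make_params(omega_yx=0.0, omega_zx=0.0, omega_zy=0.0, omega_zxy=0.0)
        ss = steady_state(p, input_on=False)
        assert ss.y == pytest.approx(p.gamma_y / p.delta_y)
        assert ss.z == pytest.approx(p.gamma_z / p.delta_z)

    def test_input_on_agrees_with_long_time_integration(self):
        for p in sample_parameters(get_motif("C1"), 5, seed=11):
            ss = steady_state(p, input_on=True)
            traj = integrate(p, horizon_factor=40.0)
            assert traj.z[-1] == pytest.approx(ss.z, rel=1e-5, abs=1e-9)
            assert traj.y[-1] == pytest.approx(ss.y, rel=1e-5, abs=1e-9)


class TestIntegrate:
    def test_inactive_input_gives_constant_trajectory(self):
        p = make_params(x_active=0.0)
        traj = integrate(p)
        assert np.allclose(traj.z, traj.z0, rtol=1e-6)
        assert traj.z_inf == pytest.approx(traj.z0)

    def test_no_binding_makes_input_invisible_to_z(self):
        p = make_params(omega_zx=0.0, omega_zy=0.0, omega_zxy=0.0)
        traj = integrate(p)
        assert np.allclose(traj.z, traj.z0, rtol=1e-6)

    def test_strong_activation_c1_rises_monotonically(self):
        p = make_params(alpha_x=20.0, beta_x=20.0, beta_y=20.0, beta_xy=40.0)
        traj = integrate(p)
        fine = integrate(p, n_points=20001)
        assert traj.z_inf > traj.z0
        assert np.all(np.diff(fine.z) > -1e-8 * traj.z_inf)
        # coarse and fine grids agree where they overlap
        assert np.interp(traj.t, fine.t, fine.z) == pytest.approx(traj.z, rel=1e-5)

    @pytest.mark.parametrize("mid", ["C1", "C3", "I1", "I2"])
    def test_trajectories_nonnegative_bounded_and_settle(self, mid):
        topo = get_motif(mid)
        ok = 0
        sets = sample_parameters(topo, 40, seed=3)
        for p in sets:
            traj = integrate(p)
            assert np.all(traj.z >= -1e-9)
            assert np.all(traj.y >= -1e-9)
            bound = max(traj.z[0], p.gamma_z * max(1, p.beta_x, p.beta_y, p.beta_xy) / p.delta_z)
            assert np.all(traj.z <= bound * (1 + 1e-6))
            if abs(traj.z[-1] - traj.z_inf) <= 1e-4 * max(abs(traj.z_inf), 1e-12):
                ok += 1
        assert ok >= 0.99 * len(sets)


class TestSerialization:
    def test_parameter_set_dict_round_trip(self):
        p = make_params()
        assert ParameterSet.from_dict(p.to_dict()) == p
        assert set(p.to_dict()) == {
            "gamma_y", "gamma_z", "omega_yx", "omega_zx", "omega_zy",
            "omega_zxy", "alpha_x", "beta_x", "beta_y", "beta_xy",
            "delta_y", "delta_z", "n", "m", "x_active",
        }

    def test_trajectory_csv_columns(self, tmp_path):
        traj = integrate(make_params(), n_points=50)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "t,Y,Z"
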