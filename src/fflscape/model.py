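"""Two-ODE gene-circuit model of the feed-forward loop.

The signal protein X is treated as an external step input: X = 0 before the
input arrives and X = ``x_active`` (constant) afterwards; X has no dynamics
of its own.  Protein Y is produced from gene G_Y under regulation by X, and
the output protein Z from gene G_Z under joint regulation by X and Y:

    dY/dt = gamma_y * (1 + alpha_x * w_yx * X^n) / (1 + w_yx * X^n)
            - delta_y * Y

    dZ/dt = gamma_z * (1 + beta_x * w_zx * X^n + beta_y * w_zy * Y^m
                         + beta_xy * w_zxy * X^n * Y^m)
                    / (1 + w_zx * X^n + w_zy * Y^m + w_zxy * X^n * Y^m)
            - delta_z * Z

gamma_* are basal production rates, w_* binding-equilibrium constants,
delta_* linear degradation rates, and n, m multimerization degrees of the
regulators.  The regulation factors alpha_x, beta_x, beta_y, beta_xy are
fold changes relative to basal transcription: values above 1 are
activation, below 1 inhibition.  Because neither equation depends on Z
except through its own degradation, and Y does not depend on Z at all, the
circuit is a feed-forward cascade with a unique, closed-form fixed point
for any constant X.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, fields
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .motifs import ACTIVATION, MotifTopology

__all__ = [
    "ParameterSet",
    "SystemState",
    "Trajectory",
    "derivative",
    "steady_state",
    "integrate",
]


@dataclass(frozen=True)
class ParameterSet:
    """All rate, binding and regulation constants for one circuit instance."""

    gamma_y: float
    gamma_z: float
    omega_yx: float
    omega_zx: float
    omega_zy: float
    omega_zxy: float
    alpha_x: float
    beta_x: float
    beta_y: float
    beta_xy: float
    delta_y: float
    delta_z: float
    n: int
    m: int
    x_active: float

    # binding constants and the input level may be zero (a vanished edge /
    # an absent input); rates and regulation factors must be positive
    _MAY_BE_ZERO = frozenset(
        {"omega_yx", "omega_zx", "omega_zy", "omega_zxy", "x_active"}
    )

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            lo_ok = v >= 0 if f.name in self._MAY_BE_ZERO else v > 0
            if not np.isfinite(v) or not lo_ok:
                raise ValueError(f"{f.name} must be finite and positive, got {v}")
        if int(self.n) != self.n or int(self.m) != self.m or self.n < 1 or self.m < 1:
            raise ValueError("n and m must be integers >= 1")

    def check_signs(self, topology: MotifTopology) -> None:
        """Raise unless regulation factors match the topology's edge signs."""
        pairs = [
            ("alpha_x", self.alpha_x, topology.sign_xy),
            ("beta_x", self.beta_x, topology.sign_xz),
            ("beta_y", self.beta_y, topology.sign_yz),
        ]
        for name, value, sign in pairs:
            if sign == ACTIVATION and value <= 1:
                raise ValueError(f"{name}={value} must exceed 1 for activation")
            if sign != ACTIVATION and value >= 1:
                raise ValueError(f"{name}={value} must be below 1 for inhibition")

    def with_updates(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)


@dataclass(frozen=True)
class SystemState:
    y: float
    z: float
    x: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.y, self.z, self.x)):
            raise ValueError("concentrations must be nonnegative")


@dataclass
class Trajectory:
    """Time course of the circuit after input onset at t = 0."""

    t: np.ndarray
    y: np.ndarray
    z: np.ndarray
    z0: float = field(default=np.nan)  # pre-input steady-state Z
    z_inf: float = field(default=np.nan)  # post-input steady-state Z

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.z.shape != self.t.shape:
            raise ValueError("z and t must have the same length")

    def to_csv(self, path) -> None:
        import pandas as pd

        y = self.y if self.y is not None else np.full_like(self.z, np.nan)
        pd.DataFrame({"t": self.t, "Y": y, "Z": self.z}).to_csv(path, index=False)


def derivative(state: SystemState, params: ParameterSet) -> tuple[float, float]:
    """Right-hand side (dY/dt, dZ/dt) of the circuit ODEs."""
    for v in (state.y, state.z, state.x):
        if not np.isfinite(v):
            raise ValueError("non-finite state component")
    return _rhs(state.x, state.y, state.z, params)


def _rhs(x: float, y: float, z: float, p: ParameterSet) -> tuple[float, float]:
    xn = x**p.n
    ym = y**p.m
    dy = p.gamma_y * (1 + p.alpha_x * p.omega_yx * xn) / (1 + p.omega_yx * xn) - p.delta_y * y
    num = 1 + p.beta_x * p.omega_zx * xn + p.beta_y * p.omega_zy * ym + p.beta_xy * p.omega_zxy * xn * ym
    den = 1 + p.omega_zx * xn + p.omega_zy * ym + p.omega_zxy * xn * ym
    dz = p.gamma_z * num / den - p.delta_z * z
    return dy, dz


def _fixed_point(p: ParameterSet, x: float) -> tuple[float, float]:
    """Closed-form fixed point for constant X (the cascade has no feedback)."""
    xn = x**p.n
    y_star = p.gamma_y / p.delta_y * (1 + p.alpha_x * p.omega_yx * xn) / (1 + p.omega_yx * xn)
    ym = y_star**p.m
    num = 1 + p.beta_x * p.omega_zx * xn + p.beta_y * p.omega_zy * ym + p.beta_xy * p.omega_zxy * xn * ym
    den = 1 + p.omega_zx * xn + p.omega_zy * ym + p.omega_zxy * xn * ym
    z_star = p.gamma_z / p.delta_z * num / den
    return y_star, z_star


def steady_state(
    params: ParameterSet, input_on: bool, residual_tol: float = 1e-9
) -> SystemState:
    """Stable steady state of the circuit with the input off or on.

    With the input off, X = 0 and Y* = gamma_y/delta_y exactly; Z* follows
    from the Z nullcline evaluated at Y*.  With the input on, X = x_active;
    the cascade structure again yields the fixed point in closed form.  The
    residual of the ODE right-hand side is verified against ``residual_tol``
    (relative to the production scale) as a guard against degenerate
    parameter values.
    """
    x = params.x_active if input_on else 0.0
    y_star, z_star = _fixed_point(params, x)
    dy, dz = _rhs(x, y_star, z_star, params)
    scale = max(params.gamma_y, params.gamma_z)
    if np.hypot(dy, dz) > residual_tol * scale:
        raise RuntimeError(
            f"steady-state residual {np.hypot(dy, dz):.3e} exceeds tolerance"
        )
    return SystemState(y=y_star, z=z_star, x=x)


def integrate(
    params: ParameterSet,
    t_grid: Sequence[float] | None = None,
    *,
    horizon_factor: float = 20.0,
    n_points: int = 2000,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate the response to a step input.

    The system starts at the input-off steady state; at t = 0 the input
    switches on (X jumps to ``x_active``) and stays constant.  By default
    the trajectory spans ``horizon_factor`` times the slowest relaxation
    time max(1/delta_y, 1/delta_z), densely sampled so that downstream
    extremum detection is reliable.
    """
    pre = steady_state(params, input_on=False)
    post = steady_state(params, input_on=True)
    if t_grid is None:
        t_end = horizon_factor * max(1.0 / params.delta_y, 1.0 / params.delta_z)
        t_grid = np.linspace(0.0, t_end, n_points)
    else:
        t_grid = np.asarray(t_grid, dtype=float)

    x = params.x_active

    def rhs(_t, s):
        return _rhs(x, s[0], s[1], params)

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [pre.y, pre.z],
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed for {params}: {sol.message}")
    return Trajectory(t=sol.t, y=sol.y[0], z=sol.y[1], z0=pre.z, z_inf=post.z)
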