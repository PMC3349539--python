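"""Qualitative classification of the output response Z(t).

After input onset a circuit's output either moves monotonically to its new
steady state (*grader* dynamics, G) or transiently over/undershoots before
settling (*pulser* dynamics, P).  Classes are annotated with the sign of
the initial slope and, for pulsers, the sign of the final target level
relative to the pre-input level:

    G+     monotone rise            G-     monotone decay
    P+T+   pulse up, settles high   P+T-   pulse up, settles low
    P-T-   dip down, settles low    P-T+   dip down, settles high

All comparisons use a tolerance band of width ``rel_tol * z0`` around the
pre-input level so that solver ripple is never mistaken for a pulse.
Responses that never leave the band are reported as NO_RESPONSE; exact
ties (a pulse whose endpoint lands exactly on z0) are reported AMBIGUOUS.
Both are excluded from probability counts downstream.
"""

from __future__ import annotations

import enum

import numpy as np

from .model import Trajectory

__all__ = ["Outcome", "CLASS_LABELS", "classify", "initial_slope_sign"]

CLASS_LABELS = ("G+", "G-", "P+T+", "P+T-", "P-T-", "P-T+")


class Outcome(str, enum.Enum):
    G_PLUS = "G+"
    G_MINUS = "G-"
    P_PLUS_T_PLUS = "P+T+"
    P_PLUS_T_MINUS = "P+T-"
    P_MINUS_T_MINUS = "P-T-"
    P_MINUS_T_PLUS = "P-T+"
    NO_RESPONSE = "no-response"
    AMBIGUOUS = "ambiguous"

    @property
    def is_class(self) -> bool:
        """True for the six functional classes, False for excluded outcomes."""
        return self.value in CLASS_LABELS


def _band(z0: float, rel_tol: float) -> float:
    # absolute floor guards the z0 == 0 edge case
    return rel_tol * abs(z0) + 1e-300


def initial_slope_sign(traj: Trajectory, rel_tol: float = 0.01) -> int:
    """Sign of the first excursion of z beyond the tolerance band around z0.

    Returns +1 or -1; 0 if z never leaves the band (undefined sign).
    """
    tol = _band(traj.z0, rel_tol)
    dev = traj.z - traj.z0
    outside = np.abs(dev) > tol
    if not outside.any():
        return 0
    return int(np.sign(dev[np.argmax(outside)]))


def classify(traj: Trajectory, rel_tol: float = 0.01) -> Outcome:
    """Assign one of the six response classes, NO_RESPONSE or AMBIGUOUS."""
    z, z0, z_inf = traj.z, traj.z0, traj.z_inf
    tol = _band(z0, rel_tol)

    excursion = np.max(np.abs(z - z0))
    settled = abs(z_inf - z0) <= tol
    if settled and excursion <= tol:
        return Outcome.NO_RESPONSE

    slope = initial_slope_sign(traj, rel_tol)
    if slope == 0:
        # z_inf differs from z0 yet the sampled curve never left the band:
        # treat as unresolved
        return Outcome.AMBIGUOUS

    # monotone within tolerance: total excursion beyond the envelope
    # [min(z0, z_inf), max(z0, z_inf)] stays below rel_tol * |z_inf - z0|
    lo, hi = min(z0, z_inf), max(z0, z_inf)
    overshoot = np.maximum(z - hi, 0.0) + np.maximum(lo - z, 0.0)
    ripple_allowance = rel_tol * max(abs(z_inf - z0), tol)
    monotone = np.max(overshoot) <= ripple_allowance

    if monotone and not settled:
        return Outcome.G_PLUS if z_inf > z0 else Outcome.G_MINUS

    # pulser: target sign from the final level relative to z0
    if z_inf > z0 + tol:
        target = +1
    elif z_inf < z0 - tol:
        target = -1
    else:
        # near-perfect adaptation: decide by the strict side of z0 the
        # endpoint lies on; an exact tie cannot be resolved
        if z_inf > z0:
            target = +1
        elif z_inf < z0:
            target = -1
        else:
            return Outcome.AMBIGUOUS

    if slope > 0:
        return Outcome.P_PLUS_T_PLUS if target > 0 else Outcome.P_PLUS_T_MINUS
    return Outcome.P_MINUS_T_MINUS if target < 0 else Outcome.P_MINUS_T_PLUS
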