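"""Synthetic inputs for exercising the pipeline without external data.

Three generators: random row-stochastic probability tables with tunable
peakedness (Dirichlet rows), abundance vectors with an exact target
Pearson correlation to a given score vector, and piecewise-smooth toy
trajectories whose response class is known by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import CLASS_LABELS
from .compare import AbundanceVector
from .landscape import ProbabilityTable
from .model import Trajectory
from .motifs import MOTIF_IDS

__all__ = [
    "random_probability_table",
    "abundance_with_correlation",
    "toy_trajectory",
]


def random_probability_table(seed: int, concentration: float = 1.0) -> ProbabilityTable:
    """Eight random probability rows from a symmetric Dirichlet.

    Large ``concentration`` pushes rows toward the uniform distribution
    (kurtosis -> -10/3); small values toward one-hot rows (kurtosis -> 6).
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet([concentration] * len(CLASS_LABELS), size=len(MOTIF_IDS))
    df = pd.DataFrame(rows, index=list(MOTIF_IDS), columns=list(CLASS_LABELS))
    return ProbabilityTable(df)


def abundance_with_correlation(
    scores, target_r: float, noise_seed: int, source: str = "synthetic"
) -> tuple[AbundanceVector, float]:
    """Nonnegative, normalized 8-vector with a target Pearson r to ``scores``.

    The construction mixes the standardized score vector with an exactly
    orthogonalized noise vector, then shifts and rescales to the simplex;
    shifting and positive scaling leave Pearson correlation unchanged, so
    the achieved r (returned alongside) equals the target up to the sign
    degeneracy of a zero-noise draw.
    """
    if not -1 <= target_r <= 1:
        raise ValueError("target_r must lie in [-1, 1]")
    s = np.asarray(scores, dtype=float)
    if s.size != len(MOTIF_IDS) or np.ptp(s) == 0:
        raise ValueError("scores must be 8 values with nonzero spread")
    rng = np.random.default_rng(noise_seed)
    s_std = (s - s.mean()) / s.std()
    noise = rng.standard_normal(s.size)
    noise -= noise.mean()
    noise -= (noise @ s_std) / (s_std @ s_std) * s_std  # orthogonalize
    if np.linalg.norm(noise) < 1e-12:  # pathological draw
        noise = np.roll(s_std, 1) - s_std
        noise -= (noise @ s_std) / (s_std @ s_std) * s_std
    noise /= noise.std()
    mix = target_r * s_std + np.sqrt(max(0.0, 1 - target_r**2)) * noise

    shifted = mix - mix.min() + 0.05 * np.ptp(mix)  # strictly positive
    values = shifted / shifted.sum()
    vec = AbundanceVector(pd.Series(values, index=list(MOTIF_IDS)), source)
    from .compare import pearson

    achieved = pearson(s, vec.to_numpy())
    return vec, achieved


def toy_trajectory(
    shape: str,
    z0: float = 1.0,
    z_inf: float = 2.0,
    pulse_height: float | None = None,
    grid: int = 2001,
    t_end: float = 10.0,
) -> Trajectory:
    """Smooth synthetic Z(t) that the class definitions label ``shape``.

    Graders relax exponentially from z0 to z_inf (``z_inf`` must lie on
    the correct side of ``z0``).  Pulsers add a transient excursion of
    amplitude ``pulse_height`` above/below both levels before settling at
    ``z_inf``; the excursion direction follows the class's initial-slope
    sign, so e.g. ("P+T-", 1, 0.5, 3) rises to ~3 before decaying to 0.5.
    """
    if shape not in CLASS_LABELS:
        raise ValueError(f"shape must be one of {CLASS_LABELS}")
    if z0 < 0 or z_inf < 0:
        raise ValueError("concentrations must be nonnegative")
    t = np.linspace(0.0, t_end, grid)
    base = z_inf + (z0 - z_inf) * np.exp(-t)

    if shape.startswith("G"):
        if shape == "G+" and z_inf <= z0:
            raise ValueError("G+ requires z_inf > z0")
        if shape == "G-" and z_inf >= z0:
            raise ValueError("G- requires z_inf < z0")
        z = base
    else:
        slope = +1 if shape[1] == "+" else -1
        target = +1 if shape[3] == "+" else -1
        if target > 0 and z_inf <= z0:
            raise ValueError(f"{shape} requires z_inf > z0")
        if target < 0 and z_inf >= z0:
            raise ValueError(f"{shape} requires z_inf < z0")
        if pulse_height is None:
            pulse_height = 2.0 * max(abs(z_inf - z0), 0.5 * max(z0, 1e-6), 1e-6)
        # bump peaking early, vanishing at t=0 and as t -> inf
        bump = np.exp(1.0) * (t / 1.0) * np.exp(-t / 1.0)
        extreme = max(z0, z_inf) if slope > 0 else min(z0, z_inf)
        amplitude = slope * (abs(extreme - z_inf) + pulse_height)
        z = base + amplitude * bump
        if slope < 0:
            z = np.maximum(z, 0.0)
    return Trajectory(t=t, y=None, z=z, z0=z0, z_inf=z_inf)
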