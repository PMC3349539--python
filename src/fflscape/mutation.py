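"""Mutational robustness and evolvability of FFL circuits.

A mutation is a change to a single circuit parameter.  Topology-changing
mutations are excluded: the regulation factors alpha_x, beta_x, beta_y
(and the joint factor beta_xy) stay on their side of 1, so activation
never turns into inhibition.  Two regimes are compared:

* *single* — every mutation is applied to the original circuit, the
  response class before and after is binned, and the mutation discarded;
* *accumulated* — mutations persist, and each round bins the transition
  from the previous round's class to the new one.

Binned transition counts, normalized by the total number of binned
events, form a 6 x 6 transition-frequency matrix per motif and regime
whose diagonal mass is the mutational *robustness* (fraction of
class-preserving mutations).  Evolvability compares the two regimes:

    E = 1 - R_accumulated / R_single,

large E meaning the circuit's function drifts readily once mutations
accumulate even though single mutations are mostly neutral.  Reference
matrices from the analytic treatment of the FFL response backbone ship
as package data; simulated matrices use parameter-level mutations and are
compared to them qualitatively, not entry-by-entry.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CLASS_LABELS, classify
from .landscape import PriorConfig, sample_parameters
from .model import ParameterSet, integrate
from .motifs import ACTIVATION, MOTIF_IDS, MotifTopology

__all__ = [
    "TransitionMatrix",
    "MutationConfig",
    "mutate",
    "transition_matrices",
    "robustness",
    "evolvability",
    "load_reference_transitions",
]

_MUTABLE_POSITIVE = (
    "gamma_y", "gamma_z", "omega_yx", "omega_zx", "omega_zy", "omega_zxy",
    "delta_y", "delta_z", "x_active",
)
_MUTABLE_REGULATION = ("alpha_x", "beta_x", "beta_y", "beta_xy")
_MUTABLE_INTEGER = ("n", "m")
MUTABLE_FIELDS = _MUTABLE_POSITIVE + _MUTABLE_REGULATION + _MUTABLE_INTEGER


@dataclass
class TransitionMatrix:
    """6 x 6 joint frequency of (class before, class after) one mutation step.

    Entries are joint frequencies over all binned events, so the grand
    total is 1 (up to print rounding for the packaged references), not
    the rows.  The diagonal holds the functionally invariant fraction.
    """

    motif_id: str
    regime: str  # "single" or "accumulated"
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.regime not in ("single", "accumulated"):
            raise ValueError(f"unknown regime {self.regime!r}")
        df = self.values.loc[list(CLASS_LABELS), list(CLASS_LABELS)].astype(float)
        if (df.values < 0).any():
            raise ValueError("transition frequencies must be nonnegative")
        # grand totals of the reference matrices hover around 1; one printed
        # block (C3, single) totals 1.106, so the hard bound is lenient
        if df.values.sum() > 1.2:
            raise ValueError(f"grand total {df.values.sum():.4f} exceeds 1")
        self.values = df

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()


@dataclass(frozen=True)
class MutationConfig:
    n_parameter_sets: int = 1000
    max_rounds: int = 10_000
    convergence_window: int = 500
    convergence_threshold: float = 1e-3
    kernel_scale: float = 1.0  # mutation step is *exp(eps), eps ~ U(+-scale*ln 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_parameter_sets, self.convergence_window) < 1 or self.max_rounds < 0:
            raise ValueError("counts must be positive")
        if self.convergence_threshold <= 0 or self.kernel_scale < 0:
            raise ValueError("threshold must be positive, kernel_scale nonnegative")


def _sign_interval(sign: int, f_max: float) -> tuple[float, float]:
    return (1.0, f_max) if sign == ACTIVATION else (1.0 / f_max, 1.0)


def mutate(
    params: ParameterSet,
    topology: MotifTopology,
    rng: np.random.Generator,
    *,
    prior: PriorConfig | None = None,
    kernel_scale: float = 1.0,
) -> ParameterSet:
    """Change exactly one randomly chosen parameter.

    Positive parameters are multiplied by exp(eps), eps uniform on
    [-kernel_scale*ln 10, +kernel_scale*ln 10], resampled until the value
    stays inside its prior range (and, for regulation factors, on its side
    of 1).  Multimerization degrees step by +-1 inside the allowed range,
    with probability min(1, kernel_scale) so a vanishing kernel leaves
    them untouched.
    """
    prior = prior or PriorConfig()
    name = MUTABLE_FIELDS[rng.integers(len(MUTABLE_FIELDS))]
    value = getattr(params, name)

    if name in _MUTABLE_INTEGER:
        if rng.uniform() >= min(1.0, kernel_scale):
            return params.with_updates()
        lo, hi = prior.nm_range
        step = int(rng.choice((-1, 1)))
        new = int(np.clip(value + step, lo, hi))
        if new == value:  # at a boundary, step inward
            new = int(np.clip(value - step, lo, hi))
        return params.with_updates(**{name: new})

    if name in _MUTABLE_REGULATION:
        sign = {
            "alpha_x": topology.sign_xy,
            "beta_x": topology.sign_xz,
            "beta_y": topology.sign_yz,
            "beta_xy": topology.sign_xz * topology.sign_yz,
        }[name]
        lo, hi = _sign_interval(sign, prior.f_max)
    elif name == "x_active":
        lo, hi = prior.x_active_range
    elif name.startswith("omega"):
        lo, hi = prior.omega_range
    else:
        lo, hi = prior.rate_range

    width = kernel_scale * np.log(10.0)
    for _ in range(1000):
        new = value * np.exp(rng.uniform(-width, width))
        if lo <= new <= hi:
            return params.with_updates(**{name: new})
    # kernel so wide relative to the interval that resampling failed;
    # fall back to a fresh draw inside the interval
    new = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return params.with_updates(**{name: new})


def _classify_params(params: ParameterSet, rel_tol: float):
    try:
        return classify(integrate(params), rel_tol=rel_tol)
    except RuntimeError:
        return None


def transition_matrices(
    topology: MotifTopology,
    cfg: MutationConfig,
    *,
    prior: PriorConfig | None = None,
    rel_tol: float = 0.01,
) -> tuple[TransitionMatrix, TransitionMatrix]:
    """Estimate the (single, accumulated) transition matrices for one motif.

    ``cfg.n_parameter_sets`` circuits are drawn from the prior; each is
    mutated for up to ``cfg.max_rounds`` rounds, stopping early once no
    bin frequency moves more than the convergence threshold across the
    convergence window.  Mutations that drive a circuit out of the six
    classes (no response) are skipped, reverted and logged, never binned.
    """
    prior = prior or PriorConfig()
    rng = np.random.default_rng(cfg.seed)
    circuits = sample_parameters(topology, cfg.n_parameter_sets, rng, prior)

    idx = {lab: i for i, lab in enumerate(CLASS_LABELS)}
    results = {}
    for regime in ("single", "accumulated"):
        counts = np.zeros((6, 6))
        skipped = 0
        states = []  # (params, class index); only classifiable circuits enter
        for params in circuits:
            outcome = _classify_params(params, rel_tol)
            if outcome is None or not outcome.is_class:
                skipped += 1
                continue
            states.append((params, idx[outcome.value]))

        last_freq = None
        stable_for = 0
        for round_no in range(cfg.max_rounds):
            for i, (params, cls) in enumerate(states):
                candidate = mutate(
                    params, topology, rng, prior=prior, kernel_scale=cfg.kernel_scale
                )
                outcome = _classify_params(candidate, rel_tol)
                if outcome is None or not outcome.is_class:
                    skipped += 1
                    continue  # revert: states[i] untouched
                new_cls = idx[outcome.value]
                counts[cls, new_cls] += 1
                if regime == "accumulated":
                    states[i] = (candidate, new_cls)

            total = counts.sum()
            freq = counts / total if total else counts
            if last_freq is not None:
                if np.max(np.abs(freq - last_freq)) < cfg.convergence_threshold:
                    stable_for += 1
                    if stable_for >= cfg.convergence_window:
                        break
                else:
                    stable_for = 0
            last_freq = freq.copy()

        total = counts.sum()
        values = pd.DataFrame(
            counts / total if total else counts,
            index=list(CLASS_LABELS),
            columns=list(CLASS_LABELS),
        )
        tm = TransitionMatrix(topology.motif_id, regime, values)
        tm.skipped = skipped
        results[regime] = tm
    return results["single"], results["accumulated"]


def robustness(tm: TransitionMatrix) -> float:
    """Diagonal mass: fraction of functionally invariant mutations."""
    return float(np.trace(tm.matrix()))


def evolvability(single: TransitionMatrix, accumulated: TransitionMatrix) -> float:
    """E = 1 - R_accumulated / R_single, the relative loss of robustness.

    Nominally in [0, 1]; empirical matrices may stray outside, in which
    case the value is returned as-is.
    """
    r1 = robustness(single)
    if r1 <= 0:
        raise ZeroDivisionError("single-mutation robustness is zero")
    return 1.0 - robustness(accumulated) / r1


def load_reference_transitions() -> dict[tuple[str, str], TransitionMatrix]:
    """Packaged reference matrices, keyed by (motif_id, regime).

    Columns are mapped by header label, never by position.
    """
    out: dict[tuple[str, str], TransitionMatrix] = {}
    data = importlib.resources.files("fflscape.data")
    for regime in ("single", "accumulated"):
        with importlib.resources.as_file(data / f"transitions_{regime}.csv") as path:
            df = pd.read_csv(path)
        for mid in MOTIF_IDS:
            block = df[df["motif"] == mid].set_index("from")
            if block.shape[0] != 6:
                raise ValueError(f"expected 6 rows for {mid} {regime}")
            out[(mid, regime)] = TransitionMatrix(mid, regime, block.drop(columns="motif"))
    return out
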