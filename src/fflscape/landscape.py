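"""Structure-function map of the FFL: P(class | motif).

For each motif, circuit parameter sets are drawn from a broad log-uniform
prior subject to the motif's edge-sign constraints, simulated through the
step response, and classified; the conditional probability table is the
matrix of class frequencies over classified samples.  The reference table
of conditional probabilities (derived analytically in prior work on the
FFL response backbone) ships as package data and is the authoritative
input for the downstream shape statistics; the Monte-Carlo estimator here
is a reproduction apparatus whose exact numbers depend on the prior.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CLASS_LABELS, Outcome, classify
from .model import ParameterSet, integrate
from .motifs import ACTIVATION, MOTIF_IDS, MotifTopology, get_motif

__all__ = [
    "PriorConfig",
    "ProbabilityTable",
    "sample_parameters",
    "estimate_landscape",
    "load_reference_table",
]


@dataclass(frozen=True)
class PriorConfig:
    """Log-uniform sampling ranges for circuit parameters.

    Regulation factors are drawn on [1, f_max] for an activating edge and
    [1/f_max, 1] for an inhibiting one, so the fold change never crosses 1.
    The joint-regulation factor beta_xy is sign-constrained to the product
    sign of beta_x and beta_y (coherent joint regulation).
    """

    f_max: float = 50.0
    rate_range: tuple[float, float] = (0.01, 100.0)
    omega_range: tuple[float, float] = (0.01, 100.0)
    x_active_range: tuple[float, float] = (0.1, 10.0)
    nm_range: tuple[int, int] = (1, 4)

    def __post_init__(self) -> None:
        if self.f_max <= 1:
            raise ValueError("f_max must exceed 1")
        for lo, hi in (self.rate_range, self.omega_range, self.x_active_range):
            if not (0 < lo < hi):
                raise ValueError("ranges must satisfy 0 < lo < hi")
        if not (1 <= self.nm_range[0] <= self.nm_range[1]):
            raise ValueError("multimerization range must lie within [1, inf)")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _regulation_factor(rng: np.random.Generator, sign: int, f_max: float) -> float:
    if sign == ACTIVATION:
        return _log_uniform(rng, 1.0, f_max)
    return _log_uniform(rng, 1.0 / f_max, 1.0)


def sample_parameters(
    topology: MotifTopology,
    n_sets: int,
    seed: int | np.random.Generator,
    prior: PriorConfig | None = None,
) -> list[ParameterSet]:
    """Draw sign-consistent parameter sets for one motif, reproducibly."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    prior = prior or PriorConfig()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        beta_x = _regulation_factor(rng, topology.sign_xz, prior.f_max)
        beta_y = _regulation_factor(rng, topology.sign_yz, prior.f_max)
        joint_sign = topology.sign_xz * topology.sign_yz
        p = ParameterSet(
            gamma_y=_log_uniform(rng, *prior.rate_range),
            gamma_z=_log_uniform(rng, *prior.rate_range),
            omega_yx=_log_uniform(rng, *prior.omega_range),
            omega_zx=_log_uniform(rng, *prior.omega_range),
            omega_zy=_log_uniform(rng, *prior.omega_range),
            omega_zxy=_log_uniform(rng, *prior.omega_range),
            alpha_x=_regulation_factor(rng, topology.sign_xy, prior.f_max),
            beta_x=beta_x,
            beta_y=beta_y,
            beta_xy=_regulation_factor(rng, joint_sign, prior.f_max),
            delta_y=_log_uniform(rng, *prior.rate_range),
            delta_z=_log_uniform(rng, *prior.rate_range),
            n=int(rng.integers(prior.nm_range[0], prior.nm_range[1] + 1)),
            m=int(rng.integers(prior.nm_range[0], prior.nm_range[1] + 1)),
            x_active=_log_uniform(rng, *prior.x_active_range),
        )
        p.check_signs(topology)
        out.append(p)
    return out


class ProbabilityTable:
    """8 x 6 row-stochastic table of P(class | motif).

    Thin wrapper over a DataFrame indexed by motif id with the six class
    labels as columns, enforcing nonnegativity and row sums of 1.
    """

    ROW_SUM_TOL = 1e-3

    def __init__(self, df: pd.DataFrame):
        df = df.loc[list(MOTIF_IDS), list(CLASS_LABELS)].astype(float)
        if (df.values < -1e-12).any() or (df.values > 1 + 1e-12).any():
            raise ValueError("probabilities must lie in [0, 1]")
        sums = df.sum(axis=1)
        bad = sums[(sums - 1).abs() > self.ROW_SUM_TOL]
        if len(bad):
            raise ValueError(f"rows do not sum to 1: {dict(bad.round(4))}")
        self.df = df

    def row(self, motif_id: str) -> np.ndarray:
        return self.df.loc[motif_id].to_numpy()

    def to_csv(self, path) -> None:
        self.df.rename_axis("motif").to_csv(path)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {mid: dict(zip(CLASS_LABELS, map(float, self.row(mid))))
                   for mid in MOTIF_IDS}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_csv(cls, path) -> "ProbabilityTable":
        df = pd.read_csv(path).set_index("motif")
        if set(df.columns) != set(CLASS_LABELS):
            raise ValueError(f"expected class columns {CLASS_LABELS}, got {tuple(df.columns)}")
        if set(df.index) != set(MOTIF_IDS):
            raise ValueError("expected one row per motif C1-C4, I1-I4")
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbabilityTable) and self.df.equals(other.df)


@dataclass
class LandscapeEstimate:
    """Monte-Carlo estimate plus its bookkeeping."""

    table: ProbabilityTable
    counts: pd.DataFrame
    excluded: pd.Series  # per-motif count of no-response / ambiguous samples
    warnings: list[str] = field(default_factory=list)


def estimate_landscape(
    n_sets_per_motif: int,
    seed: int,
    prior: PriorConfig | None = None,
    *,
    rel_tol: float = 0.01,
    motif_ids: tuple[str, ...] = MOTIF_IDS,
) -> LandscapeEstimate:
    """Estimate P(class | motif) by simulate-and-classify sampling.

    One master seed spawns an independent child seed per motif, so per-motif
    results do not change when other motifs are added or removed.
    Non-classifiable samples (no-response, ambiguous) are excluded from the
    denominator and reported; a motif losing more than half its samples
    raises a warning in the returned report.
    """
    if n_sets_per_motif < 1:
        raise ValueError("n_sets_per_motif must be >= 1")
    prior = prior or PriorConfig()
    seeds = np.random.SeedSequence(seed).spawn(len(MOTIF_IDS))
    child = dict(zip(MOTIF_IDS, seeds))

    counts = pd.DataFrame(0, index=list(MOTIF_IDS), columns=list(CLASS_LABELS))
    excluded = pd.Series(0, index=list(MOTIF_IDS))
    warnings: list[str] = []
    for mid in motif_ids:
        rng = np.random.default_rng(child[mid])
        for params in sample_parameters(get_motif(mid), n_sets_per_motif, rng, prior):
            try:
                outcome = classify(integrate(params), rel_tol=rel_tol)
            except RuntimeError:
                excluded[mid] += 1
                continue
            if outcome.is_class:
                counts.loc[mid, outcome.value] += 1
            else:
                excluded[mid] += 1
        if excluded[mid] > n_sets_per_motif / 2:
            warnings.append(
                f"{mid}: {excluded[mid]}/{n_sets_per_motif} samples excluded"
            )

    probs = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
    # rows with no classified samples (motif skipped by the caller, or all
    # samples excluded) get a uniform placeholder so the table type-checks;
    # the counts/excluded frames carry the real record
    for mid in MOTIF_IDS:
        if probs.loc[mid].isna().any():
            probs.loc[mid] = 1.0 / len(CLASS_LABELS)
            if mid in motif_ids:
                warnings.append(f"{mid}: no classifiable samples")
    return LandscapeEstimate(
        table=ProbabilityTable(probs), counts=counts, excluded=excluded, warnings=warnings
    )


def load_reference_table() -> ProbabilityTable:
    """The packaged reference table of conditional probabilities."""
    ref = importlib.resources.files("fflscape.data") / "conditional_probabilities.csv"
    with importlib.resources.as_file(ref) as path:
        return ProbabilityTable.from_csv(path)
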