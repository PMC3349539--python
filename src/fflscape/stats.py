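"""Shape statistics of the per-motif function-probability distributions.

A motif committed to a single response has a sharply peaked (one-hot)
probability row; a fully flexible motif a uniform one.  Peakedness is
measured by the bias-corrected sample kurtosis over the n = 6 class
probabilities,

    K = n(n+1) / ((n-1)(n-2)(n-3)) * sum_j ((p_j - <P>)/sigma)^4
        - 3 (n-1)^2 / ((n-2)(n-3)),

with sigma the sample standard deviation (n-1 denominator).  For n = 6
the one-hot row gives K = 6 (maximal specialization) and the uniform row
the limiting value K = -10/3 (maximal flexibility); every probability row
lies between the two.  Plasticity is the distance of |K| from the
midpoint K0 = (6 - 10/3)/2 = 4/3 of that interval,

    psi = |K| - K0,

small psi meaning a balanced trade-off between specialization and
flexibility.  The predicted relative abundance of a motif is the
normalized inverse plasticity,

    rho_i = psi_i^-1 / sum_j psi_j^-1,

so balanced motifs are predicted common.  Shannon entropy over the same
row (in bits, 0 for one-hot, log2 6 for uniform) is the complementary
homogeneity measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import ProbabilityTable
from .motifs import MOTIF_IDS

__all__ = [
    "PlasticityConfig",
    "sample_kurtosis",
    "shannon_entropy",
    "psi",
    "rho",
    "score_table",
]

N_CLASSES = 6
K_SPECIALIZED = 6.0
K_FLEXIBLE = -10.0 / 3.0  # exact value; prints as -3.33


@dataclass(frozen=True)
class PlasticityConfig:
    n_classes: int = N_CLASSES
    k_specialized: float = K_SPECIALIZED
    k_flexible: float = K_FLEXIBLE
    k0: float | None = None  # None -> midpoint of (k_flexible, k_specialized)

    def __post_init__(self) -> None:
        if self.k0 is None:
            object.__setattr__(
                self, "k0", (self.k_flexible + self.k_specialized) / 2.0
            )


def _check_probs(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (N_CLASSES,):
        raise ValueError(f"expected a {N_CLASSES}-vector, got shape {p.shape}")
    if (p < 0).any() or not np.isfinite(p).all():
        raise ValueError("probabilities must be finite and nonnegative")
    if abs(p.sum() - 1.0) > 1e-3:
        raise ValueError(f"probabilities must sum to 1, got {p.sum():.6f}")
    return p


def sample_kurtosis(p) -> float:
    """Bias-corrected sample kurtosis of a 6-class probability vector.

    The uniform vector has zero variance; its kurtosis is defined by the
    symmetric-perturbation limit, which evaluates to -10/3 for n = 6.
    """
    p = _check_probs(p)
    n = p.size
    mean = p.mean()
    sigma = p.std(ddof=1)
    if sigma < 1e-12:
        return K_FLEXIBLE
    fourth = np.sum(((p - mean) / sigma) ** 4)
    return float(
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * fourth
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )


def shannon_entropy(p) -> float:
    """Shannon entropy in bits; 0 * log(0) taken as 0."""
    p = _check_probs(p)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() + 0.0)  # +0.0 avoids -0.0


def psi(kurtosis: float, cfg: PlasticityConfig | None = None) -> float:
    """Plasticity: distance of |K| from the interval midpoint K0."""
    cfg = cfg or PlasticityConfig()
    tol = 1e-9
    if not (cfg.k_flexible - tol <= kurtosis <= cfg.k_specialized + tol):
        raise ValueError(
            f"kurtosis {kurtosis} outside [{cfg.k_flexible}, {cfg.k_specialized}]"
        )
    return abs(kurtosis) - cfg.k0


def rho(psis) -> np.ndarray:
    """Normalized inverse plasticity over the eight motifs."""
    psis = np.asarray(psis, dtype=float)
    if (psis <= 0).any():
        raise ValueError("rho requires strictly positive psi values")
    inv = 1.0 / psis
    return inv / inv.sum()


def load_reference_scores() -> pd.DataFrame:
    """Packaged printed per-motif scores (kurtosis, psi, rho)."""
    import importlib.resources

    ref = importlib.resources.files("fflscape.data") / "motif_scores_reference.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path).set_index("motif")


def score_table(
    table: ProbabilityTable, cfg: PlasticityConfig | None = None
) -> pd.DataFrame:
    """Kurtosis, entropy, psi and rho for every motif row of a table.

    Returns a DataFrame indexed by motif with columns
    ``kurtosis, entropy_bits, psi, rho``.
    """
    cfg = cfg or PlasticityConfig()
    rows = {}
    for mid in MOTIF_IDS:
        p = table.row(mid)
        k = sample_kurtosis(p)
        rows[mid] = {
            "kurtosis": k,
            "entropy_bits": shannon_entropy(p),
            "psi": psi(k, cfg),
        }
    scores = pd.DataFrame.from_dict(rows, orient="index")
    scores.index.name = "motif"
    scores["rho"] = rho(scores["psi"].to_numpy())
    return scores
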