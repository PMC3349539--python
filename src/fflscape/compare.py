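"""Correlating motif scores with each other and with abundance patterns.

The central empirical claim is that a motif's predicted abundance rho
(inverse plasticity) tracks how often the motif occurs in real
transcription networks, and that evolvability E anticorrelates with
plasticity psi.  Real abundance counts are not packaged in authoritative
form; an approximate, figure-derived fixture (clearly labelled synthetic)
supports ranking checks only, and user-supplied abundance CSVs
(columns ``motif,abundance,source``) can be used for quantitative ones.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import MOTIF_IDS

__all__ = [
    "AbundanceVector",
    "pearson",
    "compare_report",
    "load_approx_abundances",
]


@dataclass
class AbundanceVector:
    """Relative motif abundances (fractions summing to 1) from one source."""

    values: pd.Series  # indexed by motif id
    source: str

    def __post_init__(self) -> None:
        s = self.values.reindex(list(MOTIF_IDS)).astype(float)
        if s.isna().any():
            missing = list(s[s.isna()].index)
            raise ValueError(f"missing motifs {missing} in source {self.source!r}")
        if (s < 0).any():
            raise ValueError("abundances must be nonnegative")
        if abs(s.sum() - 1.0) > 1e-3:
            raise ValueError(f"abundances must sum to 1, got {s.sum():.4f}")
        self.values = s

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two aligned vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d vectors of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def compare_report(
    scores: pd.DataFrame,
    evolvability: pd.Series | None = None,
    abundances: list[AbundanceVector] | None = None,
) -> dict:
    """All pairwise correlations between scores, E and abundance vectors.

    ``scores`` is the output of :func:`fflscape.stats.score_table`
    (columns kurtosis, entropy_bits, psi, rho).  Returns a JSON-friendly
    dict with the correlation matrix entries, per-source abundance
    correlations, rank orderings and the top-two-motifs check.
    """
    scores = scores.loc[list(MOTIF_IDS)]
    columns = {c: scores[c].to_numpy() for c in ("kurtosis", "entropy_bits", "psi", "rho")}
    if evolvability is not None:
        ev = evolvability.reindex(list(MOTIF_IDS)).astype(float)
        if ev.isna().any():
            raise ValueError("evolvability must cover all eight motifs")
        columns["E"] = ev.to_numpy()

    report: dict = {"correlations": {}, "abundance": {}, "rankings": {}}
    names = list(columns)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            report["correlations"][f"{a}_vs_{b}"] = pearson(columns[a], columns[b])

    for vec in abundances or []:
        obs = vec.to_numpy()
        entry = {
            f"{name}_vs_abundance": pearson(columns[name], obs) for name in names
        }
        top2 = list(vec.values.sort_values(ascending=False).index[:2])
        entry["top_two_motifs"] = top2
        entry["top_two_are_C1_I1"] = sorted(top2) == ["C1", "I1"]
        report["abundance"][vec.source] = entry

    for name, vals in columns.items():
        order = pd.Series(vals, index=list(MOTIF_IDS)).sort_values(ascending=False)
        report["rankings"][name] = list(order.index)
    return report


def report_markdown(report: dict) -> str:
    """Render the correlation section of a compare report as a Markdown table."""
    lines = ["| pair | r |", "| --- | --- |"]
    for pair, r in report["correlations"].items():
        lines.append(f"| {pair.replace('_vs_', ' vs ')} | {r:.3f} |")
    for source, entry in report.get("abundance", {}).items():
        for key, val in entry.items():
            if key.endswith("_vs_abundance"):
                lines.append(f"| {key.removesuffix('_vs_abundance')} vs {source} | {val:.3f} |")
    return "\n".join(lines) + "\n"


def load_approx_abundances() -> list[AbundanceVector]:
    """Figure-derived approximate abundances (synthetic; ranking checks only)."""
    ref = importlib.resources.files("fflscape.data") / "abundance_approx_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    out = []
    for source, grp in df.groupby("source", sort=True):
        out.append(AbundanceVector(grp.set_index("motif")["abundance"], str(source)))
    return out
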