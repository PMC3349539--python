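#!/usr/bin/env python
"""Stage 4 — correlations between scores, evolvability and abundance.

Assembles the full correlation report: evolvability vs plasticity (the
headline anticorrelation), rho vs the approximate figure-derived
abundance fixture (ranking check only), and a synthetic-abundance
recovery demonstration at a known target correlation.

Writes: results/compare_report.json
"""

import json
from pathlib import Path

import pandas as pd

from fflscape import (
    MOTIF_IDS,
    abundance_with_correlation,
    compare_report,
    evolvability,
    load_approx_abundances,
    load_reference_table,
    load_reference_transitions,
)
from fflscape.stats import score_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20120119

def main() -> None:
    OUT.mkdir(exist_ok=True)
    scores = score_table(load_reference_table())
    refs = load_reference_transitions()
    ev = pd.Series({m: evolvability(refs[(m, "single")], refs[(m, "accumulated")])
                    for m in MOTIF_IDS})

    vectors = load_approx_abundances()
    synth, achieved = abundance_with_correlation(
        scores["rho"].to_numpy(), 0.91, noise_seed=SEED, source="synthetic_r0.91"
    )
    vectors.append(synth)

    report = compare_report(scores, ev, vectors)
    (OUT / "compare_report.json").write_text(json.dumps(report, indent=2))

    r = report["correlations"]["psi_vs_E"]
    print(f"evolvability vs plasticity: r = {r:.3f} "
          "(balanced motifs are the evolvable ones)")
    for source, entry in report["abundance"].items():
        print(f"{source}: rho vs abundance r = {entry['rho_vs_abundance']:.3f}, "
              f"top two motifs {entry['top_two_motifs']}")
    print(f"synthetic abundance generated at target r = 0.91, achieved "
          f"{achieved:.3f}")

if __name__ == "__main__":
    main()
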