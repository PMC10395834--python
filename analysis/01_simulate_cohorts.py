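#!/usr/bin/env python
"""Generate the synthetic study data every later step analyzes.

Emulates the real design at desk scale: a panel of six correlated microbial
exposures (one truly causal for the disease outcome), a diet→microbe→disease
mediation triad, and a shared genomic region for colocalization.  Writes the
summary-statistics TSVs plus truth sidecars under results/data/.
"""

import json
from pathlib import Path

import numpy as np

from micromr.gwas_io import write_summary_stats
from micromr.simulate import (
    ColocSimSpec,
    MediationSimSpec,
    MultivariableSimSpec,
    simulate_coloc_region,
    simulate_mediation,
    simulate_multivariable,
)

SEED = 2024
OUT = Path("results/data")


def _jsonable(truth):
    return {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in truth.items()
        if not isinstance(v, dict) or k == "causal_subset"
    }


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    corr = np.full((6, 6), 0.3)
    np.fill_diagonal(corr, 1.0)
    exposures, outcome, truth = simulate_multivariable(
        MultivariableSimSpec(
            n_variants=120, n_exposures=6, causal_subset={0: 0.25},
            exposure_correlation=corr, seed=SEED,
        )
    )
    for ds in exposures:
        write_summary_stats(ds, OUT / f"{ds.trait_id}.tsv")
    write_summary_stats(outcome, OUT / "outcome.tsv")
    (OUT / "panel_truth.json").write_text(
        json.dumps({"causal_subset": {str(k): v for k, v in truth["causal_subset"].items()},
                    "theta": truth["theta"].tolist()}, indent=2)
    )

    diet, microbe, disease, med_truth = simulate_mediation(MediationSimSpec(seed=SEED))
    for ds, name in [(diet, "diet"), (microbe, "microbe"), (disease, "disease")]:
        write_summary_stats(ds, OUT / f"mediation_{name}.tsv")
    (OUT / "mediation_truth.json").write_text(
        json.dumps({k: v for k, v in med_truth.items() if not isinstance(v, list)}, indent=2)
    )

    p1, p2, coloc_truth = simulate_coloc_region(ColocSimSpec(scenario="shared_causal", seed=SEED))
    p1.to_csv(OUT / "coloc_trait1.tsv", sep="\t", index=False)
    p2.to_csv(OUT / "coloc_trait2.tsv", sep="\t", index=False)
    (OUT / "coloc_truth.json").write_text(json.dumps(coloc_truth, indent=2))

    print(f"panel: 6 exposures x 120 variants (causal: exposure_0, effect 0.25)")
    print(f"mediation triad: b2=0.5, b3=0.4, direct=0.2 -> b1={med_truth['b1']:.2f}")
    print(f"coloc region: shared causal variant at index {coloc_truth['causal1']}")
    print(f"wrote inputs under {OUT}/")


if __name__ == "__main__":
    main()
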