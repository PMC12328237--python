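#!/usr/bin/env python
"""Transcriptional phenotyping of nonsense variants under three models.

Simulates allele-resolved reads and matched expression for the simple
decay model (c = t = 1), trans-reduction of the WT allele (t = 0.6) and
compensatory upregulation (c = 1.4), then estimates depletion, tests the
allele ratio, compares heterozygote vs WT expression and calls the
regime.  Writes results/nmd_phenotypes.csv.
"""

from pathlib import Path

import pandas as pd

from atlasstats.nmd import phenotype_variant
from atlasstats import simulate as sim

OUT = Path(__file__).resolve().parent.parent / "results"

DESIGNS = {
    "simple": sim.AlleleDesign(depletion=0.9, seed=41),
    "trans_reduction": sim.AlleleDesign(depletion=0.9, trans_factor=0.6, seed=42),
    "compensatory": sim.AlleleDesign(depletion=0.99, compensation=1.4, seed=43),
}

if __name__ == "__main__":
    rows = []
    for name, design in DESIGNS.items():
        expr, counts = sim.simulate_allele_counts(design)
        pheno = phenotype_variant(name, counts, expr, design.gene_id,
                                  design.genotypes)
        rows.append(
            {
                "variant": name,
                "true_depletion": design.depletion,
                "depletion_hat": round(pheno.depletion, 3),
                "binomial_p": pheno.binomial_p,
                "reduction_obs": round(pheno.reduction_obs, 3),
                "reduction_exp": round(pheno.reduction_exp, 3),
                "t_pvalue": pheno.t_pvalue,
                "regime": pheno.regime.value,
            }
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "nmd_phenotypes.csv", index=False)
    print(table.to_string(index=False))
    print("\nUnder the simple model a depletion d predicts a d/2 total "
          "reduction: 0.90 -> 0.45.")
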