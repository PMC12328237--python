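#!/usr/bin/env python
"""Differential splicing: null calibration and planted-switch power.

Simulates genes with identical junction usage across cell types (the
null) and genes with an extreme 0.9/0.1 isoform switch, runs the
z-score + MANOVA pipeline on each, and reports the type-I error at
alpha = 0.05 and the fraction of switch genes called at corrected
P < 1e-16.  Writes results/splicing_summary.csv.
"""

from pathlib import Path

import pandas as pd

from atlasstats import simulate as sim
from atlasstats.splicing import differential_splicing

OUT = Path(__file__).resolve().parent.parent / "results"


def null_type_one_error(n_genes=150, seed=11) -> float:
    genes = [
        sim.JunctionGeneDesign(f"g{k}", sim.uniform_usage(3, 3), reads_per_cell=20.0)
        for k in range(n_genes)
    ]
    jd = sim.JunctionDesign(genes=genes, cell_types=["a", "b", "c"],
                            cells_per_type=50, seed=seed)
    table = differential_splicing(sim.simulate_junctions(jd))
    tested = table[table["status"] == "ok"]
    return float((tested["p_value"] < 0.05).mean())


def switch_power(n_seeds=40, seed0=100) -> float:
    called = 0
    for seed in range(seed0, seed0 + n_seeds):
        jd = sim.JunctionDesign(
            genes=[sim.JunctionGeneDesign("g", sim.switch_usage(0.9))], seed=seed
        )
        table = differential_splicing(sim.simulate_junctions(jd))
        called += bool(table.loc[0, "called_differential"])
    return called / n_seeds


if __name__ == "__main__":
    t1e = null_type_one_error()
    power = switch_power()
    summary = pd.DataFrame(
        [
            {"quantity": "null_type_I_error_alpha_0.05", "value": t1e},
            {"quantity": "switch_power_corrected_p_1e-16", "value": power},
        ]
    )
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "splicing_summary.csv", index=False)
    print(f"type-I error under the multinomial null: {t1e:.3f} (nominal 0.05)")
    print(f"power on the planted 0.9/0.1 isoform switch: {power:.2f}")
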