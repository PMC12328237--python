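"""Cell-cell chemokine interaction network from binarized expression calls.

Per (cell type, gene), expression is binarized in two stages.  An absolute
filter requires non-zero expression in at least 5% of the cell type's
cells and a mean normalized expression of at least 0.5.  A relative filter
then compares the mean against a per-gene ceiling — the 99th percentile of
the means of all cell types passing the absolute filter (guarding against
single outlier types) — calling receptors above 5% of the ceiling and
ligands above 20% (ligands are diffusible and must be abundant to act).

Directed edges run ligand-expressing type -> receptor-expressing type for
any cognate pair, deduplicated per ordered node pair, with self-loops
allowed and cross-organ edges excluded unless one endpoint is blood
(circulating cells contact every organ).  Network density is
N_edges / N_nodes^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import ExpressionMatrix, normalize_ln_up10k

logger = logging.getLogger(__name__)


def absolute_filter(
    fraction_nonzero: float, mean_expression: float, cfg: Optional[AnalysisConfig] = None
) -> bool:
    """True iff the cell type passes the inclusive absolute thresholds."""
    cfg = cfg or AnalysisConfig()
    return (
        fraction_nonzero >= cfg.chemokine_min_fraction
        and mean_expression >= cfg.chemokine_min_mean
    )


def compute_ceiling(passing_means, percentile: float = 99.0) -> float:
    """Percentile (linear interpolation) of the passing cell-type means."""
    means = np.asarray(passing_means, dtype=float)
    if len(means) == 0:
        raise ValueError("ceiling undefined without passing cell types")
    return float(np.percentile(means, percentile))


def expression_calls(
    expr: ExpressionMatrix, genes, cfg: Optional[AnalysisConfig] = None
) -> pd.DataFrame:
    """Per (cell type, gene) expression summary and binarized calls.

    Columns: cell_type, gene, fraction, mean, ceiling, call_receptor,
    call_ligand.  Calls are False whenever the absolute filter fails;
    ceilings are computed per gene over passing cell types only.  Genes
    absent from the matrix are logged and skipped.
    """
    cfg = cfg or AnalysisConfig()
    if expr.normalized is None:
        expr = normalize_ln_up10k(expr)
    keep = np.ones(expr.n_cells, dtype=bool)
    if not cfg.include_plate_cells:
        keep &= (expr.cells["method"] == "droplet").to_numpy()
    cells = expr.cells.loc[keep]
    normalized = expr.normalized[keep]
    raw = expr.counts[keep]
    rows = []
    cell_types = sorted(cells["cell_type"].unique())
    masks = {ct: (cells["cell_type"] == ct).to_numpy() for ct in cell_types}
    for gene in genes:
        try:
            gi = expr.gene_index(gene)
        except KeyError:
            logger.warning("gene %s absent from the matrix; skipped", gene)
            continue
        col_raw = np.asarray(raw[:, gi].todense()).ravel()
        col_norm = normalized[:, gi]
        stats = []
        for ct in cell_types:
            m = masks[ct]
            frac = float((col_raw[m] > 0).mean())
            mean = float(col_norm[m].mean())
            stats.append((ct, frac, mean, absolute_filter(frac, mean, cfg)))
        passing = [mean for _, _, mean, ok in stats if ok]
        ceiling = (
            compute_ceiling(passing, cfg.chemokine_ceiling_percentile)
            if passing
            else float("nan")
        )
        for ct, frac, mean, ok in stats:
            # strict ">" at the relative thresholds, inclusive at the absolute
            rows.append(
                {
                    "cell_type": ct,
                    "gene": gene,
                    "fraction": frac,
                    "mean": mean,
                    "ceiling": ceiling,
                    "call_receptor": ok and mean > cfg.chemokine_receptor_rel * ceiling,
                    "call_ligand": ok and mean > cfg.chemokine_ligand_rel * ceiling,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cell_type", "gene", "fraction", "mean", "ceiling",
                 "call_receptor", "call_ligand"],
    )


@dataclass
class ChemokineNetwork:
    nodes: list[str]  # cell types
    organs: dict[str, str]
    edges: pd.DataFrame  # src, dst, via_pairs
    density: float


def build_network(
    calls: pd.DataFrame, pairs: pd.DataFrame, organs: dict[str, str]
) -> ChemokineNetwork:
    """Draw deduplicated directed ligand->receptor edges between cell types."""
    nodes = sorted(calls["cell_type"].unique())
    ligand_of = {
        g: set(sub.loc[sub["call_ligand"], "cell_type"])
        for g, sub in calls.groupby("gene")
    }
    receptor_of = {
        g: set(sub.loc[sub["call_receptor"], "cell_type"])
        for g, sub in calls.groupby("gene")
    }
    edge_pairs: dict[tuple[str, str], list[str]] = {}
    for row in pairs.itertuples(index=False):
        if row.ligand not in ligand_of or row.receptor not in receptor_of:
            logger.warning(
                "pair %s->%s references a gene without calls; skipped",
                row.ligand, row.receptor,
            )
            continue
        for u in ligand_of[row.ligand]:
            for v in receptor_of[row.receptor]:
                ou, ov = organs[u], organs[v]
                if ou != ov and "blood" not in (ou, ov):
                    continue
                edge_pairs.setdefault((u, v), []).append(f"{row.ligand}:{row.receptor}")
    edges = pd.DataFrame(
        [
            {"src": u, "dst": v, "via_pairs": ";".join(sorted(set(via)))}
            for (u, v), via in sorted(edge_pairs.items())
        ],
        columns=["src", "dst", "via_pairs"],
    )
    density = len(edges) / len(nodes) ** 2 if nodes else float("nan")
    return ChemokineNetwork(nodes=nodes, organs=dict(organs), edges=edges, density=density)


def density_by_partition(
    network: ChemokineNetwork, immune: dict[str, bool]
) -> dict[str, Optional[float]]:
    """Densities of the full, immune, non-immune and cross subnetworks.

    The immune (resp. non-immune) subnetwork keeps edges among its own
    nodes with its own squared node count as denominator; the cross
    network counts edges between the partitions in either direction over
    2 * N_immune * N_nonimmune.  Empty partitions yield None.
    """
    nodes = network.nodes
    imm = [n for n in nodes if immune[n]]
    non = [n for n in nodes if not immune[n]]
    edges = network.edges

    def sub_density(members: list[str]) -> Optional[float]:
        if not members:
            return None
        ms = set(members)
        n_edges = int((edges["src"].isin(ms) & edges["dst"].isin(ms)).sum())
        return n_edges / len(members) ** 2

    cross: Optional[float]
    if not imm or not non:
        cross = None
    else:
        si, sn = set(imm), set(non)
        n_cross = int(
            ((edges["src"].isin(si) & edges["dst"].isin(sn))
             | (edges["src"].isin(sn) & edges["dst"].isin(si))).sum()
        )
        cross = n_cross / (2 * len(imm) * len(non))
    return {
        "all": network.density,
        "immune": sub_density(imm),
        "non_immune": sub_density(non),
        "cross": cross,
    }
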