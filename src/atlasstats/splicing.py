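"""Cell-type differential splicing from junction counts.

Per gene, every retained cell's junction-usage fractions are variance-
stabilized into scaled z-scores,

    f_m(i) = n_m(i) / sum_j n_m(j)
    f(i)   = sum_c n_c(i) / sum_c sum_j n_c(j)
    z_m(i) = sqrt(sum_j n_m(j)) * (f_m(i) - f(i)) / sqrt(f(i) (1 - f(i)))

and a MANOVA of the z-score matrix against cell type tests whether all
cell types share the same multivariate mean junctional usage.  P values
are Benjamini-Hochberg corrected across genes; genes below a stringent
corrected threshold (default 1e-16) are called differentially spliced.

Junctions are also classified against a gene annotation into five novelty
categories: A (annotated donor-acceptor pair), B (both sites annotated,
pair novel — e.g. unannotated exon skipping), C (exactly one site
annotated), D (both sites novel but inside one annotated gene), E
(overlapping no annotated gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sp_stats
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .io import GeneAnnotationModel, JunctionCounts, JunctionRecord

logger = logging.getLogger(__name__)


class JunctionCategory(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"


def classify_junction(j: JunctionRecord, ann: GeneAnnotationModel) -> JunctionCategory:
    """Assign the junction its novelty category relative to the annotation."""
    pairs = ann.junction_pairs.get(j.chrom, set())
    donors = ann.donor_sites.get(j.chrom, set())
    acceptors = ann.acceptor_sites.get(j.chrom, set())
    donor_known = j.donor_pos in donors
    acceptor_known = j.acceptor_pos in acceptors
    if (j.donor_pos, j.acceptor_pos) in pairs:
        return JunctionCategory.A
    if donor_known and acceptor_known:
        return JunctionCategory.B
    if donor_known or acceptor_known:
        return JunctionCategory.C
    # D requires both sites inside the span of one annotated gene
    lo = min(j.donor_pos, j.acceptor_pos)
    hi = max(j.donor_pos, j.acceptor_pos)
    g = ann.genes
    if len(g):
        inside = (g["chrom"] == j.chrom) & (g["start"] <= lo) & (hi < g["end"])
        if bool(inside.any()):
            return JunctionCategory.D
    return JunctionCategory.E


def classify_all(junctions: Sequence[JunctionRecord], ann: GeneAnnotationModel) -> pd.DataFrame:
    rows = [
        {"junction_id": j.junction_id, "category": classify_junction(j, ann).value}
        for j in junctions
    ]
    return pd.DataFrame(rows, columns=["junction_id", "category"])


def percent_fewer(count: int, reference: int) -> float:
    """Percentage by which ``count`` falls below ``reference``."""
    return 100.0 * (reference - count) / reference


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_for_testing(jc: JunctionCounts, cfg: Optional[AnalysisConfig] = None) -> JunctionCounts:
    """Apply the per-tissue testability filters.

    In order: cell types with fewer than ``splicing_min_cells_per_type``
    cells are dropped; junctions nonzero in fewer than
    ``splicing_min_cells_per_junction`` cells are dropped; genes are kept
    only if every remaining cell type has at least
    ``splicing_min_gene_reads_per_type`` junctional reads over the gene;
    finally junctions whose dataset fraction within their gene is 0 or 1
    are dropped (constant usage carries no contrast).  An untestable input
    yields an empty result, not an exception.
    """
    cfg = cfg or AnalysisConfig()
    counts = sp.csc_matrix(jc.counts)
    cells = jc.cells
    keep_cells = np.ones(len(cells), dtype=bool)
    if not cfg.include_plate_cells:
        keep_cells &= (cells["method"] == "droplet").to_numpy()
    sizes = cells.loc[keep_cells, "cell_type"].value_counts()
    small = set(sizes[sizes < cfg.splicing_min_cells_per_type].index)
    if small:
        keep_cells &= ~cells["cell_type"].isin(small).to_numpy()
    counts = counts[keep_cells]
    cells = cells.loc[keep_cells].reset_index(drop=True)

    nonzero_cells = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_junc = nonzero_cells >= cfg.splicing_min_cells_per_junction

    gene_of = np.array([j.gene_id or "" for j in jc.junctions])
    cell_types = sorted(cells["cell_type"].unique())
    type_masks = {ct: (cells["cell_type"] == ct).to_numpy() for ct in cell_types}
    for gene in pd.unique(gene_of):
        cols = np.flatnonzero((gene_of == gene) & keep_junc)
        if not len(cols):
            continue
        gene_counts = np.asarray(counts[:, cols].todense())
        drop_gene = False
        for ct in cell_types:
            if gene_counts[type_masks[ct]].sum() < cfg.splicing_min_gene_reads_per_type:
                drop_gene = True
                break
        if drop_gene:
            keep_junc[cols] = False
            continue
        totals = gene_counts.sum(axis=0)
        gene_total = totals.sum()
        constant = (totals == 0) | (totals == gene_total)
        keep_junc[cols[constant]] = False

    cols = np.flatnonzero(keep_junc)
    return JunctionCounts(
        counts=sp.csr_matrix(counts[:, cols]),
        junctions=[jc.junctions[i] for i in cols],
        cells=cells,
    )


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------


@dataclass
class JunctionZScores:
    """Per-gene z-score matrix over retained cells and junctions."""

    gene_id: str
    z: np.ndarray  # retained cells x retained junctions
    f_dataset: np.ndarray  # dataset fraction per junction, f(i)
    f_cell: np.ndarray  # per-cell fractions, f_m(i)
    cell_index: np.ndarray  # row indices into the filtered JunctionCounts
    junction_ids: list[str]


def junction_zscores(jc: JunctionCounts, gene_id: str) -> Optional[JunctionZScores]:
    """Compute the scaled junction z-scores for one gene.

    Cells with zero junctional reads for the gene are excluded.  Returns
    None when the gene has no junctions in ``jc``.  A dataset fraction of
    exactly 0 or 1 at this stage means the filter contract was violated.
    """
    cols = [i for i, j in enumerate(jc.junctions) if j.gene_id == gene_id]
    if not cols:
        return None
    n = np.asarray(jc.counts[:, cols].todense(), dtype=float)
    totals = n.sum(axis=1)
    rows = np.flatnonzero(totals > 0)
    n = n[rows]
    totals = totals[rows]
    f_dataset = n.sum(axis=0) / n.sum()
    if np.any((f_dataset == 0) | (f_dataset == 1)):
        raise RuntimeError(
            f"gene {gene_id}: constant junction reached the z-score stage; "
            "run filter_for_testing first"
        )
    f_cell = n / totals[:, None]
    z = np.sqrt(totals)[:, None] * (f_cell - f_dataset) / np.sqrt(
        f_dataset * (1.0 - f_dataset)
    )
    return JunctionZScores(
        gene_id=gene_id,
        z=z,
        f_dataset=f_dataset,
        f_cell=f_cell,
        cell_index=rows,
        junction_ids=[jc.junctions[i].junction_id for i in cols],
    )


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------

_STAT_ROW = {"pillai": "Pillai's trace", "wilks": "Wilks' lambda"}


@dataclass
class GeneSplicingResult:
    gene_id: str
    p_value: float  # NaN when untestable/skipped
    p_adjusted: float = float("nan")
    n_cells: int = 0
    n_junctions: int = 0
    status: str = "ok"  # ok | untestable | singular
    called_differential: bool = False


def manova_per_gene(
    zs: JunctionZScores,
    cell_types: Sequence[str],
    statistic: str = "pillai",
) -> GeneSplicingResult:
    """One MANOVA p-value for the gene: cell types share the same mean z.

    Junction fractions sum to one per cell, so the z columns are linearly
    dependent; the last junction column is dropped before the fit.  Cell
    types must number at least two with at least two retained cells each.
    """
    labels = np.asarray(cell_types)[zs.cell_index]
    counts = pd.Series(labels).value_counts()
    result = GeneSplicingResult(
        gene_id=zs.gene_id,
        p_value=float("nan"),
        n_cells=len(labels),
        n_junctions=zs.z.shape[1],
    )
    if len(counts) < 2 or counts.min() < 2 or zs.z.shape[1] < 2:
        result.status = "untestable"
        return result
    y = zs.z[:, :-1]  # drop one column: exact collinearity otherwise
    try:
        if y.shape[1] == 1:
            # with one free junction both Pillai and Wilks reduce to the
            # ordinary one-way ANOVA F test
            groups = [y[labels == ct, 0] for ct in counts.index]
            result.p_value = float(sp_stats.f_oneway(*groups).pvalue)
        else:
            data = pd.DataFrame(y, columns=[f"z{i}" for i in range(y.shape[1])])
            data["cell_type"] = labels
            lhs = " + ".join(data.columns[:-1])
            fit = MANOVA.from_formula(f"{lhs} ~ C(cell_type)", data=data)
            stats = fit.mv_test().results["C(cell_type)"]["stat"]
            result.p_value = float(stats.loc[_STAT_ROW[statistic], "Pr > F"])
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.info("gene %s skipped: singular fit (%s)", zs.gene_id, exc)
        result.status = "singular"
    if result.status == "ok" and not np.isfinite(result.p_value):
        result.status = "singular"
    return result


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    results: list[GeneSplicingResult], threshold: float = 1e-16
) -> list[GeneSplicingResult]:
    """BH-adjust across genes and flag those below the corrected threshold."""
    tested = [r for r in results if r.status == "ok" and np.isfinite(r.p_value)]
    if tested:
        adjusted = bh_adjust([r.p_value for r in tested])
        for r, padj in zip(tested, adjusted):
            r.p_adjusted = float(padj)
            r.called_differential = bool(padj < threshold)
    return results


def differential_splicing(
    jc: JunctionCounts, cfg: Optional[AnalysisConfig] = None
) -> pd.DataFrame:
    """Full per-tissue pipeline: filter, z-scores, MANOVA, BH, calls."""
    cfg = cfg or AnalysisConfig()
    filtered = filter_for_testing(jc, cfg)
    genes = pd.unique(
        np.array([j.gene_id for j in filtered.junctions if j.gene_id is not None])
    )
    cell_types = filtered.cells["cell_type"].to_numpy()
    results = []
    for gene in genes:
        zs = junction_zscores(filtered, gene)
        if zs is None:
            continue
        results.append(manova_per_gene(zs, cell_types, cfg.splicing_statistic))
    results = call_differential(results, cfg.splicing_alpha)
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "n_cells": r.n_cells,
                "n_junctions": r.n_junctions,
                "status": r.status,
                "called_differential": r.called_differential,
            }
            for r in results
        ],
        columns=[
            "gene_id", "p_value", "p_adjusted", "n_cells", "n_junctions",
            "status", "called_differential",
        ],
    )
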