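"""Cell-type enrichment calling and the modified silhouette coefficient.

A feature (gene or unannotated transcriptionally active region, uTAR) is
called differentially expressed in a cell type of one (tissue, individual)
dataset when all three criteria hold: Bonferroni-corrected two-tailed
Wilcoxon rank-sum P < 0.05 against all other cells of the tissue;
expressed (non-zero) in at least 25% of the cell type's cells; and
cell-type mean expression at least e^0.5 (~1.65) times the mean of the
other cell types of the tissue.

The silhouette here follows the atlas definition: s(i) = (b(i) - a(i)) /
max{b(i), a(i)} with a(i) the mean in-group distance and b(i) the minimal
distance of cell i to ANY cell of a different type — not the textbook
minimum of per-cluster mean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import ExpressionMatrix, normalize_ln_up10k

logger = logging.getLogger(__name__)

#: largest group size for which the exact tie-free Wilcoxon null is used
_EXACT_MAX = 8


def wilcoxon_rank_sum(x, y) -> float:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for tie-free groups of at most 8; normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= _EXACT_MAX and len(y) <= _EXACT_MAX and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


@dataclass
class DECall:
    feature_id: str
    cell_type: str
    p_adjusted: float
    fraction: float
    ratio: float
    is_de: bool


def de_call(
    expr: ExpressionMatrix,
    features: Optional[Sequence[str]] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Three-criteria enrichment calls for one (tissue, individual) dataset.

    The Bonferroni family is all (feature x cell type) tests performed in
    the dataset.  Cell types with fewer than two cells are skipped.  The
    fold-ratio criterion uses mean normalized ln(UP10K+1) by default
    (``de_ratio_scale``; linear UP10K means optional).
    """
    cfg = cfg or AnalysisConfig()
    if expr.normalized is None:
        expr = normalize_ln_up10k(expr)
    if expr.cells["tissue"].nunique() != 1 or expr.cells["individual"].nunique() != 1:
        raise ValueError("de_call expects a single (tissue, individual) dataset")
    features = list(features) if features is not None else list(expr.genes)
    values = (
        expr.normalized
        if cfg.de_ratio_scale == "log"
        else np.expm1(expr.normalized)
    )
    raw = expr.counts
    cell_types = sorted(expr.cells["cell_type"].unique())
    masks = {}
    for ct in cell_types:
        m = (expr.cells["cell_type"] == ct).to_numpy()
        if m.sum() < 2:
            logger.info("cell type %s has <2 cells; skipped", ct)
            continue
        masks[ct] = m
    records = []
    for feature in features:
        fi = expr.gene_index(feature)
        col = values[:, fi]
        col_raw = np.asarray(raw[:, fi].todense()).ravel()
        for ct, m in masks.items():
            p = wilcoxon_rank_sum(col[m], col[~m])
            fraction = float((col_raw[m] > 0).mean())
            rest_mean = float(col[~m].mean())
            ct_mean = float(col[m].mean())
            if rest_mean > 0:
                ratio = ct_mean / rest_mean
            else:
                ratio = float("inf") if ct_mean > 0 else float("nan")
            records.append([feature, ct, p, fraction, ratio])
    n_tests = len(records)
    rows = []
    for feature, ct, p, fraction, ratio in records:
        p_adj = min(1.0, p * n_tests)  # Bonferroni over the dataset's tests
        is_de = (
            p_adj < cfg.de_alpha
            and fraction >= cfg.de_min_fraction
            and (np.isfinite(ratio) or ratio == float("inf"))
            and ratio >= cfg.de_min_ratio
        )
        rows.append(
            {
                "feature_id": feature,
                "cell_type": ct,
                "p_adjusted": p_adj,
                "fraction": fraction,
                "ratio": ratio,
                "is_de": bool(is_de),
            }
        )
    return pd.DataFrame(
        rows, columns=["feature_id", "cell_type", "p_adjusted", "fraction", "ratio", "is_de"]
    )


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------


@dataclass
class SilhouetteReport:
    per_cell: np.ndarray  # s(i) in [-1, 1]
    average: float


def silhouette(distances: np.ndarray, labels: Sequence[str]) -> SilhouetteReport:
    """Modified silhouette over one dataset's pairwise distance matrix.

    b(i) is the minimal single-cell out-group distance.  Cells in
    singleton cell types get s(i) = 0 by convention (logged).
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError(f"distance matrix {d.shape} does not match {n} labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two cell types")
    s = np.zeros(n)
    n_singleton = 0
    for i in range(n):
        same = labels == labels[i]
        other = ~same
        same[i] = False
        if not same.any():
            n_singleton += 1
            continue
        a = d[i, same].mean()
        b = d[i, other].min()
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    if n_singleton:
        logger.info("%d singleton cell(s) assigned s(i)=0", n_singleton)
    return SilhouetteReport(per_cell=s, average=float(s.mean()))


def silhouette_from_embedding(coords: np.ndarray, labels: Sequence[str]) -> SilhouetteReport:
    """Silhouette from embedding coordinates via Euclidean distances."""
    from scipy.spatial.distance import squareform, pdist

    return silhouette(squareform(pdist(np.asarray(coords, dtype=float))), labels)
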