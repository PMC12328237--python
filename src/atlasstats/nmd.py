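"""Transcriptional phenotyping of nonsense variants.

In a heterozygote, transcripts carrying a premature stop are degraded by
nonsense-mediated decay (NMD) while the wild-type allele is not, so the
mutant:WT read ratio at the variant position estimates the depletion
d = 1 - mut/wt, and under the simple two-allele model a depletion d
predicts a total-expression reduction of d/2 in heterozygotes versus WT
individuals (90% depletion -> 45% fewer transcripts).  Departures from
d/2 indicate trans-reduction of the WT transcript (or attenuated positive
feedback) when larger, or compensatory transcriptional upregulation when
smaller; low depletion with a last-exon stop indicates NMD escape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import ExpressionMatrix, normalize_ln_up10k

logger = logging.getLogger(__name__)


class Regime(str, Enum):
    SIMPLE_NMD = "simple_NMD"
    TRANS_REDUCTION = "trans_reduction_or_feedback"
    COMPENSATORY = "compensatory_upregulation"
    ESCAPES_NMD = "escapes_NMD"


@dataclass
class DepletionEstimate:
    depletion: float  # d-hat, clamped to [0, 1]
    mut_reads: int
    wt_reads: int
    per_tissue: pd.DataFrame  # tissue, wt_reads, mut_reads, depletion


def estimate_depletion(allele_counts: pd.DataFrame) -> Optional[DepletionEstimate]:
    """d-hat = 1 - (sum mut)/(sum wt) over tissues of one heterozygote.

    ``allele_counts`` needs columns tissue, wt_reads, mut_reads; tissues
    with zero coverage are omitted upstream, not counted as 0/0.  Returns
    None (undefined) when no WT reads were observed.
    """
    wt = int(allele_counts["wt_reads"].sum())
    mut = int(allele_counts["mut_reads"].sum())
    if wt == 0:
        return None
    per_tissue = allele_counts[["tissue", "wt_reads", "mut_reads"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = per_tissue["mut_reads"] / per_tissue["wt_reads"]
    per_tissue["depletion"] = (1.0 - ratio).clip(0.0, 1.0)
    return DepletionEstimate(
        depletion=float(np.clip(1.0 - mut / wt, 0.0, 1.0)),
        mut_reads=mut,
        wt_reads=wt,
        per_tissue=per_tissue,
    )


def binomial_nmd_test(mut_reads: int, wt_reads: int) -> float:
    """Exact one-tailed binomial test, P(X <= mut | n, 1/2), reads pooled
    over tissues."""
    n = mut_reads + wt_reads
    if n < 1:
        raise ValueError("binomial test needs at least one read")
    return float(stats.binom.cdf(mut_reads, n, 0.5))


def expected_het_reduction(depletion: float) -> float:
    """Expected heterozygote total-expression reduction under simple NMD.

    One intact allele plus one allele depleted by d gives
    r_exp = 1 - (1 + (1-d))/2 = d/2.
    """
    if not 0.0 <= depletion <= 1.0:
        raise ValueError(f"depletion must be in [0, 1], got {depletion}")
    return depletion / 2.0


@dataclass
class ExpressionComparison:
    reduction: float  # r_obs = 1 - mean(het values)/mean(WT values)
    t_pvalue: float
    wt_values: np.ndarray  # per (cell type, individual), normalized to WT mean
    het_values: np.ndarray
    n_cell_types: int


def expression_comparison(
    expr: ExpressionMatrix,
    gene: str,
    genotypes: dict[str, str],
    cfg: Optional[AnalysisConfig] = None,
) -> Optional[ExpressionComparison]:
    """Compare the gene's expression in heterozygous vs WT individuals.

    Cells are grouped by cell type (pooled across tissues); per (cell
    type, individual) means use only that individual's cells, excluding
    cell types with fewer than 35 profiled droplet cells per individual
    and cell types whose WT mean ln(UP10K+1) falls below 0.3.  All values
    are normalized to the mean over all WT cells and compared with a
    Welch two-tailed t-test.  The reduction ratio is computed on
    linear-scale mean UP10K by default (``nmd_ratio_scale``), matching
    relative transcript counts.  Returns None when nothing qualifies.
    """
    cfg = cfg or AnalysisConfig()
    if expr.normalized is None:
        expr = normalize_ln_up10k(expr)
    keep = np.ones(expr.n_cells, dtype=bool)
    if not cfg.include_plate_cells:
        keep &= (expr.cells["method"] == "droplet").to_numpy()
    keep &= expr.cells["individual"].isin(genotypes).to_numpy()
    cells = expr.cells.loc[keep].reset_index(drop=True)
    gi = expr.gene_index(gene)
    log_col = expr.normalized[keep, gi]
    linear_col = np.expm1(log_col)  # UP10K scale
    values = log_col if cfg.nmd_ratio_scale == "log" else linear_col

    wt_inds = [i for i, g in genotypes.items() if g == "WT"]
    het_inds = [i for i, g in genotypes.items() if g == "het"]
    if not wt_inds or not het_inds:
        raise ValueError("need at least one WT and one heterozygous individual")

    wt_cell_mask = cells["individual"].isin(wt_inds).to_numpy()
    group_mean = values[wt_cell_mask].mean() if wt_cell_mask.any() else np.nan
    if not np.isfinite(group_mean) or group_mean == 0:
        return None

    wt_vals, het_vals = [], []
    n_types = 0
    for ct, sub in cells.groupby("cell_type"):
        by_ind = sub.groupby("individual").indices
        # every profiled individual needs enough cells of this type
        sizes = {ind: len(by_ind.get(ind, ())) for ind in genotypes}
        if any(n < cfg.nmd_min_cells_per_type for n in sizes.values()):
            continue
        wt_log_means = [
            log_col[sub.index[by_ind[ind]]].mean() for ind in wt_inds
        ]
        if np.mean(wt_log_means) < cfg.nmd_min_wt_mean:
            continue
        n_types += 1
        for ind in genotypes:
            v = values[sub.index[by_ind[ind]]].mean() / group_mean
            (wt_vals if genotypes[ind] == "WT" else het_vals).append(v)
    if not wt_vals or not het_vals:
        return None
    wt_arr, het_arr = np.array(wt_vals), np.array(het_vals)
    r_obs = 1.0 - het_arr.mean() / wt_arr.mean()
    t_p = float(stats.ttest_ind(wt_arr, het_arr, equal_var=False).pvalue)
    return ExpressionComparison(
        reduction=float(r_obs),
        t_pvalue=t_p,
        wt_values=wt_arr,
        het_values=het_arr,
        n_cell_types=n_types,
    )


def classify_regime(
    depletion: float,
    reduction_obs: float,
    in_last_exon: bool = False,
    tol: float = 0.10,
    escape_max_depletion: float = 0.5,
) -> Regime:
    """Classify the variant's transcriptional regime.

    Last-exon stops with weak depletion escape NMD; otherwise the observed
    heterozygote reduction is compared with the simple-model expectation
    d/2 within an absolute tolerance band.
    """
    expected = expected_het_reduction(depletion)
    if in_last_exon and depletion < escape_max_depletion:
        return Regime.ESCAPES_NMD
    if reduction_obs > expected + tol:
        return Regime.TRANS_REDUCTION
    if reduction_obs < expected - tol:
        return Regime.COMPENSATORY
    return Regime.SIMPLE_NMD


@dataclass
class NMDPhenotype:
    variant_id: str
    depletion: float
    binomial_p: float
    reduction_obs: float
    reduction_exp: float
    t_pvalue: float
    regime: Regime


def phenotype_variant(
    variant_id: str,
    allele_counts: pd.DataFrame,
    expr: ExpressionMatrix,
    gene: str,
    genotypes: dict[str, str],
    in_last_exon: bool = False,
    cfg: Optional[AnalysisConfig] = None,
) -> Optional[NMDPhenotype]:
    """Full phenotype: depletion, binomial test, expression comparison,
    regime call.  Returns None when depletion or the comparison is
    undefined."""
    cfg = cfg or AnalysisConfig()
    het_counts = allele_counts[
        allele_counts["individual"].map(genotypes) == "het"
    ]
    est = estimate_depletion(het_counts)
    if est is None:
        return None
    comp = expression_comparison(expr, gene, genotypes, cfg)
    if comp is None:
        return None
    regime = classify_regime(
        est.depletion,
        comp.reduction,
        in_last_exon=in_last_exon,
        tol=cfg.nmd_regime_tol,
        escape_max_depletion=cfg.nmd_last_exon_escape_max_depletion,
    )
    return NMDPhenotype(
        variant_id=variant_id,
        depletion=est.depletion,
        binomial_p=binomial_nmd_test(est.mut_reads, est.wt_reads),
        reduction_obs=comp.reduction,
        reduction_exp=expected_het_reduction(est.depletion),
        t_pvalue=comp.t_pvalue,
        regime=regime,
    )
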