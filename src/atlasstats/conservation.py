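"""Primate-selective gene identification and cross-species expression
conservation.

A human gene is primate-selective (PS) when at least one lemur orthologue
is assigned by NCBI or Ensembl while NCBI, Ensembl and MGI all assign no
mouse orthologue.  Expression-pattern conservation between two species is
the Pearson correlation of a gene pair's mean cell-type expression
profiles over curated matched cell types, after normalizing each species'
profile by its E_max (the mean expression in the maximally expressing
cell type); genes first pass an E_max magnitude filter.  Human-lemur-mouse
sequence-homologue triads whose three pairwise correlations all exceed
0.3 are expression homologues, classified by orthology assignment and
lemur naming status.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

#: orthology-table columns; orthologue lists are semicolon-joined ids
ORTHOLOGY_COLUMNS = [
    "human_gene",
    "lemur_ncbi", "lemur_ensembl",
    "mouse_ncbi", "mouse_ensembl", "mouse_mgi",
    "lemur_named", "disease_phenotype",
]


def read_orthology(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ORTHOLOGY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: orthology table missing columns {missing}")
    return table


def _ids(cell: str) -> set[str]:
    return {x for x in str(cell).split(";") if x}


def identify_ps_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Human genes with a lemur orthologue (NCBI or Ensembl) and no mouse
    orthologue in any of NCBI, Ensembl and MGI.

    Returns the PS rows with the distinct lemur NCBI/Ensembl id counts
    attached.
    """
    has_lemur = table.apply(
        lambda r: bool(_ids(r["lemur_ncbi"]) | _ids(r["lemur_ensembl"])), axis=1
    )
    has_mouse = table.apply(
        lambda r: bool(
            _ids(r["mouse_ncbi"]) | _ids(r["mouse_ensembl"]) | _ids(r["mouse_mgi"])
        ),
        axis=1,
    )
    ps = table.loc[has_lemur & ~has_mouse].copy()
    ps.attrs["n_lemur_ncbi_ids"] = len(
        set().union(*[_ids(v) for v in ps["lemur_ncbi"]]) if len(ps) else set()
    )
    ps.attrs["n_lemur_ensembl_ids"] = len(
        set().union(*[_ids(v) for v in ps["lemur_ensembl"]]) if len(ps) else set()
    )
    return ps


def emax(profile) -> float:
    """Mean expression in the maximally expressing cell type."""
    return float(np.asarray(profile, dtype=float).max())


def emax_filter(
    emax_a: float, emax_b: float, cfg: Optional[AnalysisConfig] = None
) -> bool:
    """Expression-magnitude filter for conservation scoring.

    Pass when E_max > 0.5 in each species, or E_max > 0.1 in each species
    with E_max > 1.5 in at least one.
    """
    cfg = cfg or AnalysisConfig()
    both_high = emax_a > cfg.conservation_emax_each and emax_b > cfg.conservation_emax_each
    floor_plus_peak = (
        emax_a > cfg.conservation_emax_floor
        and emax_b > cfg.conservation_emax_floor
        and max(emax_a, emax_b) > cfg.conservation_emax_high
    )
    return both_high or floor_plus_peak


@dataclass
class ConservationScore:
    gene_a: str
    gene_b: str
    emax_a: float
    emax_b: float
    passes_filter: bool
    r: float  # NaN when filtered out or degenerate


def conservation_correlation(
    profile_a,
    profile_b,
    cfg: Optional[AnalysisConfig] = None,
    gene_a: str = "",
    gene_b: str = "",
) -> ConservationScore:
    """Pearson correlation of E_max-normalized profiles over matched cell
    types.

    Profiles must already be aligned to the same matched cell types (at
    least three).  Zero-variance profiles give an undefined (NaN) r.
    """
    cfg = cfg or AnalysisConfig()
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length vectors")
    if len(a) < 3:
        raise ValueError("need at least three matched cell types")
    ea, eb = emax(a), emax(b)
    passes = emax_filter(ea, eb, cfg)
    r = float("nan")
    if passes:
        an = a / ea if ea != 0 else a
        bn = b / eb if eb != 0 else b
        if np.ptp(an) > 0 and np.ptp(bn) > 0:
            r = float(stats.pearsonr(an, bn).statistic)
    return ConservationScore(
        gene_a=gene_a, gene_b=gene_b, emax_a=ea, emax_b=eb, passes_filter=passes, r=r
    )


class TriadClass(str, Enum):
    NAMED_ORTHOLOGUE = "named_orthologue"
    UNNAMED_ORTHOLOGUE = "unnamed_orthologue"
    NON_ORTHOLOGUE = "non_orthologue"


class NotATriad(Exception):
    """All three pairwise correlations must exceed the threshold."""


def classify_triad(
    pair_orthologous: tuple[bool, bool, bool],
    lemur_named: bool,
    pair_correlations: tuple[float, float, float],
    threshold: float = 0.3,
) -> TriadClass:
    """Classify a human-lemur-mouse expression-homologue triad.

    Named orthologue: all three pairs assigned orthologous and the lemur
    gene carries a symbol; unnamed orthologue: all assigned but the lemur
    gene has only a locus identifier; non-orthologue: at least one pair
    unassigned, regardless of naming.  Correlations at or below the
    threshold mean the triad does not exist (strict ``>``).
    """
    if any(not (c > threshold) for c in pair_correlations):
        raise NotATriad(
            f"correlations {pair_correlations} not all above {threshold}"
        )
    if all(pair_orthologous):
        return TriadClass.NAMED_ORTHOLOGUE if lemur_named else TriadClass.UNNAMED_ORTHOLOGUE
    return TriadClass.NON_ORTHOLOGUE


def conservation_table(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    matched_cell_types: Optional[Sequence[str]] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Score every shared gene of two gene x cell-type profile tables."""
    cfg = cfg or AnalysisConfig()
    if matched_cell_types is None:
        matched_cell_types = [c for c in profiles_a.columns if c in profiles_b.columns]
    rows = []
    for gene in profiles_a.index:
        if gene not in profiles_b.index:
            continue
        score = conservation_correlation(
            profiles_a.loc[gene, matched_cell_types],
            profiles_b.loc[gene, matched_cell_types],
            cfg,
            gene_a=gene,
            gene_b=gene,
        )
        rows.append(
            {
                "gene": gene,
                "emax_a": score.emax_a,
                "emax_b": score.emax_b,
                "passes_filter": score.passes_filter,
                "r": score.r,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "emax_a", "emax_b", "passes_filter", "r"])
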