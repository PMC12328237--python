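"""Synthetic single-cell inputs with known ground truth.

Every downstream stage is exercised on data from this module, so each
generator emulates the statistical structure its stage assumes:

* expression   — negative-binomial UMI counts with cell-type marker shifts
                 (the standard scRNA-seq noise model);
* junctions    — per-cell junctional read totals with multinomial splits
                 over per-cell-type isoform-usage vectors (the matched null
                 of the binomial-variance-stabilized junction z-score);
* alleles      — binomially split reference/mutant reads at a nonsense
                 variant, with depletion d on the mutant allele, a
                 compensation factor c >= 1 and a trans factor t <= 1 on
                 the wild-type allele in heterozygotes;
* ligand/receptor — planted directed cell-type communication edges;
* cross-species   — paired cell-type expression profiles sharing a latent
                 profile so that the expected Pearson correlation equals a
                 target.

One global seed is stream-split per stage (numpy ``SeedSequence`` spawn
keys), so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CELL_COLUMNS, ExpressionMatrix, JunctionCounts, JunctionRecord

_STAGE_KEYS = {
    "expression": 1,
    "junctions": 2,
    "alleles": 3,
    "ligand_receptor": 4,
    "cross_species": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one simulation stage under a global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],)))


def _cell_frame(cell_types: Sequence[str], cells_per_type, *, tissue="tissue0",
                individual="L1", compartments=None, prefix="c") -> pd.DataFrame:
    rows = []
    k = 0
    for idx, ct in enumerate(cell_types):
        n = cells_per_type[idx] if not np.isscalar(cells_per_type) else cells_per_type
        comp = "other" if compartments is None else compartments[idx]
        for _ in range(n):
            rows.append(
                {
                    "cell_id": f"{prefix}{k:06d}",
                    "cell_type": ct,
                    "tissue": tissue,
                    "individual": individual,
                    "compartment": comp,
                    "method": "droplet",
                }
            )
            k += 1
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def _nb_counts(rng, mean, dispersion, size):
    """Negative-binomial draws with mean/dispersion (size) parametrization."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        raise ValueError(f"dispersion must be positive, got {dispersion}")
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDesign:
    """Cell-type-structured negative-binomial expression with planted markers.

    Each of ``n_marker_genes`` markers is assigned one target cell type
    (cyclically) whose mean is multiplied by ``marker_fold_change``.
    """

    n_cell_types: int = 3
    cells_per_type: int = 100
    n_genes: int = 50
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    n_marker_genes: int = 0
    marker_fold_change: float = 8.0
    marker_base_mean: float = 0.4  # ~30% expressing fraction before the shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_marker_genes > self.n_genes:
            raise ValueError("more marker genes than genes")


def simulate_expression(d: ExpressionDesign) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the count matrix; return it with the planted marker table."""
    rng = stage_rng(d.seed, "expression")
    cell_types = [f"type{t:02d}" for t in range(d.n_cell_types)]
    cells = _cell_frame(cell_types, d.cells_per_type)
    genes = [f"gene{g:04d}" for g in range(d.n_genes)]
    means = np.full((d.n_cell_types, d.n_genes), d.nb_mean)
    truth_rows = []
    for g in range(d.n_marker_genes):
        target = g % d.n_cell_types
        means[:, g] = d.marker_base_mean
        means[target, g] = d.marker_base_mean * d.marker_fold_change
        truth_rows.append({"gene_id": genes[g], "cell_type": cell_types[target]})
    type_idx = cells["cell_type"].map({ct: i for i, ct in enumerate(cell_types)}).to_numpy()
    counts = _nb_counts(rng, means[type_idx], d.nb_dispersion, (len(cells), d.n_genes))
    matrix = ExpressionMatrix(
        counts=sp.csr_matrix(counts), cells=cells, genes=genes
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "cell_type"])
    return matrix, truth


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------


@dataclass
class JunctionGeneDesign:
    """One gene's isoform structure: per-cell-type junction-usage vectors."""

    gene_id: str
    usage: np.ndarray  # cell types x junctions, rows sum to 1
    reads_per_cell: float = 20.0  # Poisson mean of the junctional depth


@dataclass
class JunctionDesign:
    genes: list[JunctionGeneDesign] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=lambda: ["type00", "type01"])
    cells_per_type: int = 50
    seed: int = 0


def uniform_usage(n_cell_types: int, n_junctions: int) -> np.ndarray:
    """Null design: identical uniform usage in every cell type."""
    return np.full((n_cell_types, n_junctions), 1.0 / n_junctions)


def switch_usage(p_high: float = 0.9) -> np.ndarray:
    """Two-junction isoform switch between two cell types (p vs 1-p)."""
    return np.array([[p_high, 1.0 - p_high], [1.0 - p_high, p_high]])


def simulate_junctions(d: JunctionDesign) -> JunctionCounts:
    rng = stage_rng(d.seed, "junctions")
    cells = _cell_frame(d.cell_types, d.cells_per_type)
    type_idx = cells["cell_type"].map({ct: i for i, ct in enumerate(d.cell_types)}).to_numpy()
    records: list[JunctionRecord] = []
    blocks: list[np.ndarray] = []
    pos = 1000
    for gd in d.genes:
        usage = np.asarray(gd.usage, dtype=float)
        if usage.shape[0] != len(d.cell_types):
            raise ValueError(
                f"{gd.gene_id}: usage has {usage.shape[0]} rows for "
                f"{len(d.cell_types)} cell types"
            )
        if np.any(np.abs(usage.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError(f"{gd.gene_id}: usage vectors must sum to 1")
        n_junc = usage.shape[1]
        depth = rng.poisson(gd.reads_per_cell, size=len(cells))
        gene_counts = np.zeros((len(cells), n_junc), dtype=np.int64)
        for m in range(len(cells)):
            if depth[m] > 0:
                gene_counts[m] = rng.multinomial(depth[m], usage[type_idx[m]])
        blocks.append(gene_counts)
        for j in range(n_junc):
            records.append(
                JunctionRecord(
                    junction_id=f"{gd.gene_id}_j{j}",
                    chrom="chr1",
                    donor_pos=pos,
                    acceptor_pos=pos + 100 + j * 50,
                    strand="+",
                    gene_id=gd.gene_id,
                )
            )
        pos += 10_000
    counts = np.concatenate(blocks, axis=1) if blocks else np.zeros((len(cells), 0), int)
    return JunctionCounts(counts=sp.csr_matrix(counts), junctions=records, cells=cells)


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------


@dataclass
class AlleleDesign:
    """Allele-resolved reads at a nonsense variant plus matched expression.

    In heterozygotes the wild-type allele carries weight ``compensation *
    trans_factor`` and the mutant allele ``1 - depletion``, so the expected
    mutant read fraction is (1-d) / ((1-d) + c*t) and total expression
    scales as (c*t + (1-d)) / 2 relative to wild-type individuals.
    c = t = 1 is the simple decay model; c > 1 models compensatory
    transcriptional upregulation; t < 1 models trans-reduction of the WT
    allele (or attenuated positive feedback).
    """

    depletion: float = 0.9
    compensation: float = 1.0
    trans_factor: float = 1.0
    genotypes: dict[str, str] = field(
        default_factory=lambda: {"L1": "WT", "L2": "het", "L3": "WT", "L4": "het"}
    )
    tissues: tuple[str, ...] = ("blood", "lung", "kidney")
    total_allele_reads: int = 3000  # per heterozygote, split over tissues
    gene_id: str = "GENE_MUT"
    n_cell_types: int = 40
    cells_per_type: int = 60
    gene_mean: float = 1.0  # per-cell count mean of the variant gene in WT
    background_genes: int = 30
    background_mean: float = 5.0
    nb_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depletion <= 1.0:
            raise ValueError(f"depletion must be in [0, 1], got {self.depletion}")
        if self.compensation < 1.0:
            raise ValueError("compensation factor must be >= 1")
        if not 0.0 < self.trans_factor <= 1.0:
            raise ValueError("trans_factor must be in (0, 1]")

    @property
    def wt_allele_weight(self) -> float:
        return self.compensation * self.trans_factor

    @property
    def expected_mut_fraction(self) -> float:
        num = 1.0 - self.depletion
        return num / (num + self.wt_allele_weight)

    @property
    def expected_het_scale(self) -> float:
        """Heterozygote total expression relative to WT individuals."""
        return (self.wt_allele_weight + (1.0 - self.depletion)) / 2.0


def simulate_allele_counts(
    d: AlleleDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Return the expression matrix and a per-(individual, tissue) read table.

    The read table has columns individual, tissue, wt_reads, mut_reads;
    homozygous-WT individuals carry only reference reads.
    """
    rng = stage_rng(d.seed, "alleles")
    cell_types = [f"type{t:02d}" for t in range(d.n_cell_types)]
    # cell-type-specific baseline for the variant gene, shared by individuals
    type_means = d.gene_mean * np.exp(rng.normal(0.0, 0.3, size=d.n_cell_types))
    frames, counts = [], []
    genes = [d.gene_id] + [f"bg{g:03d}" for g in range(d.background_genes)]
    for individual, gt in d.genotypes.items():
        scale = d.expected_het_scale if gt == "het" else 1.0
        cells = _cell_frame(
            cell_types, d.cells_per_type, individual=individual, prefix=f"{individual}_"
        )
        n = len(cells)
        type_idx = cells["cell_type"].map(
            {ct: i for i, ct in enumerate(cell_types)}
        ).to_numpy()
        gene_col = _nb_counts(rng, type_means[type_idx] * scale, d.nb_dispersion, (n,))
        bg = _nb_counts(rng, d.background_mean, d.nb_dispersion, (n, d.background_genes))
        counts.append(np.column_stack([gene_col, bg]))
        frames.append(cells)
    matrix = ExpressionMatrix(
        counts=sp.csr_matrix(np.concatenate(counts, axis=0)),
        cells=pd.concat(frames, ignore_index=True),
        genes=genes,
    )
    rows = []
    tissue_weights = rng.dirichlet(np.full(len(d.tissues), 5.0))
    for individual, gt in d.genotypes.items():
        if gt == "WT":
            for tissue, w in zip(d.tissues, tissue_weights):
                n_reads = int(round(d.total_allele_reads * w))
                rows.append(
                    {"individual": individual, "tissue": tissue,
                     "wt_reads": n_reads, "mut_reads": 0}
                )
            continue
        p_mut = d.expected_mut_fraction
        for tissue, w in zip(d.tissues, tissue_weights):
            n_reads = int(round(d.total_allele_reads * w))
            mut = int(rng.binomial(n_reads, p_mut))
            rows.append(
                {"individual": individual, "tissue": tissue,
                 "wt_reads": n_reads - mut, "mut_reads": mut}
            )
    return matrix, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ligand / receptor
# ---------------------------------------------------------------------------


@dataclass
class PlantedPair:
    """One ligand-receptor pair with its designated expressing cell types."""

    ligand: str
    receptor: str
    ligand_types: tuple[str, ...]
    receptor_types: tuple[str, ...]
    mean_counts: float = 3.0  # per-cell counts in expressing types


@dataclass
class LigandReceptorDesign:
    pairs: list[PlantedPair] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)
    organs: dict[str, str] = field(default_factory=dict)  # cell type -> organ
    immune: dict[str, bool] = field(default_factory=dict)
    cells_per_type: int = 60
    background_genes: int = 10
    background_mean: float = 5.0
    nb_dispersion: float = 5.0
    seed: int = 0


def simulate_ligand_receptor(
    d: LigandReceptorDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Return (expression, pair table, planted edge list).

    Planted edges are the ligand-type x receptor-type products of each
    pair, restricted to same-organ node pairs unless one endpoint's organ
    is blood, and deduplicated over pairs — i.e. the ground truth the
    network builder should recover.
    """
    import warnings

    rng = stage_rng(d.seed, "ligand_receptor")
    lr_genes: list[str] = []
    for p in d.pairs:
        for g in (p.ligand, p.receptor):
            if g not in lr_genes:
                lr_genes.append(g)
    genes = lr_genes + [f"bg{g:03d}" for g in range(d.background_genes)]
    cells = _cell_frame(d.cell_types, d.cells_per_type)
    n = len(cells)
    means = np.zeros((len(d.cell_types), len(genes)))
    means[:, len(lr_genes):] = d.background_mean
    tindex = {ct: i for i, ct in enumerate(d.cell_types)}
    gindex = {g: i for i, g in enumerate(genes)}
    for p in d.pairs:
        for ct in p.ligand_types:
            means[tindex[ct], gindex[p.ligand]] = p.mean_counts
        for ct in p.receptor_types:
            means[tindex[ct], gindex[p.receptor]] = p.mean_counts
        if p.mean_counts < 1.0:
            warnings.warn(
                f"pair {p.ligand}->{p.receptor}: planted mean {p.mean_counts} "
                "may fall below the absolute expression filter",
                stacklevel=2,
            )
    type_idx = cells["cell_type"].map(tindex).to_numpy()
    counts = _nb_counts(rng, means[type_idx], d.nb_dispersion, (n, len(genes)))
    matrix = ExpressionMatrix(counts=sp.csr_matrix(counts), cells=cells, genes=genes)
    pair_table = pd.DataFrame(
        [{"receptor": p.receptor, "ligand": p.ligand} for p in d.pairs]
    )
    edges = set()
    for p in d.pairs:
        for u in p.ligand_types:
            for v in p.receptor_types:
                ou, ov = d.organs[u], d.organs[v]
                if ou == ov or "blood" in (ou, ov):
                    edges.add((u, v))
    truth = pd.DataFrame(sorted(edges), columns=["src", "dst"])
    return matrix, pair_table, truth


# ---------------------------------------------------------------------------
# cross-species
# ---------------------------------------------------------------------------


@dataclass
class CrossSpeciesDesign:
    """Paired cell-type expression profiles with a target Pearson correlation.

    For each gene, both species' profiles share a standard-normal latent
    cell-type component with weight sqrt(r) plus independent noise with
    weight sqrt(1-r), then are shifted/scaled to positive expression
    means, so the expected cross-species correlation equals ``target_r``.
    """

    target_r: dict[str, float] = field(default_factory=dict)  # gene -> r
    n_cell_types: int = 30
    baseline: float = 2.0
    scale: float = 0.5
    seed: int = 0


def simulate_cross_species(
    d: CrossSpeciesDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (profiles_a, profiles_b): gene x cell-type mean expression."""
    rng = stage_rng(d.seed, "cross_species")
    cell_types = [f"type{t:02d}" for t in range(d.n_cell_types)]
    rows_a, rows_b = {}, {}
    for gene, r in d.target_r.items():
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target correlation for {gene} outside [-1, 1]")
        z = rng.normal(size=d.n_cell_types)
        ea = rng.normal(size=d.n_cell_types)
        eb = rng.normal(size=d.n_cell_types)
        w = np.sqrt(abs(r))
        nv = np.sqrt(1.0 - abs(r))
        xa = w * z + nv * ea
        xb = np.sign(r) * w * z + nv * eb if r != 0 else eb
        rows_a[gene] = d.baseline + d.scale * xa
        rows_b[gene] = d.baseline + d.scale * xb
    a = pd.DataFrame.from_dict(rows_a, orient="index", columns=cell_types)
    b = pd.DataFrame.from_dict(rows_b, orient="index", columns=cell_types)
    return a, b
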