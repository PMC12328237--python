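"""Data model and file I/O for atlas-style single-cell inputs.

Containers are thin dataclasses around scipy sparse matrices and pandas
frames.  On-disk formats are the field standards: matrix-market for counts,
TSV for cell/gene/junction metadata, GTF for gene models, VCF 4.x for
variants.  Genomic coordinates are 0-based half-open internally and 1-based
inclusive in every file read or written (the GTF/VCF dialect); conversion
happens only in the readers and writers in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

COMPARTMENTS = frozenset(
    {"immune", "epithelial", "endothelial", "stromal", "neural", "germ", "other"}
)
METHODS = frozenset({"droplet", "plate"})

#: columns every cell-metadata table must carry
CELL_COLUMNS = ["cell_id", "cell_type", "tissue", "individual", "compartment", "method"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_cells(cells: pd.DataFrame, source: str = "cell metadata") -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise FormatError(f"{source}: duplicate cell_id {dup!r}")
    for col in CELL_COLUMNS:
        vals = cells[col].astype(str)
        if (vals.str.len() == 0).any() or vals.isin(["nan", "None"]).any():
            raise FormatError(f"{source}: empty values in column {col!r}")
    bad = set(cells["compartment"]) - COMPARTMENTS
    if bad:
        raise FormatError(
            f"{source}: unknown compartment label(s) {sorted(bad)}; "
            f"valid values are {sorted(COMPARTMENTS)}"
        )
    bad = set(cells["method"]) - METHODS
    if bad:
        raise FormatError(
            f"{source}: unknown method label(s) {sorted(bad)}; "
            f"valid values are {sorted(METHODS)}"
        )
    return cells.reset_index(drop=True)


def _check_counts(counts: sp.spmatrix, source: str) -> sp.csr_matrix:
    counts = sp.csr_matrix(counts)
    if counts.nnz and counts.data.min() < 0:
        raise FormatError(f"{source}: negative count encountered")
    if counts.nnz and np.any(counts.data != np.round(counts.data)):
        raise FormatError(f"{source}: non-integral count encountered")
    return counts


@dataclass
class ExpressionMatrix:
    """Sparse cell x gene UMI counts with cell annotations.

    ``normalized`` holds ln(UP10K + 1) values when populated (see
    :func:`normalize_ln_up10k`); raw counts are never modified.
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: list[str]
    normalized: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = _check_counts(self.counts, "expression matrix")
        self.cells = _check_cells(self.cells)
        self.genes = list(self.genes)
        if self.counts.shape[0] != len(self.cells):
            raise FormatError(
                f"expression matrix has {self.counts.shape[0]} rows but "
                f"{len(self.cells)} cell metadata lines"
            )
        if self.counts.shape[1] != len(self.genes):
            raise FormatError(
                f"expression matrix has {self.counts.shape[1]} columns but "
                f"{len(self.genes)} gene identifiers"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            counts=self.counts[mask],
            cells=self.cells.loc[mask].reset_index(drop=True),
            genes=self.genes,
            normalized=None if self.normalized is None else self.normalized[mask],
        )


def normalize_ln_up10k(m: ExpressionMatrix) -> ExpressionMatrix:
    """Populate ``normalized`` with ln(UMI_gene / UMI_total x 10^4 + 1).

    Cells with zero total counts produce an all-zero normalized row (and a
    warning); raw counts are left untouched.
    """
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        logger.warning(
            "%d cell(s) with zero total counts normalize to all-zero rows", zero.sum()
        )
    safe = np.where(zero, 1.0, totals)
    dense = m.counts.toarray().astype(float)
    normalized = np.log1p(dense / safe[:, None] * 1e4)
    normalized[zero] = 0.0
    return replace(m, normalized=normalized)


@dataclass(frozen=True)
class JunctionRecord:
    """A splice junction: donor/acceptor genomic positions (0-based internal)."""

    junction_id: str
    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.donor_pos == self.acceptor_pos:
            raise FormatError(
                f"junction {self.junction_id}: donor and acceptor coincide "
                f"at {self.donor_pos}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"junction {self.junction_id}: strand must be + or -, got "
                f"{self.strand!r}"
            )


@dataclass
class JunctionCounts:
    """Sparse cell x junction spliced-read counts with junction metadata."""

    counts: sp.csr_matrix
    junctions: list[JunctionRecord]
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = _check_counts(self.counts, "junction matrix")
        self.cells = _check_cells(self.cells)
        if self.counts.shape[0] != len(self.cells):
            raise FormatError(
                f"junction matrix has {self.counts.shape[0]} rows but "
                f"{len(self.cells)} cell metadata lines"
            )
        if self.counts.shape[1] != len(self.junctions):
            raise FormatError(
                f"junction matrix has {self.counts.shape[1]} columns but "
                f"{len(self.junctions)} junction records"
            )


@dataclass
class GeneAnnotationModel:
    """Annotated gene intervals, junction pairs and splice-site sets.

    Intervals are 0-based half-open.  ``junction_pairs`` maps chrom to the
    set of annotated (donor, acceptor) position pairs; the site sets pool
    all annotated donor (resp. acceptor) positions per chromosome.
    """

    genes: pd.DataFrame  # chrom, start, end, strand, gene_id
    junction_pairs: dict[str, set[tuple[int, int]]]
    donor_sites: dict[str, set[int]]
    acceptor_sites: dict[str, set[int]]

    def __post_init__(self) -> None:
        for chrom, pairs in self.junction_pairs.items():
            for d, a in pairs:
                if d not in self.donor_sites.get(chrom, set()):
                    raise FormatError(
                        f"annotated junction ({chrom}:{d}-{a}) donor missing "
                        "from donor site set"
                    )
                if a not in self.acceptor_sites.get(chrom, set()):
                    raise FormatError(
                        f"annotated junction ({chrom}:{d}-{a}) acceptor missing "
                        "from acceptor site set"
                    )


@dataclass(frozen=True)
class VariantRecord:
    """A profiled variant with per-individual genotypes.

    ``genotypes`` maps individual id -> one of {"WT", "het", "hom"};
    ``in_last_exon`` must be set for every stop_gain variant (last-exon
    premature stops escape NMD).
    """

    variant_id: str
    chrom: str
    pos: int  # 0-based internal
    ref: str
    alt: str
    gene_id: str
    consequence: str  # stop_gain | frameshift | other
    in_last_exon: Optional[bool]
    genotypes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.consequence not in {"stop_gain", "frameshift", "other"}:
            raise FormatError(
                f"variant {self.variant_id}: bad consequence {self.consequence!r}"
            )
        if self.consequence == "stop_gain" and self.in_last_exon is None:
            raise FormatError(
                f"variant {self.variant_id}: in_last_exon required for stop_gain"
            )
        seen = [ind for ind, _ in self.genotypes]
        if len(seen) != len(set(seen)):
            raise FormatError(
                f"variant {self.variant_id}: duplicate individual genotype"
            )
        for ind, gt in self.genotypes:
            if gt not in {"WT", "het", "hom"}:
                raise FormatError(
                    f"variant {self.variant_id}: bad genotype {gt!r} for {ind}"
                )

    def genotype_of(self, individual: str) -> str:
        for ind, gt in self.genotypes:
            if ind == individual:
                return gt
        raise KeyError(individual)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(matrix_path, cells_path, genes_path) -> ExpressionMatrix:
    """Read a matrix-market counts file plus cell/gene metadata TSVs.

    The matrix is cells x genes; metadata rows attach in file order.
    Dimension mismatches raise :class:`FormatError` naming the offending
    file.
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    genes_df = pd.read_csv(genes_path, sep="\t", dtype=str)
    if "gene_id" not in genes_df.columns:
        raise FormatError(f"{genes_path}: gene table needs a gene_id column")
    genes = genes_df["gene_id"].tolist()
    if counts.shape[0] != len(cells):
        raise FormatError(
            f"{cells_path}: {len(cells)} metadata lines for a matrix with "
            f"{counts.shape[0]} rows"
        )
    if counts.shape[1] != len(genes):
        raise FormatError(
            f"{genes_path}: {len(genes)} gene lines for a matrix with "
            f"{counts.shape[1]} columns"
        )
    return ExpressionMatrix(counts=counts, cells=cells, genes=genes)


def write_expression(m: ExpressionMatrix, matrix_path, cells_path, genes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(m.counts), field="integer")
    m.cells.to_csv(cells_path, sep="\t", index=False)
    pd.DataFrame({"gene_id": m.genes}).to_csv(genes_path, sep="\t", index=False)


_JUNCTION_COLS = ["junction_id", "chrom", "donor_pos", "acceptor_pos", "strand", "gene_id"]


def read_junctions(matrix_path, junctions_path, cells_path) -> JunctionCounts:
    """Read junction counts (MTX) plus a BED-like junction TSV (1-based)."""
    counts = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    table = pd.read_csv(junctions_path, sep="\t", dtype=str)
    missing = [c for c in _JUNCTION_COLS if c not in table.columns]
    if missing:
        raise FormatError(f"{junctions_path}: missing columns {missing}")
    records = []
    for lineno, row in enumerate(table.itertuples(index=False), start=2):
        try:
            records.append(
                JunctionRecord(
                    junction_id=row.junction_id,
                    chrom=row.chrom,
                    donor_pos=int(row.donor_pos) - 1,
                    acceptor_pos=int(row.acceptor_pos) - 1,
                    strand=row.strand,
                    gene_id=None if pd.isna(row.gene_id) or row.gene_id == "" else row.gene_id,
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{junctions_path} line {lineno}: {exc}") from None
    if counts.shape[0] != len(cells):
        raise FormatError(
            f"{cells_path}: {len(cells)} metadata lines for a matrix with "
            f"{counts.shape[0]} rows"
        )
    if counts.shape[1] != len(records):
        raise FormatError(
            f"{junctions_path}: {len(records)} junctions for a matrix with "
            f"{counts.shape[1]} columns"
        )
    return JunctionCounts(counts=counts, junctions=records, cells=cells)


def write_junctions(jc: JunctionCounts, matrix_path, junctions_path, cells_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(jc.counts), field="integer")
    rows = [
        {
            "junction_id": j.junction_id,
            "chrom": j.chrom,
            "donor_pos": j.donor_pos + 1,
            "acceptor_pos": j.acceptor_pos + 1,
            "strand": j.strand,
            "gene_id": "" if j.gene_id is None else j.gene_id,
        }
        for j in jc.junctions
    ]
    pd.DataFrame(rows, columns=_JUNCTION_COLS).to_csv(junctions_path, sep="\t", index=False)
    jc.cells.to_csv(cells_path, sep="\t", index=False)


def read_annotation(gtf_path) -> GeneAnnotationModel:
    """Build a gene/junction annotation model from a GTF file.

    Annotated junctions are derived per transcript by pairing adjacent exon
    boundaries: for consecutive exons the junction donor is the end of the
    upstream exon and the acceptor the start of the downstream exon (in
    genomic order; intron positions, 0-based internal).
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    gene_rows = []
    pairs: dict[str, set[tuple[int, int]]] = {}
    donors: dict[str, set[int]] = {}
    acceptors: dict[str, set[int]] = {}
    exons_by_tx: dict[str, list] = {}
    for feat in db.all_features():
        if feat.strand not in {"+", "-"}:
            raise FormatError(
                f"{gtf_path}: strand {feat.strand!r} for {feat.id} (must be + or -)"
            )
        if feat.featuretype == "gene":
            gene_rows.append(
                {
                    "chrom": feat.seqid,
                    "start": feat.start - 1,
                    "end": feat.end,
                    "strand": feat.strand,
                    "gene_id": feat.attributes["gene_id"][0],
                }
            )
        elif feat.featuretype == "exon":
            tx = feat.attributes["transcript_id"][0]
            exons_by_tx.setdefault(tx, []).append(feat)
    for exons in exons_by_tx.values():
        exons = sorted(exons, key=lambda e: e.start)
        for up, down in zip(exons, exons[1:]):
            chrom = up.seqid
            # first intronic base after the upstream exon / last before the next
            donor, acceptor = up.end, down.start - 2
            pairs.setdefault(chrom, set()).add((donor, acceptor))
            donors.setdefault(chrom, set()).add(donor)
            acceptors.setdefault(chrom, set()).add(acceptor)
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    return GeneAnnotationModel(
        genes=genes, junction_pairs=pairs, donor_sites=donors, acceptor_sites=acceptors
    )


def read_variants(vcf_path) -> list[VariantRecord]:
    """Read nonsense/frameshift variants from a VCF 4.x file.

    Expects INFO keys GENE, CONSEQ (stop_gained / frameshift_variant /
    other) and, for stop-gained variants, LAST_EXON (0/1).  Genotypes come
    from the per-sample GT field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    records = []
    conseq_map = {
        "stop_gained": "stop_gain",
        "frameshift_variant": "frameshift",
        "other": "other",
    }
    for var in vcf:
        raw = var.INFO.get("CONSEQ", "other")
        conseq = conseq_map.get(raw, "other")
        last_exon = var.INFO.get("LAST_EXON")
        genotypes = []
        for sample, gts in zip(samples, var.genotypes):
            alleles = [g for g in gts[:-1] if g >= 0]
            n_alt = sum(1 for g in alleles if g > 0)
            if n_alt == 0:
                gt = "WT"
            elif n_alt == len(alleles):
                gt = "hom"
            else:
                gt = "het"
            genotypes.append((sample, gt))
        records.append(
            VariantRecord(
                variant_id=var.ID or f"{var.CHROM}:{var.POS}:{var.REF}>{var.ALT[0]}",
                chrom=var.CHROM,
                pos=var.POS - 1,
                ref=var.REF,
                alt=var.ALT[0],
                gene_id=var.INFO.get("GENE", ""),
                consequence=conseq,
                in_last_exon=None if last_exon is None else bool(int(last_exon)),
                genotypes=tuple(genotypes),
            )
        )
    return records


def write_results(df: pd.DataFrame, path) -> None:
    """Write a result table as CSV (the output dialect of every stage)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
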