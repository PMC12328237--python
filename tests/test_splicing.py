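"""Junction categories, testability filters, z-scores and the MANOVA stage."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from atlasstats.config import AnalysisConfig
from atlasstats.io import GeneAnnotationModel, JunctionCounts, JunctionRecord
from atlasstats import simulate as sim
from atlasstats.splicing import (
    JunctionCategory,
    bh_adjust,
    call_differential,
    classify_junction,
    differential_splicing,
    filter_for_testing,
    junction_zscores,
    manova_per_gene,
    percent_fewer,
)
from conftest import make_cells


def make_annotation():
    genes = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 100, "end": 1000, "strand": "+", "gene_id": "gA"},
            {"chrom": "chr1", "start": 2000, "end": 3000, "strand": "-", "gene_id": "gB"},
        ]
    )
    pairs = {"chr1": {(200, 298), (200, 498), (400, 498)}}
    donors = {"chr1": {200, 400, 2200}}
    acceptors = {"chr1": {298, 498, 2400}}
    return GeneAnnotationModel(
        genes=genes, junction_pairs=pairs, donor_sites=donors, acceptor_sites=acceptors
    )


def jrec(donor, acceptor, chrom="chr1"):
    return JunctionRecord("j", chrom, donor, acceptor, "+", None)


class TestClassification:
    @pytest.mark.parametrize(
        "donor,acceptor,expected",
        [
            (200, 298, JunctionCategory.A),  # annotated pair
            (200, 2400, JunctionCategory.B),  # both sites known, pair novel
            (200, 333, JunctionCategory.C),  # one known site
            (410, 633, JunctionCategory.D),  # novel sites inside gA
            (5000, 6000, JunctionCategory.E),  # intergenic
        ],
    )
    def test_category_rules(self, donor, acceptor, expected):
        assert classify_junction(jrec(donor, acceptor), make_annotation()) == expected

    def test_gene_straddling_junction_is_E_not_D(self):
        # novel sites spanning from inside gA to inside gB: no single gene
        # contains both, so the junction is not "within an annotated gene"
        assert classify_junction(jrec(500, 2500), make_annotation()) == JunctionCategory.E

    def test_matches_brute_force_oracle_on_random_junctions(self):
        rng = np.random.default_rng(42)
        n_genes = 20
        starts = rng.choice(np.arange(0, 100_000, 1000), size=n_genes, replace=False)
        genes = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + rng.integers(200, 900, n_genes),
                "strand": "+",
                "gene_id": [f"g{k}" for k in range(n_genes)],
            }
        )
        donors = set(rng.integers(0, 100_000, 300).tolist())
        acceptors = set(rng.integers(0, 100_000, 300).tolist()) - donors
        pairs = {
            (d, a)
            for d, a in zip(rng.choice(sorted(donors), 100), rng.choice(sorted(acceptors), 100))
        }
        ann = GeneAnnotationModel(
            genes=genes,
            junction_pairs={"chr1": pairs},
            donor_sites={"chr1": donors},
            acceptor_sites={"chr1": acceptors},
        )

        def oracle(j):
            # independent literal restatement of the category definitions
            if (j.donor_pos, j.acceptor_pos) in pairs:
                return "A"
            dk = j.donor_pos in donors
            ak = j.acceptor_pos in acceptors
            if dk and ak:
                return "B"
            if dk != ak:
                return "C"
            lo, hi = sorted((j.donor_pos, j.acceptor_pos))
            for row in genes.itertuples():
                if row.start <= lo and hi < row.end:
                    return "D"
            return "E"

        pool = sorted(donors | acceptors | set(rng.integers(0, 100_000, 500).tolist()))
        for _ in range(1000):
            d, a = rng.choice(pool, 2, replace=False)
            j = jrec(int(d), int(a))
            assert classify_junction(j, ann).value == oracle(j)


def build_counts(matrix, cell_types, gene_ids):
    """JunctionCounts from a dense matrix; one junction per column."""
    matrix = np.asarray(matrix)
    recs = [
        JunctionRecord(f"j{k}", "chr1", 100 + 1000 * k, 600 + 1000 * k, "+", g)
        for k, g in enumerate(gene_ids)
    ]
    return JunctionCounts(
        counts=sp.csr_matrix(matrix), junctions=recs, cells=make_cells(cell_types)
    )


class TestFiltering:
    def test_small_cell_type_dropped(self):
        types = ["a"] * 10 + ["b"] * 9
        m = np.ones((19, 2), dtype=int)
        out = filter_for_testing(build_counts(m, types, ["g", "g"]))
        assert set(out.cells["cell_type"]) == {"a"}

    def test_junction_in_single_cell_dropped(self):
        types = ["a"] * 10 + ["b"] * 10
        m = np.ones((20, 2), dtype=int)
        m[1:, 1] = 0  # second junction seen in exactly one cell
        out = filter_for_testing(build_counts(m, types, ["g", "g"]))
        assert [j.junction_id for j in out.junctions] == []  # lone survivor is constant

    def test_gene_needs_two_reads_in_every_cell_type(self):
        types = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        m = np.zeros((30, 2), dtype=int)
        m[:10] = [[2, 2]]
        m[10:20] = [[1, 2]]
        m[20:25, 0] = 1  # cell type c: 5 reads on j0, 0 on j1... gene has 5
        out = filter_for_testing(build_counts(m, types, ["g", "g"]))
        assert len(out.junctions) == 2  # every type has >=2 gene reads
        m2 = m.copy()
        m2[20:25, 0] = 0
        m2[20, 0] = 1  # cell type c: 1 junctional read over the gene
        out2 = filter_for_testing(build_counts(m2, types, ["g", "g"]))
        assert len(out2.junctions) == 0

    def test_single_junction_gene_excluded(self):
        types = ["a"] * 10 + ["b"] * 10
        m = np.ones((20, 1), dtype=int) * 3
        out = filter_for_testing(build_counts(m, types, ["g"]))
        assert len(out.junctions) == 0

    def test_adding_cells_never_removes_a_retained_junction(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_junc = int(rng.integers(2, 5))
            base = rng.integers(0, 4, size=(24, n_junc))
            types = ["a"] * 12 + ["b"] * 12
            kept_before = {
                j.junction_id
                for j in filter_for_testing(
                    build_counts(base, types, ["g"] * n_junc)
                ).junctions
            }
            extra = rng.integers(0, 4, size=(6, n_junc))
            grown = np.vstack([base, extra])
            kept_after = {
                j.junction_id
                for j in filter_for_testing(
                    build_counts(grown, types + ["a"] * 3 + ["b"] * 3, ["g"] * n_junc)
                ).junctions
            }
            assert kept_before <= kept_after


class TestZScores:
    def test_symmetric_counts_give_half_fractions(self):
        jc = build_counts([[3, 1], [1, 3]], ["a", "b"], ["g", "g"])
        zs = junction_zscores(jc, "g")
        assert zs.f_dataset == pytest.approx([0.5, 0.5])

    def test_hand_evaluated_z(self):
        # cell 0: total 4 reads, n_i = 3, dataset f = 0.5
        # z = sqrt(4) * (0.75 - 0.5) / sqrt(0.25) = 1.0
        jc = build_counts([[3, 1], [1, 3]], ["a", "b"], ["g", "g"])
        zs = junction_zscores(jc, "g")
        assert zs.z[0, 0] == pytest.approx(1.0)
        assert zs.z[1, 0] == pytest.approx(-1.0)

    def test_cell_at_dataset_average_has_zero_z(self):
        jc = build_counts([[2, 2], [1, 3], [3, 1]], ["a", "b", "b"], ["g", "g"])
        zs = junction_zscores(jc, "g")
        assert zs.z[0] == pytest.approx([0.0, 0.0])

    @given(
        st.lists(
            st.lists(st.integers(0, 20), min_size=3, max_size=3),
            min_size=2,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_per_cell_fractions_sum_to_one(self, rows):
        m = np.array(rows)
        if (m.sum(axis=1) == 0).all() or (m.sum(axis=0) == 0).any():
            return  # degenerate: filter contract not met
        totals = m.sum(axis=0)
        if (totals == totals.sum()).any():
            return
        jc = build_counts(m, ["a"] * len(rows), ["g", "g", "g"])
        zs = junction_zscores(jc, "g")
        assert np.allclose(zs.f_cell.sum(axis=1), 1.0, atol=1e-12)


def pillai_oracle(y, labels):
    """Independent Pillai trace p-value: direct SSCP algebra + F approx."""
    from scipy.stats import f as fdist

    y = np.asarray(y, float)
    labels = np.asarray(labels)
    grand = y.mean(axis=0)
    groups = np.unique(labels)
    H = np.zeros((y.shape[1], y.shape[1]))
    W = np.zeros_like(H)
    for g in groups:
        sub = y[labels == g]
        mu = sub.mean(axis=0)
        H += len(sub) * np.outer(mu - grand, mu - grand)
        W += (sub - mu).T @ (sub - mu)
    V = np.trace(H @ np.linalg.inv(H + W))
    p, k, N = y.shape[1], len(groups), len(y)
    s = min(p, k - 1)
    m = (abs(p - k + 1) - 1) / 2
    n = (N - k - p - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n + s + 1)
    F = (2 * n + s + 1) / (2 * m + s + 1) * V / (s - V)
    return float(fdist.sf(F, df1, df2))


class TestManova:
    def _zscores(self, seed, nt=3, p_high=None):
        usage = (
            sim.uniform_usage(nt, 4)
            if p_high is None
            else np.vstack([[p_high, 1 - p_high, 0.0, 0.0][: 4]] * nt)
        )
        jd = sim.JunctionDesign(
            genes=[sim.JunctionGeneDesign("g", sim.uniform_usage(nt, 4))],
            cell_types=[f"t{k}" for k in range(nt)],
            cells_per_type=30,
            seed=seed,
        )
        jc = sim.simulate_junctions(jd)
        filtered = filter_for_testing(jc)
        return filtered, junction_zscores(filtered, "g")

    def test_matches_independent_pillai_oracle(self):
        for seed in range(5):
            filtered, zs = self._zscores(seed)
            labels = filtered.cells["cell_type"].to_numpy()[zs.cell_index]
            res = manova_per_gene(zs, filtered.cells["cell_type"].to_numpy())
            assert res.status == "ok"
            expected = pillai_oracle(zs.z[:, :-1], labels)
            assert res.p_value == pytest.approx(expected, abs=1e-8)

    def test_single_cell_type_untestable(self):
        filtered, zs = self._zscores(1, nt=1)
        res = manova_per_gene(zs, filtered.cells["cell_type"].to_numpy())
        assert res.status == "untestable"
        assert np.isnan(res.p_value)

    def test_extreme_switch_called(self):
        jd = sim.JunctionDesign(
            genes=[sim.JunctionGeneDesign("g", sim.switch_usage(0.9))], seed=3
        )
        table = differential_splicing(sim.simulate_junctions(jd))
        assert bool(table.loc[0, "called_differential"])
        assert table.loc[0, "p_adjusted"] < 1e-16


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_no_calls(self):
        from atlasstats.splicing import GeneSplicingResult

        results = [GeneSplicingResult(f"g{k}", 1.0) for k in range(3)]
        out = call_differential(results)
        assert not any(r.called_differential for r in out)
        assert all(r.p_adjusted >= r.p_value for r in out)


def test_percent_fewer_arithmetic():
    assert percent_fewer(50, 100) == pytest.approx(50.0)
    assert percent_fewer(100, 100) == 0.0
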