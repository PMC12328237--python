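"""Binarization thresholds, ceiling, edge rules and network densities."""

import numpy as np
import pandas as pd
import pytest

from atlasstats.chemokine import (
    ChemokineNetwork,
    absolute_filter,
    build_network,
    compute_ceiling,
    density_by_partition,
    expression_calls,
)
from atlasstats.config import AnalysisConfig
from atlasstats import simulate as sim


class TestAbsoluteFilter:
    @pytest.mark.parametrize(
        "fraction,mean,expected",
        [
            (0.10, 0.6, True),
            (0.04, 2.0, False),  # fraction clause fails
            (0.10, 0.4, False),  # mean clause fails
            (0.05, 0.5, True),  # inclusive "at least" at both bounds
        ],
    )
    def test_rule(self, fraction, mean, expected):
        assert absolute_filter(fraction, mean) is expected


class TestCeiling:
    def test_linear_interpolation_percentile(self):
        assert compute_ceiling([0.6, 1.0, 2.0, 5.0]) == pytest.approx(4.91)

    def test_singleton(self):
        assert compute_ceiling([3.0]) == 3.0

    def test_all_equal(self):
        assert compute_ceiling([1.2, 1.2, 1.2]) == pytest.approx(1.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_ceiling([])


def planted_design(seed=0, mean_counts=8.0):
    return sim.LigandReceptorDesign(
        pairs=[
            sim.PlantedPair("L1g", "R1g", ("stromal0",), ("immune0", "immune1"),
                            mean_counts=mean_counts),
            sim.PlantedPair("L2g", "R2g", ("epi0",), ("immune1",),
                            mean_counts=mean_counts),
        ],
        cell_types=["stromal0", "epi0", "immune0", "immune1"],
        organs={"stromal0": "bone", "epi0": "gut",
                "immune0": "blood", "immune1": "blood"},
        immune={"stromal0": False, "epi0": False,
                "immune0": True, "immune1": True},
        cells_per_type=80,
        seed=seed,
    )


class TestCalls:
    def test_relative_thresholds_receptor_vs_ligand(self):
        # ceiling 4.91: mean 0.30 passes the 5% receptor bar (0.2455)
        # but not the 20% ligand bar (0.982); boundary mean is excluded
        cfg = AnalysisConfig()
        ceiling = 4.91
        assert 0.30 > cfg.chemokine_receptor_rel * ceiling
        assert 0.30 < cfg.chemokine_ligand_rel * ceiling
        rec_threshold = cfg.chemokine_receptor_rel * ceiling
        assert not rec_threshold > rec_threshold  # strict ">" at the bar

    def test_absolute_failure_blocks_any_call(self):
        expr, pairs, _ = sim.simulate_ligand_receptor(planted_design())
        calls = expression_calls(expr, ["L1g"], AnalysisConfig())
        off = calls[calls["cell_type"] == "epi0"].iloc[0]
        assert not off["call_ligand"] and not off["call_receptor"]

    def test_planted_mean_below_filter_warns(self):
        with pytest.warns(UserWarning, match="absolute expression filter"):
            sim.simulate_ligand_receptor(planted_design(mean_counts=0.5))


def edges_df(pairs):
    return pd.DataFrame([{"src": u, "dst": v, "via_pairs": ""} for u, v in pairs])


class TestNetwork:
    def test_density_hand_count(self):
        net = ChemokineNetwork(
            nodes=["A", "B", "C"],
            organs={},
            edges=edges_df([("A", "B"), ("B", "A"), ("A", "A"), ("C", "B")]),
            density=4 / 9,
        )
        assert net.density == pytest.approx(0.4444, abs=1e-4)

    def test_planted_edges_recovered_exactly(self):
        design = planted_design(seed=3)
        expr, pairs, truth = sim.simulate_ligand_receptor(design)
        calls = expression_calls(expr, sorted(set(pairs["ligand"]) | set(pairs["receptor"])))
        net = build_network(calls, pairs, design.organs)
        got = set(zip(net.edges["src"], net.edges["dst"]))
        expected = set(zip(truth["src"], truth["dst"]))
        assert got == expected  # precision = recall = 1

    def test_same_direction_edges_deduplicated(self):
        calls = pd.DataFrame(
            [
                {"cell_type": "A", "gene": g, "fraction": 1.0, "mean": 3.0,
                 "ceiling": 3.0, "call_receptor": True, "call_ligand": True}
                for g in ["l1", "r1", "l2", "r2"]
            ]
            + [
                {"cell_type": "B", "gene": g, "fraction": 1.0, "mean": 3.0,
                 "ceiling": 3.0, "call_receptor": True, "call_ligand": False}
                for g in ["l1", "r1", "l2", "r2"]
            ]
        )
        pairs = pd.DataFrame(
            [{"receptor": "r1", "ligand": "l1"}, {"receptor": "r2", "ligand": "l2"}]
        )
        net = build_network(calls, pairs, {"A": "lung", "B": "lung"})
        # A->B realized via both pairs but counted once
        ab = net.edges[(net.edges["src"] == "A") & (net.edges["dst"] == "B")]
        assert len(ab) == 1
        assert ab.iloc[0]["via_pairs"] == "l1:r1;l2:r2"

    def test_cross_organ_excluded_unless_blood(self):
        calls = pd.DataFrame(
            [
                {"cell_type": ct, "gene": g, "fraction": 1.0, "mean": 3.0,
                 "ceiling": 3.0, "call_receptor": g == "r", "call_ligand": g == "l"}
                for ct in ["A", "B", "C"]
                for g in ["l", "r"]
            ]
        )
        pairs = pd.DataFrame([{"receptor": "r", "ligand": "l"}])
        organs = {"A": "lung", "B": "gut", "C": "blood"}
        net = build_network(calls, pairs, organs)
        got = set(zip(net.edges["src"], net.edges["dst"]))
        # lung<->gut forbidden; anything touching blood allowed; self-loops kept
        assert ("A", "B") not in got and ("B", "A") not in got
        assert {("A", "C"), ("C", "A"), ("B", "C"), ("C", "B"),
                ("A", "A"), ("C", "C")} <= got

    def test_unknown_gene_in_pair_table_skipped(self, caplog):
        calls = pd.DataFrame(
            [{"cell_type": "A", "gene": "l", "fraction": 1.0, "mean": 3.0,
              "ceiling": 3.0, "call_receptor": True, "call_ligand": True}]
        )
        pairs = pd.DataFrame([{"receptor": "missing", "ligand": "l"}])
        net = build_network(calls, pairs, {"A": "lung"})
        assert len(net.edges) == 0

    def test_raising_expression_never_deletes_edges(self):
        design = planted_design(seed=5)
        expr, pairs, _ = sim.simulate_ligand_receptor(design)
        genes = sorted(set(pairs["ligand"]) | set(pairs["receptor"]))
        before = build_network(expression_calls(expr, genes), pairs, design.organs)
        boosted = expr.counts.tolil()
        gi = expr.genes.index("L2g")
        mask = (expr.cells["cell_type"] == "immune0").to_numpy()
        boosted[np.flatnonzero(mask), gi] = 4
        expr2 = type(expr)(counts=boosted.tocsr(), cells=expr.cells, genes=expr.genes)
        after = build_network(expression_calls(expr2, genes), pairs, design.organs)
        got_before = set(zip(before.edges["src"], before.edges["dst"]))
        got_after = set(zip(after.edges["src"], after.edges["dst"]))
        assert got_before <= got_after


class TestPartitionDensities:
    def _net(self, nodes, pairs):
        return ChemokineNetwork(nodes=nodes, organs={}, edges=edges_df(pairs),
                                density=len(pairs) / len(nodes) ** 2)

    def test_complete_graph_density_one(self):
        nodes = ["A", "B"]
        pairs = [(u, v) for u in nodes for v in nodes]
        out = density_by_partition(self._net(nodes, pairs), {"A": True, "B": False})
        assert out["all"] == 1.0 and out["cross"] == 1.0
        assert out["immune"] == 1.0 and out["non_immune"] == 1.0

    def test_empty_partition_is_none(self):
        nodes = ["A", "B"]
        out = density_by_partition(
            self._net(nodes, [("A", "B")]), {"A": True, "B": True}
        )
        assert out["non_immune"] is None and out["cross"] is None

    def test_hand_counted_partition_densities(self):
        nodes = ["i1", "i2", "n1"]
        pairs = [("i1", "i2"), ("i2", "i1"), ("i1", "n1"), ("n1", "n1")]
        out = density_by_partition(
            self._net(nodes, pairs), {"i1": True, "i2": True, "n1": False}
        )
        assert out["all"] == pytest.approx(4 / 9)
        assert out["immune"] == pytest.approx(2 / 4)
        assert out["non_immune"] == pytest.approx(1 / 1)
        assert out["cross"] == pytest.approx(1 / (2 * 2 * 1))


def test_thresholds_at_zero_give_dense_coexpression_graph():
    """Limit check: with the filters disabled the network equals the
    'any co-expression' graph."""
    design = planted_design(seed=9)
    expr, pairs, _ = sim.simulate_ligand_receptor(design)
    cfg = AnalysisConfig(
        chemokine_min_fraction=0.0, chemokine_min_mean=0.0,
        chemokine_receptor_rel=0.0, chemokine_ligand_rel=0.0,
    )
    genes = sorted(set(pairs["ligand"]) | set(pairs["receptor"]))
    calls = expression_calls(expr, genes, cfg)
    net = build_network(calls, pairs, design.organs)
    # brute-force: any cell type with >0 mean of ligand -> any with >0 mean
    # of receptor, organ rule applied
    expected = set()
    by = calls.set_index(["gene", "cell_type"])["mean"]
    for row in pairs.itertuples(index=False):
        for u in design.cell_types:
            for v in design.cell_types:
                if by[(row.ligand, u)] > 0 and by[(row.receptor, v)] > 0:
                    ou, ov = design.organs[u], design.organs[v]
                    if ou == ov or "blood" in (ou, ov):
                        expected.add((u, v))
    got = set(zip(net.edges["src"], net.edges["dst"]))
    assert got == expected
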