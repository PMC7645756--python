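"""communication_network: expression thresholding, link counting, comparisons."""

import numpy as np
import pandas as pd
import pytest

from scbmm.communication_network import (
    LRDatabase,
    build_links,
    communication_strength,
    delta_network,
    expressed_genes_by_type,
    ligand_and_receptor_lists,
    network_from_links,
)

from conftest import make_count_matrix
from oracles import brute_force_network


def _lrdb(pairs):
    return LRDatabase(pd.DataFrame(pairs, columns=["ligand", "receptor"]))


class TestLRDatabase:
    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _lrdb([("L1", "R1"), ("L1", "R1")])

    def test_empty_symbol_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            _lrdb([("", "R1")])

    def test_tsv_round_trip(self, tmp_path):
        db = _lrdb([("L1", "R1"), ("L2", "R2")])
        db.to_tsv(tmp_path / "lr.tsv")
        back = LRDatabase.from_tsv(tmp_path / "lr.tsv")
        assert back.pairs.equals(db.pairs)

    def test_coverage_report(self):
        db = _lrdb([("L1", "R1"), ("L2", "Rmissing")])
        cov = db.coverage({"L1", "R1", "L2"})
        assert cov == {"n_pairs": 2, "n_pairs_measurable": 1, "coverage": 0.5}


class TestExpressedGenesByType:
    def _cm(self, per_type_expr):
        """per_type_expr: {type: expressed-cell count out of 5 for gene g0}"""
        rows, types = [], []
        for t, k in per_type_expr.items():
            for i in range(5):
                rows.append([1 if i < k else 0, 1])
                types.append(t)
        return make_count_matrix(np.array(rows), cell_types=types)

    def test_boundary_inclusive_at_threshold(self):
        cm = self._cm({"A": 1})  # 1 of 5 = exactly 0.20
        out = expressed_genes_by_type(cm, "D0", threshold=0.20)
        assert "g0" in out["A"]

    def test_below_threshold_excluded(self):
        rows = np.zeros((100, 2), dtype=int)
        rows[:19, 0] = 1  # 0.19
        rows[:, 1] = 1
        cm = make_count_matrix(rows, cell_types=["A"] * 100)
        out = expressed_genes_by_type(cm, "D0", threshold=0.20)
        assert "g0" not in out["A"]

    def test_zero_threshold_gives_any_detected(self):
        cm = self._cm({"A": 1})
        out = expressed_genes_by_type(cm, "D0", threshold=0.0)
        assert out["A"] == {"g0", "g1"}


class TestBuildLinks:
    def test_two_types_both_genes_four_links(self):
        """Both types express both genes of one pair: 4 links incl. autocrine."""
        expressed = {"A": {"L1", "R1"}, "B": {"L1", "R1"}}
        links = build_links(expressed, _lrdb([("L1", "R1")]), "D0")
        got = set(
            map(tuple, links.links[["sender_type", "receiver_type"]].itertuples(index=False, name=None))
        )
        assert got == {("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")}

    def test_ligand_nowhere_no_links(self):
        expressed = {"A": {"R1"}, "B": {"R1"}}
        links = build_links(expressed, _lrdb([("L1", "R1")]), "D0")
        assert len(links) == 0

    def test_directed_enumeration(self):
        expressed = {"A": {"L1"}, "B": {"R1"}, "C": {"R1"}}
        links = build_links(expressed, _lrdb([("L1", "R1")]), "D0")
        got = set(
            map(tuple, links.links[["sender_type", "receiver_type"]].itertuples(index=False, name=None))
        )
        assert got == {("A", "B"), ("A", "C")}

    def test_unmeasured_pair_counted_in_coverage(self):
        expressed = {"A": {"L1", "R1"}}
        links = build_links(
            expressed, _lrdb([("L1", "R1"), ("Lx", "Rx")]), "D0",
            gene_universe={"L1", "R1"},
        )
        assert links.coverage["n_pairs_measurable"] == 1


class TestNetwork:
    def _four_link_net(self):
        expressed = {"A": {"L1", "R1"}, "B": {"L1", "R1"}}
        return network_from_links(build_links(expressed, _lrdb([("L1", "R1")]), "D0"))

    def test_empty_links_zero_network(self):
        links = build_links({"A": set()}, _lrdb([("L1", "R1")]), "D0")
        net = network_from_links(links, nodes=["A"])
        assert net.total_links() == 0

    def test_weights_from_four_link_example(self):
        net = self._four_link_net()
        assert net.weight("A", "A") == 1
        assert net.weight("A", "B") == 1
        assert net.weight("B", "A") == 1
        assert net.weight("B", "B") == 1
        assert net.total_links() == 4

    def test_delta_self_is_zero_and_antisymmetric(self):
        net = self._four_link_net()
        assert delta_network(net, net) == {}
        expressed = {"A": {"L1", "R1"}, "B": {"R1"}}
        net2 = network_from_links(build_links(expressed, _lrdb([("L1", "R1")]), "D3"))
        d12 = delta_network(net, net2)
        d21 = delta_network(net2, net)
        assert d12 == {k: -v for k, v in d21.items()}

    def test_communication_strength(self):
        net = self._four_link_net()
        s = communication_strength(net, "A")
        assert s == {"out_links": 2, "in_links": 2, "total": 4}
        total_out = sum(communication_strength(net, t)["out_links"] for t in net.nodes)
        assert total_out == net.total_links()
        with pytest.raises(KeyError):
            communication_strength(net, "Z")

    def test_isolated_type(self):
        net = network_from_links(
            build_links({"A": {"L1", "R1"}, "B": set()}, _lrdb([("L1", "R1")]), "D0"),
            nodes=["A", "B"],
        )
        assert communication_strength(net, "B") == {"out_links": 0, "in_links": 0, "total": 0}

    def test_networkx_export(self):
        g = self._four_link_net().to_networkx()
        assert g.number_of_edges() == 4
        assert g["A"]["B"]["weight"] == 1


class TestLigandReceptorLists:
    def test_no_lr_genes_empty(self):
        out = ligand_and_receptor_lists({"A": {"g1"}}, _lrdb([("L1", "R1")]), "A")
        assert out == {"expressed_ligands": set(), "expressed_receptors": set()}

    def test_dual_role_gene_in_both_lists(self):
        db = _lrdb([("G1", "R1"), ("L2", "G1")])
        out = ligand_and_receptor_lists({"A": {"G1"}}, db, "A")
        assert out["expressed_ligands"] == {"G1"}
        assert out["expressed_receptors"] == {"G1"}


class TestOracleEquivalence:
    def _random_instance(self, rng):
        n_types = rng.integers(2, 6)
        n_genes = rng.integers(5, 31)
        n_pairs = min(int(rng.integers(1, 51)), int(n_genes) * int(n_genes) // 2)
        genes = [f"g{i}" for i in range(n_genes)]
        types = [f"T{i}" for i in range(n_types)]
        cells_per_type = rng.integers(3, 12)
        counts = (rng.random((n_types * cells_per_type, n_genes)) < 0.3).astype(int)
        cell_types = np.repeat(types, cells_per_type)
        pairs = set()
        while len(pairs) < n_pairs:
            pairs.add((genes[rng.integers(n_genes)], genes[rng.integers(n_genes)]))
        return counts, cell_types, genes, sorted(pairs)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            counts, cell_types, genes, pairs = self._random_instance(rng)
            cm = make_count_matrix(counts, cell_types=list(cell_types), gene_names=genes)
            expressed = expressed_genes_by_type(cm, "D0", 0.20)
            net = network_from_links(
                build_links(expressed, _lrdb(pairs), "D0"), nodes=sorted(set(cell_types))
            )
            expected = brute_force_network(counts, cell_types, genes, pairs, 0.20)
            got = {k: v for k, v in net.weights.items() if v}
            assert got == expected

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        counts, cell_types, genes, pairs = self._random_instance(rng)
        cm = make_count_matrix(counts, cell_types=list(cell_types), gene_names=genes)
        prev_total = None
        for thr in (0.0, 0.1, 0.2, 0.4, 0.8):
            expressed = expressed_genes_by_type(cm, "D0", thr)
            net = network_from_links(build_links(expressed, _lrdb(pairs), "D0"))
            if prev_total is not None:
                assert net.total_links() <= prev_total
            prev_total = net.total_links()

    def test_ligand_knockout_never_increases_outdegree(self):
        rng = np.random.default_rng(11)
        counts, cell_types, genes, pairs = self._random_instance(rng)
        cm = make_count_matrix(counts, cell_types=list(cell_types), gene_names=genes)
        db = _lrdb(pairs)
        expressed = expressed_genes_by_type(cm, "D0", 0.2)
        net = network_from_links(build_links(expressed, db, "D0"))
        ko_gene = pairs[0][0]
        counts_ko = counts.copy()
        counts_ko[:, genes.index(ko_gene)] = 0
        cm_ko = make_count_matrix(counts_ko, cell_types=list(cell_types), gene_names=genes)
        net_ko = network_from_links(
            build_links(expressed_genes_by_type(cm_ko, "D0", 0.2), db, "D0")
        )
        for t in net.nodes:
            before = communication_strength(net, t)["out_links"]
            after = communication_strength(net_ko, t)["out_links"] if t in net_ko.nodes else 0
            assert after <= before


def test_planted_channel_recovery(lognormed_timecourse):
    """Active channels produce links; inactive channels essentially never do."""
    cm, truth = lognormed_timecourse
    db = LRDatabase(
        pd.DataFrame(
            {"ligand": ["Gene00001", "Gene00003"], "receptor": ["Gene00002", "Gene00004"]}
        )
    )
    active = set(
        map(tuple, truth.active_channels[
            ["ligand", "receptor", "sender", "receiver", "timepoint"]
        ].itertuples(index=False, name=None))
    )
    observed = set()
    for tp in ("D0", "D3", "D6"):
        expressed = expressed_genes_by_type(cm, tp, 0.20)
        for row in build_links(expressed, db, tp).links.itertuples(index=False):
            observed.add((row.ligand, row.receptor, row.sender_type, row.receiver_type, row.timepoint))
    assert active <= observed  # full sensitivity on this fixture
    false_links = {o for o in observed if o not in active}
    types = sorted({t for tp in ("D0", "D3", "D6") for t in expressed_genes_by_type(cm, tp, 0.2)})
    n_candidates = len(db.pairs) * len(types) ** 2 * 3 - len(active)
    assert len(false_links) / n_candidates <= 0.05
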