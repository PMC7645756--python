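"""differential_expression: rank-sum test, logFC, DE cascade, conserved markers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scbmm.differential_expression import (
    DETable,
    conserved_markers,
    count_de_by_direction,
    de_by_timepoint,
    log_fold_change,
    wilcoxon_rank_sum,
)

from conftest import make_count_matrix
from oracles import exact_rank_sum_p


class TestWilcoxon:
    def test_separated_groups_exact_p(self):
        """x={1,2,3} vs y={4,5,6}: the most extreme of C(6,3)=20 splits, p=0.1."""
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_symmetric(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n1*n2/2
        assert p == 1.0

    def test_all_values_tied_p_one(self):
        _, p = wilcoxon_rank_sum([2.0] * 8, [2.0] * 10)
        assert p == 1.0
        _, p = wilcoxon_rank_sum([2.0] * 20, [2.0] * 20, force_approx=True)
        assert p == 1.0

    @settings(max_examples=60, deadline=None)
    @given(
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_small_sample_p_matches_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=n1).astype(float)
        y = rng.integers(0, 4, size=n2).astype(float)
        u, p = wilcoxon_rank_sum(x, y)
        u_o, p_o = exact_rank_sum_p(x, y)
        assert u == pytest.approx(u_o)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_approx_close_to_exact_at_moderate_n(self):
        """Normal approximation within 0.02 of the exact p at 20 vs 20."""
        rng = np.random.default_rng(42)
        from scbmm.differential_expression import _exact_p, _rank_sum_u

        for _ in range(50):
            x = np.round(rng.normal(0, 1, 20), 1)
            y = np.round(rng.normal(0.4, 1, 20), 1)
            u, p_approx = wilcoxon_rank_sum(x, y, force_approx=True)
            _, ranks = _rank_sum_u(x, y)
            p_exact = _exact_p(ranks, 20, u)
            assert abs(p_approx - p_exact) <= 0.02


class TestLogFoldChange:
    def test_identical_groups_zero(self):
        v = np.log1p([1.0, 2.0, 3.0])
        assert log_fold_change(v, v) == 0.0

    def test_closed_form(self):
        """Linear means 3 vs 1 give ln(4) - ln(2) = ln 2."""
        g1 = np.log1p([3.0, 3.0])
        g2 = np.log1p([1.0, 1.0])
        assert log_fold_change(g1, g2) == pytest.approx(np.log(2))

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.exponential(1, 10), rng.exponential(2, 12)
        assert log_fold_change(np.log1p(a), np.log1p(b)) == pytest.approx(
            -log_fold_change(np.log1p(b), np.log1p(a))
        )

    def test_shared_offset_shrinks_toward_zero(self):
        """Adding a constant in linear space to both groups moves logFC to 0."""
        g1, g2 = np.log1p([4.0] * 5), np.log1p([1.0] * 5)
        base = log_fold_change(g1, g2)
        shifted = log_fold_change(np.log1p([14.0] * 5), np.log1p([11.0] * 5))
        assert 0 < shifted < base


def _two_timepoint_matrix(n1=20, n2=20, n_genes=30, seed=0, planted=None):
    """Type 'T' at D0/D3 with optionally planted fold changes on gene 0."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(2.0, size=(n1 + n2, n_genes))
    if planted:
        counts[:n2, 0] = rng.poisson(planted, size=n2)
    tps = ["D3"] * n2 + ["D0"] * n1 if False else ["D0"] * n1 + ["D3"] * n2
    cm = make_count_matrix(counts, timepoints=tps, cell_types=["T"] * (n1 + n2))
    from scbmm.core_io import lognormalize

    lognormalize(cm)
    return cm


class TestDeByTimepoint:
    def test_small_group_skipped_with_reason(self):
        cm = _two_timepoint_matrix(n1=4, n2=200)
        de = de_by_timepoint(cm, "T", "D3", min_cells=5)
        assert de.reason == "min_cells"
        assert de.table.empty

    def test_low_pct_gene_excluded_before_testing(self):
        """A gene at 8% expressed in both groups is never tested."""
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(100, 5))
        rare = np.zeros(100, dtype=int)
        rare[rng.choice(50, 4, replace=False)] = 5  # 8% of D0 cells
        rare[50 + rng.choice(50, 4, replace=False)] = 50  # 8% of D3, big fold
        counts[:, 0] = rare
        cm = make_count_matrix(
            counts, timepoints=["D0"] * 50 + ["D3"] * 50, cell_types=["T"] * 100
        )
        from scbmm.core_io import lognormalize

        lognormalize(cm)
        de = de_by_timepoint(cm, "T", "D3", min_pct=0.10)
        assert "g0" not in set(de.table["gene"])

    def test_bonferroni_multiplier_is_all_genes(self):
        cm = _two_timepoint_matrix(n_genes=30)
        de = de_by_timepoint(cm, "T", "D3")
        assert de.meta["bonferroni_m"] == 30
        if len(de.table):
            assert (de.table["p_adj"] >= de.table["p_raw"] - 1e-15).all()
            assert np.allclose(
                de.table["p_adj"], np.minimum(1.0, de.table["p_raw"] * 30)
            )

    def test_retained_rows_satisfy_fold_filter(self):
        cm = _two_timepoint_matrix(planted=8.0, seed=2)
        de = de_by_timepoint(cm, "T", "D3")
        assert (de.table["logFC"].abs() >= np.log(1.5) - 1e-12).all()

    def test_unknown_type_or_timepoint_rejected(self):
        cm = _two_timepoint_matrix()
        with pytest.raises(KeyError):
            de_by_timepoint(cm, "nope", "D3")
        with pytest.raises(KeyError):
            de_by_timepoint(cm, "T", "D99")

    def test_planted_recovery(self, lognormed_timecourse):
        """Planted ln2 DE genes in type A at D3 are mostly recovered."""
        cm, truth = lognormed_timecourse
        de = de_by_timepoint(cm, "A", "D3")
        sig = set(de.significant_rows()["gene"])
        planted = set(truth.de_truth["gene"])
        assert len(sig & planted) / len(planted) >= 0.7  # small-n fixture; full
        # power is exercised at 300 cells/group in the acceptance suite


class TestCountByDirection:
    def test_empty(self):
        assert count_de_by_direction(DETable.empty("x")) == {"n_over": 0, "n_under": 0}

    def test_counting_contract(self):
        """A constructed table with 64 over / 38 under rows counts as (64, 38)."""
        rows = [
            {"gene": f"u{i}", "direction": "over", "significant": True} for i in range(64)
        ] + [
            {"gene": f"d{i}", "direction": "under", "significant": True} for i in range(38)
        ] + [
            {"gene": "ns", "direction": "over", "significant": False}
        ]
        table = DETable(pd.DataFrame(rows))
        assert count_de_by_direction(table) == {"n_over": 64, "n_under": 38}

    def test_all_under(self):
        rows = [{"gene": f"d{i}", "direction": "under", "significant": True} for i in range(5)]
        assert count_de_by_direction(DETable(pd.DataFrame(rows))) == {
            "n_over": 0,
            "n_under": 5,
        }


class TestConservedMarkers:
    def _three_cluster_matrix(self, marker_frac_in=0.9, marker_frac_out=0.1, fold=6.0):
        rng = np.random.default_rng(5)
        n_per, n_genes = 40, 20
        counts = rng.poisson(1.5, size=(3 * n_per, n_genes))
        marker = np.zeros(3 * n_per, dtype=int)
        in_cells = rng.random(n_per) < marker_frac_in
        marker[:n_per][in_cells] = rng.poisson(fold, in_cells.sum()) + 1
        for k in (1, 2):
            out_cells = rng.random(n_per) < marker_frac_out
            marker[k * n_per : (k + 1) * n_per][out_cells] = 1
        counts[:, 0] = marker
        cm = make_count_matrix(
            counts,
            timepoints=["D0"] * (3 * n_per),
            cell_types=["A"] * n_per + ["B"] * n_per + ["C"] * n_per,
        )
        from scbmm.core_io import lognormalize

        return lognormalize(cm)

    def test_strong_marker_retained(self):
        cm = self._three_cluster_matrix()
        table = conserved_markers(cm, "A", exclude_timepoints=())
        assert "g0" in set(table.table["gene"])
        row = table.table.set_index("gene").loc["g0"]
        assert row["min_logFC"] >= np.log(2)
        assert row["pct_in"] >= 0.75

    def test_weak_pct_marker_excluded(self):
        cm = self._three_cluster_matrix(marker_frac_in=0.6)
        table = conserved_markers(cm, "A", exclude_timepoints=())
        assert "g0" not in set(table.table["gene"])

    def test_excluded_timepoint_ignored(self):
        """A marker only present at D12 does not qualify when D12 is excluded."""
        rng = np.random.default_rng(8)
        n = 30
        counts = rng.poisson(1.0, size=(4 * n, 6))
        # gene 0: marker for A only among D12 cells
        counts[:, 0] = 0
        d12_a = np.arange(2 * n, 3 * n)  # A cells at D12
        counts[d12_a, 0] = 10
        cm = make_count_matrix(
            counts,
            timepoints=["D0"] * n + ["D0"] * n + ["D12"] * n + ["D12"] * n,
            cell_types=["A"] * n + ["B"] * n + ["A"] * n + ["B"] * n,
        )
        from scbmm.core_io import lognormalize

        lognormalize(cm)
        table = conserved_markers(cm, "A", exclude_timepoints=("D12",))
        assert "g0" not in set(table.table["gene"])

    def test_small_cluster_skipped(self):
        cm = self._three_cluster_matrix()
        sub = cm.subset(cells=np.r_[np.arange(3), np.arange(40, 120)])
        table = conserved_markers(sub, "A", exclude_timepoints=())
        assert table.reason == "min_cells"

    def test_planted_marker_recovery(self, lognormed_timecourse):
        """Planted per-type markers recovered with precision and recall >= 0.9."""
        cm, truth = lognormed_timecourse
        found = set(
            conserved_markers(cm, "A", exclude_timepoints=()).table["gene"]
        )
        planted = set(truth.markers["A"]) & set(cm.gene_ids)
        recall = len(found & planted) / len(planted)
        precision = len(found & planted) / max(len(found), 1)
        assert recall >= 0.9
        assert precision >= 0.9
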