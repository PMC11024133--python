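import itertools
import logging

import numpy as np
import pytest

from spade.model import SingleCellDataset
from spade.reference import (
    build_signature,
    filter_cells_genes,
    find_marker_genes,
    scale_by_library_size,
    wilcoxon_rank_sum,
)


def exact_rank_sum_p(x, y):
    """Brute-force two-sided p: enumerate every assignment of the pooled
    values to the two groups and count U statistics as extreme as observed."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    us = [
        u_stat([pooled[i] for i in comb],
               [pooled[i] for i in range(len(pooled)) if i not in set(comb)])
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    total = len(us)
    mid = n1 * (len(y))
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_separated_groups_exact(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_tied_groups(self):
        _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    def test_empty_sample_fatal(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_mode_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6, size=2)
        vals = rng.permutation(20)[: n1 + n2].astype(float)  # no ties
        x, y = vals[:n1], vals[n1:]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)


class TestFiltersAndScaling:
    def test_zero_count_gene_removed(self, tiny_sc):
        sc = tiny_sc
        sc.counts[1, :] = 0
        out = filter_cells_genes(sc)
        assert out.gene_ids == ["gA", "gC"]

    def test_keep_types_drops_cells(self, tiny_sc):
        out = filter_cells_genes(tiny_sc, keep_types={"A"})
        assert set(out.cell_type) == {"A"}

    def test_no_op_is_identity(self, tiny_sc):
        out = filter_cells_genes(tiny_sc)
        assert out.gene_ids == tiny_sc.gene_ids
        assert np.array_equal(out.counts, tiny_sc.counts)

    def test_library_size_scaling(self):
        sc = SingleCellDataset(
            gene_ids=["g1", "g2"], cell_ids=["c1"], counts=np.array([[3], [1]]),
            cell_type=["A"], sample_id=["s"],
        )
        out = scale_by_library_size(sc)
        assert np.allclose(out.counts[:, 0], [0.75, 0.25])

    def test_columns_sum_to_one(self, tiny_sc):
        out = scale_by_library_size(tiny_sc)
        assert np.allclose(out.counts.sum(axis=0), 1.0)

    def test_zero_total_cell_dropped(self, tiny_sc, caplog):
        tiny_sc.counts[:, 2] = 0
        with caplog.at_level(logging.WARNING, logger="spade"):
            out = scale_by_library_size(tiny_sc)
        assert out.n_cells == 3 and "1 zero-total" in caplog.text


def _marker_dataset(n_per_type=6):
    """Two types with equal library sizes; gMarkA/gMarkB exclusive to one
    type each, gFlat and gNoise identical across cells (so they stay flat
    after library-size scaling)."""
    n = 2 * n_per_type
    a = np.r_[np.full(n_per_type, 20.0), np.zeros(n_per_type)]
    counts = np.vstack([a, a[::-1], np.full(n, 10.0), np.full(n, 15.0)])
    return SingleCellDataset(
        gene_ids=["gMarkA", "gMarkB", "gFlat", "gNoise"],
        cell_ids=[f"c{i}" for i in range(n)],
        counts=counts,
        cell_type=["A"] * n_per_type + ["B"] * n_per_type,
        sample_id=["s"] * n,
    )


class TestMarkers:
    def test_exclusive_gene_called_for_its_type_only(self):
        sc = scale_by_library_size(_marker_dataset())
        res = find_marker_genes(sc, min_lfc=0.25, max_adj_p=0.05)
        called = {(r.gene_id, r.cell_type) for r in res}
        assert ("gMarkA", "A") in called
        assert ("gMarkA", "B") not in called
        assert not any(g == "gFlat" for g, _ in called)

    def test_adjusted_p_is_benjamini_hochberg(self):
        sc = scale_by_library_size(_marker_dataset(n_per_type=8))
        res = find_marker_genes(sc, min_lfc=-1e9, max_adj_p=1.0)
        by_type = {}
        for r in res:
            by_type.setdefault(r.cell_type, []).append(r)
        for rows in by_type.values():
            # recompute BH by the step-up formula over this type's p-values
            ps = np.array([r.p_value for r in rows])
            order = np.argsort(ps)
            m = len(ps)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                i = order[rank]
                running = min(running, ps[i] * m / (rank + 1))
                adj[i] = running
            for r, a in zip(rows, adj):
                assert r.adjusted_p == pytest.approx(a, rel=1e-9)
                assert r.adjusted_p >= r.p_value - 1e-12

    def test_small_type_excluded_with_warning(self, caplog):
        sc = _marker_dataset()
        sc.cell_type = ["A"] * 6 + ["B"] * 4 + ["C"] * 2
        sc = scale_by_library_size(sc)
        with caplog.at_level(logging.WARNING, logger="spade"):
            find_marker_genes(sc)
        assert "'C'" in caplog.text

    def test_relabeling_types_permutes_results(self):
        sc = scale_by_library_size(_marker_dataset())
        res1 = find_marker_genes(sc, min_lfc=0.0, max_adj_p=1.0)
        swapped = SingleCellDataset(
            gene_ids=sc.gene_ids,
            cell_ids=sc.cell_ids,
            counts=sc.counts,
            cell_type=["B" if t == "A" else "A" for t in sc.cell_type],
            sample_id=sc.sample_id,
        )
        res2 = find_marker_genes(swapped, min_lfc=0.0, max_adj_p=1.0)
        key1 = {(r.gene_id, r.cell_type): r.p_value for r in res1}
        key2 = {(r.gene_id, "B" if r.cell_type == "A" else "A"): r.p_value
                for r in res2}
        assert key1 == key2


class TestSignature:
    def test_columns_are_per_type_means(self, tiny_sc):
        sc = scale_by_library_size(tiny_sc)
        sig = build_signature(sc, spatial_genes=set(sc.gene_ids))
        labels = np.asarray(sc.cell_type)
        for j, t in enumerate(sig.cell_types):
            expected = np.stack(
                [sc.counts[:, i] for i in np.flatnonzero(labels == t)]
            ).mean(axis=0)
            assert np.allclose(sig.values[:, j], expected)

    def test_disjoint_types_give_block_structure(self, tiny_sc):
        sc = scale_by_library_size(tiny_sc)
        sig = build_signature(sc, spatial_genes=set(sc.gene_ids))
        a = sig.cell_types.index("A")
        b = sig.cell_types.index("B")
        gc = sig.gene_ids.index("gC")
        assert sig.values[gc, a] == 0 and sig.values[gc, b] > 0

    def test_marker_absent_from_spatial_excluded(self, tiny_sc):
        sc = scale_by_library_size(tiny_sc)
        sig = build_signature(
            sc, spatial_genes={"gA", "gB"}, user_markers={"gC"}
        )
        assert "gC" not in sig.gene_ids

    def test_single_cell_per_type_column_equals_cell(self):
        sc = SingleCellDataset(
            gene_ids=["g1", "g2"], cell_ids=["c1", "c2"],
            counts=np.array([[4, 0], [0, 2]]),
            cell_type=["A", "B"], sample_id=["s", "s"],
        )
        sc = scale_by_library_size(sc)
        sig = build_signature(sc, spatial_genes={"g1", "g2"})
        assert np.allclose(sig.values, [[1, 0], [0, 1]])

    def test_too_few_feature_genes_fatal(self, tiny_sc):
        sc = scale_by_library_size(tiny_sc)
        with pytest.raises(ValueError, match="feature genes"):
            build_signature(sc, spatial_genes={"gA"})
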