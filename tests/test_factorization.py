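"""Gene filtering, NMF, and factor gene prioritization."""

import numpy as np
import pytest

from mprog.factorization import (
    FactorSet,
    _largest_component,
    elbow_rank_scan,
    filter_genes,
    normalize_log1p_cp10k,
    prioritize_factor_genes,
    run_nmf,
    zscore_loadings,
)
from mprog.synthetic import default_spec, generate_mouse_cohorts

from conftest import make_count_matrix


class TestFilterGenes:
    def test_at_least_one_percent_is_inclusive(self):
        # gene 0 nonzero in exactly 1 of 100 cells -> kept at min_frac 0.01
        counts = np.zeros((2, 100), dtype=int)
        counts[0, 0] = 5
        counts[1, :] = 1
        cm = filter_genes(make_count_matrix(counts), 0.01)
        assert cm.gene_ids == ["g0", "g1"]

    def test_all_zero_gene_removed(self):
        counts = np.array([[0, 0, 0], [1, 2, 3]])
        cm = filter_genes(make_count_matrix(counts), 0.01)
        assert cm.gene_ids == ["g1"]

    def test_zero_threshold_keeps_everything(self):
        counts = np.array([[0, 0, 0], [1, 2, 3]])
        cm = filter_genes(make_count_matrix(counts), 0.0)
        assert cm.gene_ids == ["g0", "g1"]

    def test_no_survivors_is_error(self):
        counts = np.array([[0, 0], [0, 0], [1, 0]])
        with pytest.raises(ValueError, match="filter"):
            filter_genes(make_count_matrix(counts), 0.9)


class TestRunNmf:
    def test_rank_one_input_reconstructed_exactly(self):
        # identical cells -> normalized matrix has rank 1
        col = np.array([5, 3, 0, 2, 7, 1])
        counts = np.tile(col[:, None], (1, 30))
        cm = make_count_matrix(counts)
        fs = run_nmf(cm, "A", n_factors=1, seed=0)
        x = np.asarray(normalize_log1p_cp10k(cm).todense())
        rel = fs.reconstruction_err / np.linalg.norm(x)
        assert rel <= 1e-6

    def test_same_seed_identical_loadings(self, small_mouse):
        cm, _ = small_mouse
        a = run_nmf(cm, "A", n_factors=5, seed=42)
        b = run_nmf(cm, "A", n_factors=5, seed=42)
        assert np.array_equal(a.loadings, b.loadings)

    def test_block_structure_recovered(self):
        """Two disjoint gene blocks expressed by disjoint cell groups: each
        factor's top genes coincide with one block."""
        rng = np.random.default_rng(1)
        counts = np.zeros((20, 40), dtype=int)
        counts[:10, :20] = rng.poisson(20, size=(10, 20))
        counts[10:, 20:] = rng.poisson(20, size=(10, 20))
        counts += rng.poisson(0.2, size=counts.shape)  # noise floor
        cm = make_count_matrix(counts)
        fs = run_nmf(cm, "A", n_factors=2, seed=0)
        blocks = [set(range(10)), set(range(10, 20))]
        for j in range(2):
            top = set(np.argsort(-fs.loadings[:, j])[:10])
            assert top in blocks
        # the two factors cover different blocks
        tops = [frozenset(np.argsort(-fs.loadings[:, j])[:10]) for j in range(2)]
        assert tops[0] != tops[1]

    def test_too_many_factors_rejected(self):
        cm = make_count_matrix(np.ones((3, 4), dtype=int))
        with pytest.raises(ValueError, match="n_factors"):
            run_nmf(cm, "A", n_factors=10, seed=0)


class TestElbowScan:
    def test_error_non_increasing(self, small_mouse):
        cm, _ = small_mouse
        sub = cm.subset_cells(cm.cohort == "A")
        errs = elbow_rank_scan(sub, [1, 2, 4], seed=0)
        vals = [errs[r] for r in [1, 2, 4]]
        assert vals[0] >= vals[1] - 1e-8 and vals[1] >= vals[2] - 1e-8

    def test_planted_programs_set_the_elbow(self):
        """With 5 planted programs the largest error drop happens at rank <= 5."""
        spec = default_spec(seed=3, n_genes=300, n_cells_per_cohort=120)
        cm, _ = generate_mouse_cohorts(spec)
        sub = cm.subset_cells(cm.cohort == "A")
        ranks = list(range(1, 9))
        errs = elbow_rank_scan(sub, ranks, seed=0)
        drops = {r2: errs[r1] - errs[r2] for r1, r2 in zip(ranks, ranks[1:])}
        assert max(drops, key=drops.get) <= 5

    def test_single_rank(self, small_mouse):
        cm, _ = small_mouse
        sub = cm.subset_cells(cm.cohort == "A")
        errs = elbow_rank_scan(sub, [3], seed=0)
        assert set(errs) == {3}

    def test_unsorted_ranks_rejected(self, small_mouse):
        cm, _ = small_mouse
        with pytest.raises(ValueError, match="sorted"):
            elbow_rank_scan(cm, [4, 2])


class TestZscoreLoadings:
    def test_mean_zero_sd_one_per_gene(self):
        rng = np.random.default_rng(0)
        z = zscore_loadings(rng.random((10, 6)))
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_gene_gets_zero(self):
        load = np.vstack([np.full(5, 3.0), np.arange(5.0)])
        z = zscore_loadings(load)
        assert np.all(z[0] == 0)


def _union_find_components(n, edges):
    """Independent oracle: connected components by union-find."""
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _oracle_largest(adj, loading, genes):
    n = adj.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]
    comps = _union_find_components(n, edges)
    best = None
    for comp in comps:
        key = (len(comp), float(loading[comp].sum()))
        names = tuple(sorted(genes[m] for m in comp))
        if best is None or key > best[0] or (key == best[0] and names < best[1]):
            best = (key, names, sorted(comp))
    return best[2]


class TestLargestComponent:
    def test_matches_union_find_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 51))
            adj = (rng.random((n, n)) < 0.08).astype(np.int8)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            loading = rng.random(n)
            genes = [f"g{i:02d}" for i in range(n)]
            got = sorted(_largest_component(adj, loading, genes))
            assert got == _oracle_largest(adj, loading, genes)

    def test_component_tie_broken_by_summed_loading(self):
        # components {0,1} and {2,3}; loadings favor {2,3}
        adj = np.zeros((4, 4), dtype=np.int8)
        adj[0, 1] = adj[1, 0] = 1
        adj[2, 3] = adj[3, 2] = 1
        loading = np.array([0.1, 0.1, 5.0, 5.0])
        got = _largest_component(adj, loading, ["A", "B", "C", "D"])
        assert sorted(got) == [2, 3]


def _factor_set(loadings, gene_ids, cell_ids, cohort="A"):
    return FactorSet(
        cohort=cohort,
        loadings=np.asarray(loadings, dtype=float),
        cell_weights=np.zeros((np.asarray(loadings).shape[1], len(cell_ids))),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        seed=0,
        reconstruction_err=0.0,
    )


class TestPrioritizeFactorGenes:
    def _expr_with_blocks(self, rng, n_cells=60):
        """Genes A,B co-vary; C,D co-vary; E independent; plus filler genes."""
        base1 = rng.poisson(10, n_cells)
        base2 = rng.poisson(10, n_cells)
        rows = [
            base1 + rng.poisson(1, n_cells),  # A
            base1 + rng.poisson(1, n_cells),  # B
            base2 + rng.poisson(1, n_cells),  # C
            base2 + rng.poisson(1, n_cells),  # D
            rng.poisson(10, n_cells),  # E
            rng.poisson(5, n_cells),  # filler f0
            rng.poisson(5, n_cells),  # filler f1
        ]
        return np.vstack(rows)

    def test_largest_coexpression_component_wins(self):
        rng = np.random.default_rng(5)
        counts = self._expr_with_blocks(rng)
        genes = ["A", "B", "C", "D", "E", "f0", "f1"]
        cm = make_count_matrix(counts, gene_ids=genes)
        # factor 0 loads high on A..E; factor 1 on fillers (keeps z finite)
        loadings = np.array(
            [
                [9.0, 0.1],
                [9.0, 0.1],
                [9.5, 0.1],
                [9.6, 0.1],
                [9.0, 0.1],
                [0.1, 9.0],
                [0.1, 9.0],
            ]
        )
        fs = _factor_set(loadings, genes, cm.cell_ids)
        fs = prioritize_factor_genes(fs, cm, z_thr=0.5, corr_thr=0.4, min_genes=2)
        # A-B and C-D form size-2 components; C-D has larger summed loading
        assert sorted(fs.prioritized_genes[0]) == ["C", "D"]
        assert fs.retained[0]

    def test_fully_correlated_candidates_all_kept(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(20, 50)
        counts = np.vstack([base + rng.poisson(1, 50) for _ in range(4)]
                           + [rng.poisson(5, 50) for _ in range(2)])
        genes = ["A", "B", "C", "D", "f0", "f1"]
        cm = make_count_matrix(counts, gene_ids=genes)
        loadings = np.array(
            [[9.0, 0.1]] * 4 + [[0.1, 9.0]] * 2
        )
        fs = _factor_set(loadings, genes, cm.cell_ids)
        fs = prioritize_factor_genes(fs, cm, z_thr=0.5, corr_thr=0.4, min_genes=2)
        assert sorted(fs.prioritized_genes[0]) == ["A", "B", "C", "D"]

    def test_min_genes_discards_small_factors(self):
        rng = np.random.default_rng(5)
        counts = self._expr_with_blocks(rng)
        genes = ["A", "B", "C", "D", "E", "f0", "f1"]
        cm = make_count_matrix(counts, gene_ids=genes)
        loadings = np.array(
            [[9.0, 0.1]] * 5 + [[0.1, 9.0]] * 2
        )
        fs = _factor_set(loadings, genes, cm.cell_ids)
        fs = prioritize_factor_genes(fs, cm, z_thr=0.5, corr_thr=0.4, min_genes=10)
        assert not fs.retained.any()

    def test_planted_program_recovered_with_high_jaccard(self, small_mouse):
        """On planted synthetic data, at least one retained factor per strong
        program overlaps its gene set at Jaccard >= 0.5."""
        cm, truth = small_mouse
        fs = run_nmf(cm, "A", n_factors=8, seed=1)
        fs = prioritize_factor_genes(fs, cm, z_thr=1.5, corr_thr=0.4, min_genes=10)
        planted = set(truth.programs["P1"])  # A-exclusive program
        best = 0.0
        for j in fs.retained_indices():
            s = set(fs.prioritized_genes[j])
            best = max(best, len(s & planted) / len(s | planted))
        assert best >= 0.5
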