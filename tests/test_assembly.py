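"""Factor clustering, consensus gene lists and inactive-MP filtering."""

import numpy as np
import pandas as pd
import pytest

from mprog.assembly import (
    Metaprogram,
    cluster_factors,
    consensus_genes,
    drop_inactive,
    factor_activity_correlation,
)
from mprog.scoring import ActivityMatrix


def _activity(scores: np.ndarray, names=None, thresholds=None) -> ActivityMatrix:
    names = names or [f"F{i}" for i in range(scores.shape[1])]
    df = pd.DataFrame(scores, columns=names)
    thr = pd.Series(
        thresholds if thresholds is not None else np.full(len(names), 0.5),
        index=names,
    )
    return ActivityMatrix(scores=df, thresholds=thr, top_frac=0.05)


class TestFactorActivityCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        corr = factor_activity_correlation(_activity(rng.random((30, 3))))
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        col = rng.random(25)
        corr = factor_activity_correlation(
            _activity(np.column_stack([col, col, rng.random(25)]))
        )
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed_pearson_on_five_cells(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        b = np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        corr = factor_activity_correlation(_activity(np.column_stack([a, b])))
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_constant_factor_flagged_zero(self, caplog):
        rng = np.random.default_rng(2)
        scores = np.column_stack([np.full(20, 0.4), rng.random(20)])
        with caplog.at_level("WARNING"):
            corr = factor_activity_correlation(_activity(scores))
        assert corr.iloc[0, 1] == 0.0
        assert corr.iloc[0, 0] == 1.0


def _block_corr(sizes, within=0.9, between=0.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    corr = np.full((n, n), between)
    start = 0
    for s in sizes:
        corr[start : start + s, start : start + s] = within
        start += s
    if noise:
        sym = rng.normal(0, noise, (n, n))
        corr += (sym + sym.T) / 2
    np.fill_diagonal(corr, 1.0)
    names = [f"F{i}" for i in range(n)]
    return pd.DataFrame(corr, index=names, columns=names)


def _oracle_silhouette(dist, labels):
    """Hand-rolled mean silhouette on a precomputed distance matrix."""
    n = len(labels)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in same])
        b = min(
            np.mean([dist[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestClusterFactors:
    def test_two_well_separated_blocks(self):
        corr = _block_corr([4, 4])
        labels, k, _ = cluster_factors(corr)
        assert k == 2
        assert labels.iloc[:4].nunique() == 1 and labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_single_candidate_k_forced(self):
        corr = _block_corr([3, 3, 3], noise=0.02)
        _, k, _ = cluster_factors(corr, k_candidates=[2])
        assert k == 2

    def test_three_noisy_blocks_recovered(self):
        corr = _block_corr([4, 4, 4], within=0.85, noise=0.05, seed=3)
        labels, k, _ = cluster_factors(corr)
        assert k == 3

    def test_silhouette_argmax_matches_independent_evaluation(self):
        corr = _block_corr([4, 3, 5], within=0.8, noise=0.08, seed=5)
        ks = [2, 3, 4, 5]
        labels, chosen, sils = cluster_factors(corr, k_candidates=ks)
        # recompute silhouettes with a hand-rolled oracle on the same tree cuts
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        dist = 1 - corr.values
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform((dist + dist.T) / 2, checks=False), method="average")
        oracle = {
            kk: _oracle_silhouette(dist, fcluster(Z, t=kk, criterion="maxclust"))
            for kk in ks
        }
        for kk in ks:
            assert sils[kk] == pytest.approx(oracle[kk], abs=1e-10)
        assert chosen == max(oracle, key=lambda kk: (oracle[kk], -kk))

    def test_all_equal_correlations_is_error(self):
        corr = _block_corr([6], within=0.5)
        np.fill_diagonal(corr.values, 1.0)
        with pytest.raises(ValueError, match="silhouette"):
            cluster_factors(corr)

    def test_too_few_factors_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            cluster_factors(_block_corr([2]))


class TestConsensusGenes:
    def test_one_of_four_lists_meets_quarter_threshold(self):
        lists = [["A", "B"], ["B"], ["B", "C"], ["B"]]
        out = consensus_genes(lists, 0.25)
        assert "A" in out and "C" in out  # ceil(0.25*4)=1

    def test_one_of_five_lists_fails_quarter_threshold(self):
        lists = [["A", "B"], ["B"], ["B"], ["B"], ["B"]]
        out = consensus_genes(lists, 0.25)
        assert out == ["B"]  # ceil(0.25*5)=2 > 1 occurrence of A

    def test_single_factor_consensus_is_its_genes(self):
        assert sorted(consensus_genes([["X", "Y"]], 0.25)) == ["X", "Y"]

    def test_ordered_by_count_then_gene(self):
        lists = [["B", "A"], ["A", "B"], ["C", "A"]]
        assert consensus_genes(lists, 0.25) == ["A", "B", "C"]

    def test_permutation_invariant_in_factor_order(self):
        lists = [["A", "B"], ["B", "C"], ["C", "D"], ["A", "D"]]
        a = consensus_genes(lists, 0.5)
        b = consensus_genes(list(reversed(lists)), 0.5)
        assert a == b

    def test_empty_member_list_is_error(self):
        with pytest.raises(ValueError):
            consensus_genes([], 0.25)


class TestDropInactive:
    def _mps_and_activities(self, frac_a, frac_b):
        """One MP whose active fractions per cohort are as requested."""
        n = 100
        scores = np.zeros((2 * n, 1))
        scores[: int(frac_a * n), 0] = 1.0
        scores[n : n + int(frac_b * n), 0] = 1.0
        act = _activity(scores, names=["cluster1"], thresholds=[0.5])
        cohorts = np.array(["A"] * n + ["B"] * n, dtype=object)
        mp = Metaprogram(id="cluster1", member_factors=[("A", 0)], genes=["g1"])
        return [mp], act, cohorts

    def test_active_in_one_cohort_survives_by_default(self):
        mps, act, cohorts = self._mps_and_activities(0.30, 0.02)
        assert len(drop_inactive(mps, act, cohorts, 0.10)) == 1

    def test_inactive_everywhere_discarded(self):
        mps, act, cohorts = self._mps_and_activities(0.04, 0.06)
        assert drop_inactive(mps, act, cohorts, 0.10) == []

    def test_any_mode_is_stricter(self):
        mps, act, cohorts = self._mps_and_activities(0.30, 0.02)
        assert drop_inactive(mps, act, cohorts, 0.10, mode="any") == []

    def test_zero_threshold_discards_nothing(self):
        mps, act, cohorts = self._mps_and_activities(0.0, 0.0)
        assert len(drop_inactive(mps, act, cohorts, 0.0)) == 1

    def test_survivors_relabeled_by_total_activity(self):
        n = 50
        scores = np.zeros((2 * n, 2))
        scores[: 2 * n // 2, 0] = 1.0  # program "x": active in all of A
        scores[::4, 1] = 1.0  # program "y": less active overall
        act = _activity(scores, names=["x", "y"], thresholds=[0.5, 0.5])
        cohorts = np.array(["A"] * n + ["B"] * n, dtype=object)
        mps = [
            Metaprogram(id="y", member_factors=[("A", 1)], genes=["g2"]),
            Metaprogram(id="x", member_factors=[("A", 0)], genes=["g1"]),
        ]
        out = drop_inactive(mps, act, cohorts, 0.05)
        assert [mp.id for mp in out] == ["MP1", "MP2"]
        assert out[0].genes == ["g1"]  # most-active program becomes MP1
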