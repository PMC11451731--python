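"""Pseudobulk scoring, signature correlation and log-rank survival tests."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from mprog.datamodel import GeneSetCollection
from mprog.outcome import (
    logrank_test,
    median_split_logrank,
    pseudobulk,
    signature_correlation,
    signature_score,
    signature_scores,
)

from conftest import make_count_matrix


def _pb(counts, samples, genes=None):
    cm = make_count_matrix(
        counts,
        gene_ids=genes,
        sample_id=samples,
        cohort=["h"] * len(samples),
    )
    return pseudobulk(cm)


class TestPseudobulk:
    def test_single_gene_carries_all_counts(self):
        pb = _pb(np.array([[10], [0]]), ["s1"])
        assert pb.loc["g0", "s1"] == pytest.approx(np.log2(1e6 + 0.001))

    def test_zero_count_gene_hits_pseudocount_floor(self):
        pb = _pb(np.array([[10], [0]]), ["s1"])
        assert pb.loc["g1", "s1"] == pytest.approx(np.log2(0.001))

    def test_cpm_scale_invariance_across_cell_splits(self):
        # two identical cells vs one cell with doubled counts
        a = _pb(np.array([[3, 3], [1, 1]]), ["s1", "s1"])
        b = _pb(np.array([[6], [2]]), ["s1"])
        assert np.allclose(a.values, b.values)

    def test_cpm_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, size=(50, 30))
        samples = [f"s{i % 3}" for i in range(30)]
        pb = _pb(counts, samples)
        cpm = 2.0**pb.values - 0.001
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_sample_is_error(self):
        with pytest.raises(ValueError, match="zero total"):
            _pb(np.array([[1, 0], [1, 0]]), ["s1", "s2"])


class TestSignatureScore:
    def test_single_gene_signature_is_its_zscore(self):
        pb = pd.DataFrame({"s1": [1.0], "s2": [3.0]}, index=["gA"])
        s = signature_score(pb, ["gA"])
        assert np.allclose(s.values, [-0.7071067811865475, 0.7071067811865475])

    def test_scores_center_to_zero_across_samples(self):
        rng = np.random.default_rng(1)
        pb = pd.DataFrame(
            rng.normal(size=(20, 8)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(8)],
        )
        s = signature_score(pb, [f"g{i}" for i in range(0, 20, 3)])
        assert s.mean() == pytest.approx(0.0, abs=1e-12)

    def test_absent_genes_omitted_and_empty_is_error(self):
        pb = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["gA"])
        s = signature_score(pb, ["gA", "missing"])
        assert len(s) == 2
        with pytest.raises(ValueError, match="mysig"):
            signature_score(pb, ["missing"], name="mysig")

    def test_collection_scoring_shape(self):
        rng = np.random.default_rng(2)
        pb = pd.DataFrame(
            rng.normal(size=(10, 5)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(5)],
        )
        coll = GeneSetCollection({"S1": ["g0", "g1"], "S2": ["g5"]})
        out = signature_scores(pb, coll)
        assert out.shape == (5, 2)


class TestSignatureCorrelation:
    def test_monotone_transform_gives_rho_one(self):
        a = pd.Series([0.1, 0.5, 0.2, 0.9, 0.4], index=list("abcde"))
        rho, _ = signature_correlation(a, a**3)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        rho, _ = signature_correlation(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle_n5(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(size=5), index=list("abcde"))
        b = pd.Series(rng.normal(size=5), index=list("abcde"))
        rho, p = signature_correlation(a, b)
        # oracle: enumerate all 120 rank permutations
        ra = a.rank().values
        rb = b.rank().values
        def _rho(x, y):
            return np.corrcoef(x, y)[0, 1]
        obs = _rho(ra, rb)
        count = sum(
            abs(_rho(ra, np.array(perm))) >= abs(obs) - 1e-12
            for perm in permutations(rb)
        )
        assert p == pytest.approx(count / 120)

    def test_constant_vector_gives_nan(self):
        a = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        b = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        rho, p = signature_correlation(a, b)
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_samples_rejected(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="at least 4"):
            signature_correlation(a, a)


class TestLogrank:
    def test_exchangeable_groups_give_chi2_zero(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([True, True, False, True, True, False])
        group = np.array([1, 1, 1, 0, 0, 0])
        chi2, p, _ = logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_hypergeometric_toy(self):
        """High events at t=1,2; Low at t=3,4 (all observed):
        O-E = 7/6, V = 17/36, chi2 = 49/17."""
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=bool)
        group = np.array([1, 1, 0, 0])
        chi2, p, ome = logrank_test(time, event, group)
        assert ome == pytest.approx(7 / 6)
        assert chi2 == pytest.approx(49 / 17)

    def test_matches_lifelines_oracle(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            time = np.round(rng.exponential(1.0, n), 2)  # rounding forces ties
            event = rng.random(n) < 0.7
            group = (rng.random(n) < 0.5).astype(int)
            if group.sum() in (0, n):
                continue
            chi2, p, _ = logrank_test(time, event, group)
            ref = ll_logrank(
                time[group == 1], time[group == 0], event[group == 1], event[group == 0]
            )
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_group_relabeling_preserves_chi2(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(1.0, 30)
        event = rng.random(30) < 0.6
        group = (rng.random(30) < 0.5).astype(int)
        a = logrank_test(time, event, group)[0]
        b = logrank_test(time, event, 1 - group)[0]
        assert a == pytest.approx(b)


class TestMedianSplit:
    def _survival(self, n, rng):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "time": rng.exponential(1.0, n),
                "event": rng.random(n) < 0.7,
            }
        )

    def test_median_goes_to_high_group(self):
        rng = np.random.default_rng(0)
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=[f"s{i}" for i in range(5)])
        surv = self._survival(5, rng)
        groups, _, _, _ = median_split_logrank(scores, surv)
        assert groups["s2"] == "High"  # score == median -> High
        assert (groups == "High").sum() == 3

    def test_all_equal_scores_is_degenerate(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(np.ones(6), index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="degenerate"):
            median_split_logrank(scores, self._survival(6, rng))

    def test_missing_survival_record_is_error(self):
        rng = np.random.default_rng(2)
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=["s0", "s1", "s2", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            median_split_logrank(scores, self._survival(4, rng))

    def test_null_scores_control_type_one_error(self):
        """Scores independent of survival: ~5% rejections at alpha 0.05."""
        rng = np.random.default_rng(3)
        n = 40
        rejections = 0
        reps = 400
        for _ in range(reps):
            scores = pd.Series(
                rng.normal(size=n), index=[f"s{i}" for i in range(n)]
            )
            surv = pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(n)],
                    "time": rng.exponential(1.0, n),
                    "event": rng.random(n) < 0.7,
                }
            )
            _, _, p, _ = median_split_logrank(scores, surv)
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.02 < rate < 0.08
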