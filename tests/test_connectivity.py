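import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pharmflow.connectivity import (
    SignatureLibrary,
    collapse_best,
    connectivity_analysis,
    empirical_null,
    empirical_p,
    match_genes,
    score_library,
    spearman,
    top_hits,
)
from pharmflow.synthetic import gen_signature_library

from oracles import spearman_reference


def make_library(values, perturbagens, conditions=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_sig = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if conditions is None:
        conditions = [f"c{i}" for i in range(n_sig)]
    sig_ids = [f"{p}:{c}" for p, c in zip(perturbagens, conditions)]
    return SignatureLibrary(
        values=pd.DataFrame(values, index=gene_ids, columns=sig_ids),
        signature_meta=pd.DataFrame(
            {"perturbagen_id": perturbagens, "condition": conditions}, index=sig_ids
        ),
    )


class TestMatchGenes:
    def test_identical_universes(self, rng):
        lib = make_library(rng.normal(size=(6, 2)), ["p1", "p2"])
        q = pd.Series(rng.normal(size=6), index=lib.gene_ids)
        qa, va, n = match_genes(q, lib, min_common=1)
        assert n == 6
        assert list(qa.index) == lib.gene_ids

    def test_partial_overlap_in_library_order(self, rng):
        lib = make_library(rng.normal(size=(3, 1)), ["p1"], gene_ids=["B", "C", "D"])
        q = pd.Series([1.0, 2.0, 3.0], index=["A", "B", "C"])
        qa, va, n = match_genes(q, lib, min_common=1)
        assert n == 2
        assert list(qa.index) == ["B", "C"]

    def test_disjoint_raises(self, rng):
        lib = make_library(rng.normal(size=(3, 1)), ["p1"], gene_ids=["X", "Y", "Z"])
        q = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValueError):
            match_genes(q, lib)

    def test_low_overlap_warns(self, rng):
        lib = make_library(rng.normal(size=(3, 1)), ["p1"], gene_ids=["A", "B", "C"])
        q = pd.Series(rng.normal(size=3), index=["A", "B", "C"])
        with pytest.warns(UserWarning):
            match_genes(q, lib, min_common=100)


class TestSpearman:
    def test_monotone_transform_is_one(self, rng):
        x = rng.normal(size=20)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self, rng):
        x = np.sort(rng.normal(size=15))
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_reference(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 3.0, 2.0, 4.0]
        assert spearman(x, y) == pytest.approx(spearman_reference(x, y), abs=1e-12)

    def test_constant_flagged(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3 * y + 2) == pytest.approx(base, abs=1e-12)
        assert spearman(x, y) == pytest.approx(spearman_reference(x, y), abs=1e-12)


class TestScoreLibrary:
    def test_self_column_is_one(self, rng):
        q = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        vals = np.column_stack([q.to_numpy(), rng.normal(size=30)])
        lib = make_library(vals, ["p1", "p2"], gene_ids=list(q.index))
        rho = score_library(q, lib.values)
        assert rho.iloc[0] == pytest.approx(1.0)

    def test_reversed_is_minus_one(self, rng):
        q = pd.Series(np.arange(20, dtype=float), index=[f"g{i}" for i in range(20)])
        lib = make_library(-q.to_numpy()[:, None], ["p1"], gene_ids=list(q.index))
        rho = score_library(q, lib.values)
        assert rho.iloc[0] == pytest.approx(-1.0)

    def test_null_mean_near_zero(self, rng):
        n = 100
        q = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        vals = rng.normal(size=(n, 50))
        lib = make_library(vals, [f"p{i}" for i in range(50)], gene_ids=list(q.index))
        rho = score_library(q, lib.values)
        se = 1.0 / np.sqrt(n - 1) / np.sqrt(50)
        assert abs(rho.mean()) < 3 * se


class TestCollapse:
    def test_max_per_perturbagen(self):
        rho = pd.Series([0.2, 0.46], index=["p1:c1", "p1:c2"])
        meta = pd.DataFrame(
            {"perturbagen_id": ["p1", "p1"], "condition": ["c1", "c2"]},
            index=rho.index,
        )
        best = collapse_best(rho, meta)
        assert best.loc["p1", "best_rho"] == pytest.approx(0.46)
        assert best.loc["p1", "best_condition"] == "c2"

    def test_single_condition(self):
        rho = pd.Series([0.3], index=["p1:c1"])
        meta = pd.DataFrame(
            {"perturbagen_id": ["p1"], "condition": ["c1"]}, index=rho.index
        )
        assert collapse_best(rho, meta).loc["p1", "best_rho"] == pytest.approx(0.3)

    def test_tie_breaks_lexicographically(self):
        rho = pd.Series([0.3, 0.3], index=["p1:c2", "p1:c1"])
        meta = pd.DataFrame(
            {"perturbagen_id": ["p1", "p1"], "condition": ["c2", "c1"]},
            index=rho.index,
        )
        assert collapse_best(rho, meta).loc["p1", "best_condition"] == "c1"


class TestEmpiricalNull:
    def test_pool_size(self, rng):
        n = 50
        q = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        lib = make_library(
            rng.normal(size=(n, 5)), [f"p{i}" for i in range(5)],
            gene_ids=list(q.index),
        )
        pool = empirical_null(q, lib, n_random=1, seed=0)
        assert pool.size == 5

    def test_reproducible(self, rng):
        n = 40
        q = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        lib = make_library(
            rng.normal(size=(n, 8)), [f"p{i % 4}" for i in range(8)],
            gene_ids=list(q.index),
        )
        a = empirical_null(q, lib, n_random=5, seed=7)
        b = empirical_null(q, lib, n_random=5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_matches_direct_simulation_of_max_of_k(self, rng):
        # pool mean should match an independent simulation of the best-of-k
        # Spearman statistic under the null
        n_genes, n_pert, k = 60, 20, 2
        q = pd.Series(rng.normal(size=n_genes), index=[f"g{i}" for i in range(n_genes)])
        perturbagens = [f"p{i // k}" for i in range(n_pert * k)]
        lib = make_library(
            rng.normal(size=(n_genes, n_pert * k)), perturbagens,
            conditions=[f"c{i % k}" for i in range(n_pert * k)],
            gene_ids=list(q.index),
        )
        pool = empirical_null(q, lib, n_random=50, seed=3)
        sim_rng = np.random.default_rng(99)
        sims = []
        for _ in range(2000):
            rhos = [
                spearman_reference(sim_rng.permutation(n_genes), np.arange(n_genes))
                for _ in range(k)
            ]
            sims.append(max(rhos))
        se = np.std(sims, ddof=1) / np.sqrt(pool.size)
        assert abs(pool.mean() - np.mean(sims)) < 4 * se + 3 * np.std(sims) / np.sqrt(2000)


class TestEmpiricalP:
    def test_boundary_retained(self, rng):
        pool = rng.uniform(-0.3, 0.3, size=999)
        p, retained = empirical_p(0.99, pool)
        assert p == pytest.approx(1.0 / 1000)
        assert retained

    def test_below_pool_discarded(self, rng):
        pool = rng.uniform(0.0, 0.5, size=200)
        p, retained = empirical_p(-0.9, pool)
        assert p == pytest.approx(1.0)
        assert not retained

    def test_median_is_half(self, rng):
        pool = rng.normal(size=1001)
        p, _ = empirical_p(np.median(pool), pool)
        assert p == pytest.approx(0.5, abs=2.0 / pool.size)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            empirical_p(0.5, np.array([]))


class TestTopHits:
    def _results(self, rhos, retained):
        return pd.DataFrame(
            {
                "best_rho": rhos,
                "best_condition": ["c1"] * len(rhos),
                "empirical_p": [0.001] * len(rhos),
                "retained": retained,
            },
            index=[f"p{i}" for i in range(len(rhos))],
        )

    def test_all_discarded_empty(self):
        res = self._results([0.5, 0.4], [False, False])
        assert top_hits(res, 5).empty

    def test_k_larger_than_retained(self):
        res = self._results([0.5, 0.4, 0.3], [True, True, False])
        assert len(top_hits(res, 10)) == 2

    def test_sorted_descending(self):
        res = self._results([0.3, 0.6, 0.5], [True, True, True])
        hits = top_hits(res, 2)
        assert hits["best_rho"].tolist() == [0.6, 0.5]


class TestPlantedMimics:
    def test_exact_rho_one_mimic(self, rng):
        n = 80
        q = rng.normal(size=n)
        lib, _ = gen_signature_library(3, 1, n, {"pert001": 1.0}, q, seed=2)
        rho = score_library(
            pd.Series(q, index=lib.gene_ids), lib.values
        )
        assert rho["pert001:c1"] == pytest.approx(1.0)

    def test_target_rho_calibrated_within_tolerance(self, rng):
        n = 400
        q = rng.normal(size=n)
        targets = {"pert001": 0.49, "pert002": 0.6, "pert003": -0.3}
        lib, truth = gen_signature_library(5, 1, n, targets, q, seed=8)
        rho = score_library(pd.Series(q, index=lib.gene_ids), lib.values)
        for pert, target in targets.items():
            assert rho[f"{pert}:c1"] == pytest.approx(target, abs=0.05)
        assert truth.mimic_perturbagens == targets

    def test_mimic_spec_unknown_perturbagen_rejected(self, rng):
        with pytest.raises(ValueError):
            gen_signature_library(3, 1, 50, {"nope": 0.5}, rng.normal(size=50), seed=1)

    def test_gene_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gen_signature_library(3, 1, 50, {}, rng.normal(size=49), seed=1)

    def test_small_pool_feasibility_warning(self, rng):
        # a pool too small to ever reach the retention threshold must warn
        n = 60
        q = rng.normal(size=n)
        lib, _ = gen_signature_library(5, 1, n, {}, q, seed=3)
        with pytest.warns(UserWarning, match="null pool"):
            connectivity_analysis(
                pd.Series(q, index=lib.gene_ids), lib, n_random=2,
                threshold=0.001, seed=3, min_common=1,
            )

    def test_planted_top_hits_in_order(self, rng):
        n = 300
        q = rng.normal(size=n)
        targets = {"pert001": 0.6, "pert002": 0.49, "pert003": 0.4}
        lib, _ = gen_signature_library(100, 2, n, targets, q, seed=4)
        res = connectivity_analysis(
            pd.Series(q, index=lib.gene_ids), lib, n_random=20, seed=4,
            min_common=1,
        )
        hits = top_hits(res, 3)
        assert list(hits.index) == ["pert001", "pert002", "pert003"]
        assert (hits["empirical_p"] <= 0.001).all()
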