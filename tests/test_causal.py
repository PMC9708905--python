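import numpy as np
import pandas as pd
import pytest

from pharmflow.causal import (
    InferredNetwork,
    PriorKnowledgeNetwork,
    RegulonSet,
    aggregate_solutions,
    build_ilp,
    export_network,
    read_regulons,
    read_sif,
    solve,
    tf_activity,
    write_regulons,
    write_sif,
)
from pharmflow.dose_response import fit_dose_response
from pharmflow.synthetic import gen_pkn

from oracles import exhaustive_min_objective


def stats_frame(tvals: dict) -> pd.DataFrame:
    return pd.DataFrame({"t_stat": pd.Series(tvals, dtype=float)})


class TestTfActivity:
    def test_single_target_raw_score(self):
        regs = RegulonSet()
        regs.add("TF1", "g1", 1)
        res = tf_activity(stats_frame({"g1": 2.0, "g2": 0.0}), regs,
                          n_permutations=100, seed=0)
        assert res.loc["TF1", "raw_score"] == pytest.approx(2.0)

    def test_mode_adjusted_mean(self):
        regs = RegulonSet()
        regs.add("TF1", "g1", 1)
        regs.add("TF1", "g2", -1)
        res = tf_activity(stats_frame({"g1": 2.0, "g2": -2.0}), regs,
                          n_permutations=100, seed=0)
        assert res.loc["TF1", "raw_score"] == pytest.approx(2.0)

    def test_weights_scale_contributions(self):
        regs = RegulonSet()
        regs.add("TF1", "g1", 1, weight=1.0)
        regs.add("TF1", "g2", 1, weight=0.5)
        res = tf_activity(stats_frame({"g1": 3.0, "g2": 0.0}), regs,
                          n_permutations=100, seed=0)
        assert res.loc["TF1", "raw_score"] == pytest.approx(3.0 / 1.5)

    def test_unmeasured_regulon_skipped_with_warning(self):
        regs = RegulonSet()
        regs.add("TF1", "g1", 1)
        regs.add("TF2", "nope", 1)
        with pytest.warns(UserWarning, match="TF2"):
            res = tf_activity(stats_frame({"g1": 1.0, "g2": 0.5}), regs,
                              n_permutations=100, seed=0)
        assert "TF2" not in res.index

    def test_duplicate_target_rejected(self):
        regs = RegulonSet()
        regs.add("TF1", "g1", 1)
        with pytest.raises(ValueError):
            regs.add("TF1", "g1", -1)

    def test_planted_tf_top1(self, noisy_sim):
        matrix, truth = noisy_sim
        stats = fit_dose_response(matrix, adjust_for_cell_system=True)
        _, regulons, net_truth = gen_pkn(
            12, 0.05, 2, 2, seed=21, genes=matrix.feature_ids, ground_truth=truth
        )
        res = tf_activity(stats, regulons, n_permutations=300, seed=2, top_k=1)
        top = res["z_score"].abs().idxmax()
        assert top in net_truth.active_tfs
        assert int(res.loc[top, "sign"]) == net_truth.active_tfs[top]

    def test_top_k_selection_and_tie_break(self):
        regs = RegulonSet()
        for i in range(4):
            regs.add(f"TF{i}", f"g{i}", 1)
        stats = stats_frame({f"g{i}": float(i) for i in range(4)})
        res = tf_activity(stats, regs, n_permutations=100, seed=0, top_k=2)
        assert res["selected"].sum() == 2

    def test_regulon_tsv_roundtrip(self, tmp_path):
        regs = RegulonSet()
        regs.add("TF1", "g1", 1, 0.8)
        regs.add("TF1", "g2", -1, 1.0)
        write_regulons(regs, tmp_path / "r.tsv")
        back = read_regulons(tmp_path / "r.tsv")
        assert back == regs


class TestPkn:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            PriorKnowledgeNetwork(edges=[("A", 1, "A")])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError):
            PriorKnowledgeNetwork(edges=[("A", 1, "B"), ("A", 1, "B")])

    def test_opposite_sign_parallel_allowed(self):
        pkn = PriorKnowledgeNetwork(edges=[("A", 1, "B"), ("A", -1, "B")])
        assert len(pkn.edges) == 2

    def test_sif_roundtrip(self, tmp_path):
        pkn = PriorKnowledgeNetwork(
            edges=[("A", 1, "B"), ("B", -1, "C"), ("A", -1, "C")]
        )
        write_sif(pkn, tmp_path / "n.sif")
        back = read_sif(tmp_path / "n.sif")
        assert back.edges == pkn.edges


class TestIlp:
    def test_two_hop_activation_chain(self):
        pkn = PriorKnowledgeNetwork(edges=[("P", 1, "A"), ("A", 1, "T")])
        inst = build_ilp(pkn, "P", 1, {"T": 1}, {"T": 1.0}, node_penalty=0.1)
        sols = solve(inst)
        assert len(sols) == 1
        assert sols[0].states == {"P": 1, "A": 1, "T": 1}
        assert sols[0].objective == pytest.approx(0.3)

    def test_inhibitor_edge_mismatch_tradeoff(self):
        # P --(-1)--> T with T measured up and P forced up: T cannot be
        # activated, so the optimum leaves T inactive (mismatch 1)
        pkn = PriorKnowledgeNetwork(edges=[("P", -1, "T")])
        inst = build_ilp(pkn, "P", 1, {"T": 1}, {"T": 1.0}, node_penalty=0.1)
        sols = solve(inst)
        assert sols[0].states == {"P": 1, "T": 0}
        assert sols[0].objective == pytest.approx(1.0 + 0.1)

    def test_free_sign_flips_perturbation(self):
        pkn = PriorKnowledgeNetwork(edges=[("P", -1, "T")])
        inst = build_ilp(pkn, "P", "free", {"T": 1}, {"T": 1.0}, node_penalty=0.1)
        sols = solve(inst)
        assert sols[0].states == {"P": -1, "T": 1}
        assert sols[0].objective == pytest.approx(0.2)

    def test_sign_composition_two_negatives(self):
        pkn = PriorKnowledgeNetwork(edges=[("P", -1, "A"), ("A", -1, "T")])
        inst = build_ilp(pkn, "P", 1, {"T": 1}, {"T": 1.0}, node_penalty=0.01)
        sols = solve(inst)
        assert sols[0].states == {"P": 1, "A": -1, "T": 1}

    def test_unreachable_tf_warns(self):
        pkn = PriorKnowledgeNetwork(edges=[("P", 1, "A"), ("B", 1, "T")])
        with pytest.warns(UserWarning, match="unreachable"):
            build_ilp(pkn, "P", 1, {"T": 1}, {"T": 1.0}, node_penalty=0.1)

    def test_missing_perturbation_rejected(self):
        pkn = PriorKnowledgeNetwork(edges=[("A", 1, "B")])
        with pytest.raises(ValueError):
            build_ilp(pkn, "P", 1, {"B": 1}, {"B": 1.0}, node_penalty=0.1)

    def test_symmetric_parallel_paths_two_optima(self):
        pkn = PriorKnowledgeNetwork(
            edges=[("P", 1, "A"), ("A", 1, "T"), ("P", 1, "B"), ("B", 1, "T")]
        )
        inst = build_ilp(pkn, "P", 1, {"T": 1}, {"T": 1.0}, node_penalty=0.1)
        sols = solve(inst)
        assert len(sols) == 2
        assert {frozenset(k for k, v in s.states.items() if v != 0) for s in sols} == {
            frozenset({"P", "A", "T"}),
            frozenset({"P", "B", "T"}),
        }

    def test_enumerate_cap_one(self):
        pkn = PriorKnowledgeNetwork(
            edges=[("P", 1, "A"), ("A", 1, "T"), ("P", 1, "B"), ("B", 1, "T")]
        )
        inst = build_ilp(pkn, "P", 1, {"T": 1}, {"T": 1.0}, node_penalty=0.1)
        sols = solve(inst, enumerate_cap=1)
        assert len(sols) == 1
        assert sols[0].objective == pytest.approx(0.3)

    @pytest.mark.parametrize("backend", ["milp", "exhaustive"])
    def test_backends_agree(self, backend):
        pkn = PriorKnowledgeNetwork(
            edges=[("P", 1, "A"), ("A", -1, "T1"), ("P", -1, "B"), ("B", -1, "T2")]
        )
        inst = build_ilp(
            pkn, "P", "free", {"T1": -1, "T2": 1},
            {"T1": 1.0, "T2": 2.0}, node_penalty=0.05,
        )
        sols = solve(inst, backend=backend)
        # P up, A up, T1 down, B down, T2 up: zero mismatch, 5 active nodes
        assert sols[0].objective == pytest.approx(5 * 0.05, abs=1e-9)
        assert sols[0].states == {"P": 1, "A": 1, "T1": -1, "B": -1, "T2": 1}

    def test_oracle_equivalence_random_instances(self, rng):
        for trial in range(30):
            n_nodes = int(rng.integers(4, 8))
            nodes = [f"n{i}" for i in range(n_nodes)]
            edges = []
            for i in range(n_nodes):
                for j in range(n_nodes):
                    if i != j and rng.random() < 0.3:
                        edges.append((nodes[i], int(rng.choice([-1, 1])), nodes[j]))
            if not edges:
                continue
            pkn_nodes = sorted({v for e in edges for v in (e[0], e[2])})
            pert = pkn_nodes[0]
            tf_pool = [v for v in pkn_nodes if v != pert]
            tfs = {
                v: int(rng.choice([-1, 1]))
                for v in rng.choice(tf_pool, size=min(2, len(tf_pool)), replace=False)
            }
            weights = {t: float(rng.uniform(0.5, 2.0)) for t in tfs}
            pkn = PriorKnowledgeNetwork(edges=edges)
            inst = build_ilp(pkn, pert, 1, tfs, weights, node_penalty=0.07)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                sols = solve(inst)
            oracle_obj, _ = exhaustive_min_objective(
                edges, pert, 1, tfs, weights, 0.07
            )
            assert sols[0].objective == pytest.approx(oracle_obj, abs=1e-6)

    def test_solutions_satisfy_propagation_and_acyclicity(self, rng):
        import networkx as nx

        pkn, _, truth = gen_pkn(14, 0.15, 2, 3, seed=33)
        measurements = dict(truth.active_tfs)
        inst = build_ilp(pkn, "PERT", 1, measurements,
                         {t: 1.0 for t in measurements}, node_penalty=0.05)
        sols = solve(inst)
        for s in sols:
            g = nx.DiGraph()
            g.add_edges_from((a, b) for a, _, b in s.used_edges)
            assert nx.is_directed_acyclic_graph(g)
            for node, state in s.states.items():
                if state == 0 or node == "PERT":
                    continue
                assert any(
                    tgt == node and s.states[src] != 0
                    and sign * s.states[src] == state
                    for src, sign, tgt in s.used_edges
                ), f"unsupported active node {node}"


class TestAggregate:
    def _sol(self, states, edges=(), objective=0.0):
        from pharmflow.causal import Solution

        return Solution(states=states, used_edges=tuple(edges), objective=objective)

    def test_single_solution_up_is_100(self):
        net = aggregate_solutions([self._sol({"A": 1})])
        assert net.node_values["A"] == 100

    def test_half_up_is_50(self):
        net = aggregate_solutions([self._sol({"A": 1}), self._sol({"A": 0})])
        assert net.node_values["A"] == 50

    def test_up_down_cancel_to_0(self):
        net = aggregate_solutions([self._sol({"A": 1}), self._sol({"A": -1})])
        assert net.node_values["A"] == 0
        assert net.magnitude("A") == 0

    def test_edge_use_fraction(self):
        e = ("A", 1, "B")
        net = aggregate_solutions(
            [self._sol({"A": 1, "B": 1}, [e]), self._sol({"A": 1, "B": 0})]
        )
        assert net.edges == [("A", 1, "B", 0.5)]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_solutions([])


class TestExport:
    def test_empty_network(self, tmp_path):
        net = InferredNetwork({}, {}, [], 0.0, 1)
        export_network(net, tmp_path / "n.sif", tmp_path / "a.tsv")
        assert (tmp_path / "n.sif").read_text() == ""
        header = (tmp_path / "a.tsv").read_text().splitlines()[0]
        assert header == "id\tvalue\tmagnitude\trole"

    def test_chain_roundtrip(self, tmp_path):
        net = InferredNetwork(
            {"P": 100, "A": 100, "T": -100},
            {"P": "perturbation", "A": "intermediate", "T": "tf"},
            [("P", 1, "A", 1.0), ("A", -1, "T", 1.0)],
            0.3,
            1,
        )
        export_network(net, tmp_path / "n.sif", tmp_path / "a.tsv")
        back = read_sif(tmp_path / "n.sif")
        assert back.edges == [("P", 1, "A"), ("A", -1, "T")]
        attrs = pd.read_csv(tmp_path / "a.tsv", sep="\t", index_col=0)
        assert attrs.loc["T", "value"] == -100
        assert attrs.loc["T", "role"] == "tf"


class TestPlantedPathRecovery:
    def test_noise_free_recovery(self):
        for seed in range(5):
            pkn, _, truth = gen_pkn(16, 0.1, 3, 2, seed=seed)
            measurements = dict(truth.active_tfs)
            weights = {t: 1.0 for t in measurements}
            inst = build_ilp(pkn, "PERT", 1, measurements, weights,
                             node_penalty=0.01)
            sols = solve(inst)
            net = aggregate_solutions(sols, perturbation="PERT",
                                      tfs=measurements)
            planted = {v for path in truth.active_paths.values() for v in path}
            for node, value in net.node_values.items():
                if node in planted:
                    assert abs(value) == 100, (seed, node, value)
                else:
                    assert value == 0, (seed, node, value)
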