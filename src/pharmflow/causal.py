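"""Signed-network causal inference from TF activities.

Two stages:

1. ``tf_activity`` scores transcription factors by the mode-weighted mean of
   their regulon targets' ranking statistics, with a gene-label permutation
   z-score; the top-K TFs by |z| are selected.
2. ``build_ilp``/``solve``/``aggregate_solutions`` fit the selected TF signs
   onto a signed directed prior-knowledge network by integer linear
   programming: minimize TF sign mismatches plus a per-active-node penalty,
   subject to signal-propagation consistency and acyclicity of used edges.
   All optimal node-state assignments (up to a cap) are enumerated with
   exclusion cuts and aggregated into per-node activation values in
   [-100, 100] (signed fraction of optimal solutions).

The solver backend is ``scipy.optimize.milp`` (HiGHS); a pure-Python
branch-and-bound over node states is available as ``backend="exhaustive"``
for small instances and environments without a MILP solver.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from ._util import child_rng

__all__ = [
    "RegulonSet",
    "PriorKnowledgeNetwork",
    "InferredNetwork",
    "Solution",
    "IlpInstance",
    "tf_activity",
    "build_ilp",
    "solve",
    "aggregate_solutions",
    "export_network",
    "read_sif",
    "write_sif",
    "read_regulons",
    "write_regulons",
]

_OBJ_TOL = 1e-6
_EDGE_EPS = 1e-7  # tiny edge-use penalty: keeps used-edge sets minimal


# ---------------------------------------------------------------------------
# regulons and TF activity


class RegulonSet(dict):
    """Mapping tf -> list of (target, mode in {-1,+1}, weight in (0,1])."""

    def add(self, tf: str, target: str, mode: int, weight: float = 1.0) -> None:
        if mode not in (-1, 1):
            raise ValueError(f"mode must be -1 or +1, got {mode}")
        if not 0 < weight <= 1:
            raise ValueError(f"weight must be in (0, 1], got {weight}")
        entries = self.setdefault(tf, [])
        if any(t == target for t, _, _ in entries):
            raise ValueError(f"duplicate (tf, target) pair ({tf}, {target})")
        entries.append((target, mode, weight))


def read_regulons(path) -> RegulonSet:
    df = pd.read_csv(path, sep="\t")
    regs = RegulonSet()
    for row in df.itertuples(index=False):
        regs.add(str(row.tf), str(row.target), int(row.mode), float(row.weight))
    return regs


def write_regulons(regulons: RegulonSet, path) -> None:
    rows = [
        {"tf": tf, "target": t, "mode": m, "weight": w}
        for tf in sorted(regulons)
        for t, m, w in regulons[tf]
    ]
    pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def tf_activity(
    stats: pd.DataFrame,
    regulons: RegulonSet,
    n_permutations: int = 1000,
    seed: int = 0,
    top_k: int = 10,
    stat_col: str = "t_stat",
) -> pd.DataFrame:
    """Regulon-based TF activity scores with a permutation z-score.

    ``raw_score(tf) = sum(w * mode * t_target) / sum(w)`` over the TF's
    measured targets; the null permutes gene labels of the statistic vector.
    The top-K TFs by |z_score| are marked selected (ties break by tf id).
    """
    t = stats[stat_col]
    gene_index = {g: i for i, g in enumerate(stats.index)}
    tvec = t.to_numpy(dtype=float)
    rng = child_rng(seed, "tf-activity")
    perms = np.empty((n_permutations, tvec.size))
    for r in range(n_permutations):
        perms[r] = tvec[rng.permutation(tvec.size)]

    rows = []
    skipped = []
    for tf in sorted(regulons):
        idx, coef = [], []
        for target, mode, weight in regulons[tf]:
            if target in gene_index:
                idx.append(gene_index[target])
                coef.append(weight * mode)
        if not idx:
            skipped.append(tf)
            continue
        coef = np.asarray(coef)
        wsum = sum(w for tgt, _, w in regulons[tf] if tgt in gene_index)
        raw = float(tvec[idx] @ coef / wsum)
        null = perms[:, idx] @ coef / wsum
        sd = null.std(ddof=1)
        z = (raw - null.mean()) / sd if sd > 0 else 0.0
        rows.append({"tf": tf, "raw_score": raw, "z_score": float(z)})
    if skipped:
        warnings.warn(f"regulons with no measured targets skipped: {skipped}", stacklevel=2)
    if not rows:
        raise ValueError("no regulon has measured targets")
    res = pd.DataFrame(rows).set_index("tf")
    res["sign"] = np.where(res["z_score"] >= 0, 1, -1)
    order = sorted(res.index, key=lambda tf: (-abs(res.loc[tf, "z_score"]), tf))
    selected = set(order[:top_k])
    res["selected"] = [tf in selected for tf in res.index]
    return res


# ---------------------------------------------------------------------------
# prior-knowledge network


@dataclass
class PriorKnowledgeNetwork:
    """Signed directed interaction network.

    Edges are (source, sign, target) with sign in {-1, +1}; self-loops are
    rejected, parallel edges of opposite sign are allowed, duplicates not.
    """

    edges: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for src, sign, tgt in self.edges:
            if src == tgt:
                raise ValueError(f"self-loop on {src!r}")
            if sign not in (-1, 1):
                raise ValueError(f"edge sign must be -1 or +1, got {sign!r}")
            if (src, sign, tgt) in seen:
                raise ValueError(f"duplicate edge {(src, sign, tgt)}")
            seen.add((src, sign, tgt))

    @property
    def nodes(self) -> list:
        out = []
        seen = set()
        for src, _, tgt in self.edges:
            for v in (src, tgt):
                if v not in seen:
                    seen.add(v)
                    out.append(v)
        return out

    def reachable_from(self, start) -> set:
        adj: dict = {}
        for src, _, tgt in self.edges:
            adj.setdefault(src, set()).add(tgt)
        seen, stack = {start}, [start]
        while stack:
            v = stack.pop()
            for u in adj.get(v, ()):
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return seen


_REL_TO_SIGN = {"+1": 1, "1": 1, "-1": -1, "activates": 1, "inhibits": -1}
_SIGN_TO_REL = {1: "activates", -1: "inhibits"}


def read_sif(path) -> PriorKnowledgeNetwork:
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            src, rel, tgt = parts
            if rel not in _REL_TO_SIGN:
                raise ValueError(f"{path}:{ln}: unknown relation {rel!r}")
            edges.append((src, _REL_TO_SIGN[rel], tgt))
    return PriorKnowledgeNetwork(edges=edges)


def write_sif(pkn_or_edges, path) -> None:
    edges = getattr(pkn_or_edges, "edges", pkn_or_edges)
    with open(path, "w") as fh:
        for src, sign, tgt in edges:
            fh.write(f"{src}\t{_SIGN_TO_REL[sign]}\t{tgt}\n")


# ---------------------------------------------------------------------------
# ILP construction


@dataclass
class IlpInstance:
    pkn: PriorKnowledgeNetwork
    perturbation: str
    perturbation_sign: object  # +1 | -1 | "free"
    tf_measurements: dict  # tf -> measured sign in {-1, +1}
    mismatch_weights: dict  # tf -> positive weight
    node_penalty: float
    nodes: list = field(init=False)

    def __post_init__(self):
        self.nodes = self.pkn.nodes
        if self.perturbation not in self.nodes:
            raise ValueError(f"perturbation node {self.perturbation!r} not in PKN")
        missing = [t for t in self.tf_measurements if t not in self.nodes]
        if missing:
            raise ValueError(f"measured TFs not in PKN: {missing}")
        if self.perturbation_sign not in (1, -1, "free"):
            raise ValueError("perturbation_sign must be +1, -1 or 'free'")
        reach = self.pkn.reachable_from(self.perturbation)
        self.unreachable_tfs = sorted(
            t for t in self.tf_measurements if t not in reach
        )
        if self.unreachable_tfs:
            warnings.warn(
                "structurally unfittable TFs (unreachable from perturbation): "
                f"{self.unreachable_tfs}",
                stacklevel=2,
            )

    def state_objective(self, states: dict) -> float:
        """Objective of a node-state assignment (no edge epsilon)."""
        obj = self.node_penalty * sum(1 for v in states.values() if v != 0)
        for tf, measured in self.tf_measurements.items():
            if states.get(tf, 0) != measured:
                obj += self.mismatch_weights[tf]
        return obj


@dataclass(frozen=True)
class Solution:
    states: dict  # node -> {-1, 0, +1}
    used_edges: tuple  # ((source, sign, target), ...)
    objective: float


def build_ilp(
    pkn: PriorKnowledgeNetwork,
    perturbation_node: str,
    perturbation_sign,
    tf_measurements: dict,
    mismatch_weights: dict | None = None,
    node_penalty: float | None = None,
) -> IlpInstance:
    """Assemble the inference problem.

    ``mismatch_weights`` default to 1 per TF; ``node_penalty`` defaults to
    0.1 x the mean mismatch weight.
    """
    if mismatch_weights is None:
        mismatch_weights = {tf: 1.0 for tf in tf_measurements}
    missing_w = set(tf_measurements) - set(mismatch_weights)
    if missing_w:
        raise ValueError(f"mismatch weights missing for {sorted(missing_w)}")
    if node_penalty is None:
        node_penalty = 0.1 * float(np.mean([mismatch_weights[t] for t in tf_measurements]))
    return IlpInstance(
        pkn=pkn,
        perturbation=perturbation_node,
        perturbation_sign=perturbation_sign,
        tf_measurements=dict(tf_measurements),
        mismatch_weights={t: float(mismatch_weights[t]) for t in tf_measurements},
        node_penalty=float(node_penalty),
    )


def _solve_fixed_milp(inst: IlpInstance, pert_sign: int, enumerate_cap: int) -> list[Solution]:
    """Enumerate optimal solutions for a fixed perturbation sign via MILP."""
    nodes = inst.nodes
    edges = inst.pkn.edges
    n, m = len(nodes), len(edges)
    node_idx = {v: i for i, v in enumerate(nodes)}

    # variable layout: u[0:n], d[n:2n], eu[2n:2n+m], ed[2n+m:2n+2m], l[2n+2m:2n+2m+n]
    n_var = 2 * n + 2 * m + n
    U = lambda i: i
    D = lambda i: n + i
    EU = lambda k: 2 * n + k
    ED = lambda k: 2 * n + m + k
    L = lambda i: 2 * n + 2 * m + i

    c = np.zeros(n_var)
    c[: 2 * n] = inst.node_penalty
    c[2 * n : 2 * n + 2 * m] = _EDGE_EPS
    const_term = 0.0
    for tf, measured in inst.tf_measurements.items():
        w = inst.mismatch_weights[tf]
        i = node_idx[tf]
        const_term += w
        c[U(i) if measured > 0 else D(i)] -= w  # w*(1 - x) = w - w*x

    rows, cols, vals, lbs, ubs = [], [], [], [], []
    r = 0

    def add_row(entries, lb, ub):
        nonlocal r
        for col, val in entries:
            rows.append(r)
            cols.append(col)
            vals.append(val)
        lbs.append(lb)
        ubs.append(ub)
        r += 1

    p = node_idx[inst.perturbation]
    for i in range(n):
        add_row([(U(i), 1.0), (D(i), 1.0)], -np.inf, 1.0)  # mutually exclusive
    in_up: dict[int, list[int]] = {i: [] for i in range(n)}
    in_dn: dict[int, list[int]] = {i: [] for i in range(n)}
    for k, (src, sign, tgt) in enumerate(edges):
        i, j = node_idx[src], node_idx[tgt]
        src_up_var = U(i) if sign > 0 else D(i)
        src_dn_var = D(i) if sign > 0 else U(i)
        add_row([(EU(k), 1.0), (src_up_var, -1.0)], -np.inf, 0.0)
        add_row([(ED(k), 1.0), (src_dn_var, -1.0)], -np.inf, 0.0)
        add_row([(EU(k), 1.0), (U(j), -1.0)], -np.inf, 0.0)
        add_row([(ED(k), 1.0), (D(j), -1.0)], -np.inf, 0.0)
        # acyclicity big-M: l_j - l_i >= 1 - n*(1 - eu - ed)
        add_row(
            [(L(j), 1.0), (L(i), -1.0), (EU(k), -float(n)), (ED(k), -float(n))],
            1.0 - n,
            np.inf,
        )
        in_up[j].append(k)
        in_dn[j].append(k)
    for i in range(n):
        if i == p:
            continue
        add_row([(U(i), 1.0)] + [(EU(k), -1.0) for k in in_up[i]], -np.inf, 0.0)
        add_row([(D(i), 1.0)] + [(ED(k), -1.0) for k in in_dn[i]], -np.inf, 0.0)

    lb = np.zeros(n_var)
    ub = np.ones(n_var)
    ub[2 * n + 2 * m :] = float(n)
    # fixed perturbation state
    if pert_sign > 0:
        lb[U(p)] = 1.0
        ub[D(p)] = 0.0
    else:
        lb[D(p)] = 1.0
        ub[U(p)] = 0.0
    integrality = np.ones(n_var)
    integrality[2 * n + 2 * m :] = 0  # levels may be continuous

    base_A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(r, n_var)
    )
    base_lb = np.array(lbs)
    base_ub = np.array(ubs)

    solutions: list[Solution] = []
    cuts: list[tuple[np.ndarray, float]] = []  # (row, lower bound)
    best_obj = None
    while len(solutions) < enumerate_cap:
        if cuts:
            cut_A = sparse.csr_matrix(np.vstack([row for row, _ in cuts]))
            A = sparse.vstack([base_A, cut_A])
            clb = np.concatenate([base_lb, [b for _, b in cuts]])
            cub = np.concatenate([base_ub, np.full(len(cuts), np.inf)])
        else:
            A, clb, cub = base_A, base_lb, base_ub
        res = milp(
            c=c,
            constraints=LinearConstraint(A, clb, cub),
            integrality=integrality,
            bounds=Bounds(lb, ub),
        )
        if res.status != 0:
            break
        x = res.x
        states = {}
        for v, i in node_idx.items():
            if x[U(i)] > 0.5:
                states[v] = 1
            elif x[D(i)] > 0.5:
                states[v] = -1
            else:
                states[v] = 0
        obj = inst.state_objective(states)
        if best_obj is None:
            best_obj = obj
        elif obj > best_obj + _OBJ_TOL:
            break
        used = tuple(
            edges[k]
            for k in range(m)
            if x[EU(k)] > 0.5 or x[ED(k)] > 0.5
        )
        solutions.append(Solution(states=states, used_edges=used, objective=obj))
        # exclusion cut on the state variables of this exact assignment
        row = np.zeros(n_var)
        offset = 0.0
        for v, i in node_idx.items():
            for var in (U(i), D(i)):
                if x[var] > 0.5:
                    row[var] = -1.0
                    offset += 1.0
                else:
                    row[var] = 1.0
        cuts.append((row, 1.0 - offset))
    return solutions


def _feasible_states(inst: IlpInstance, states: dict, pert_sign: int) -> bool:
    """A state assignment is realizable iff every active node is reachable
    from the perturbation through sign-consistent edges between active nodes."""
    if states.get(inst.perturbation, 0) != pert_sign:
        return False
    active = {v for v, s in states.items() if s != 0}
    adj: dict = {}
    for src, sign, tgt in inst.pkn.edges:
        if src in active and tgt in active and sign * states[src] == states[tgt]:
            adj.setdefault(src, []).append(tgt)
    seen = {inst.perturbation}
    stack = [inst.perturbation]
    while stack:
        v = stack.pop()
        for u in adj.get(v, ()):
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return active <= seen


def _support_edges(inst: IlpInstance, states: dict) -> tuple:
    """A minimal spanning explanation (BFS tree over consistent edges)."""
    active = {v for v, s in states.items() if s != 0}
    parent: dict = {}
    seen = {inst.perturbation}
    queue = [inst.perturbation]
    adj: dict = {}
    for src, sign, tgt in sorted(inst.pkn.edges):
        if src in active and tgt in active and sign * states[src] == states[tgt]:
            adj.setdefault(src, []).append((src, sign, tgt))
    while queue:
        v = queue.pop(0)
        for edge in adj.get(v, ()):
            tgt = edge[2]
            if tgt not in seen:
                seen.add(tgt)
                parent[tgt] = edge
                queue.append(tgt)
    return tuple(parent[v] for v in sorted(parent))


def _solve_fixed_exhaustive(
    inst: IlpInstance, pert_sign: int, enumerate_cap: int
) -> list[Solution]:
    """Branch over node states; only nodes reachable from the perturbation
    can be active, so everything else is fixed to 0 up front."""
    reach = sorted(
        (inst.pkn.reachable_from(inst.perturbation) - {inst.perturbation})
    )
    if len(reach) > 18:
        raise ValueError(
            f"exhaustive backend limited to 18 free nodes, got {len(reach)}"
        )
    best_obj = None
    best: list[Solution] = []
    zero = {v: 0 for v in inst.nodes}
    for combo in itertools.product((0, 1, -1), repeat=len(reach)):
        states = dict(zero)
        states[inst.perturbation] = pert_sign
        states.update(zip(reach, combo))
        if not _feasible_states(inst, states, pert_sign):
            continue
        obj = inst.state_objective(states)
        if best_obj is None or obj < best_obj - _OBJ_TOL:
            best_obj = obj
            best = [Solution(states, _support_edges(inst, states), obj)]
        elif abs(obj - best_obj) <= _OBJ_TOL and len(best) < enumerate_cap:
            best.append(Solution(states, _support_edges(inst, states), obj))
    return best


def solve(
    instance: IlpInstance, enumerate_cap: int = 100, backend: str = "milp"
) -> list[Solution]:
    """All optimal solutions (up to ``enumerate_cap``), equal objective values.

    With ``perturbation_sign="free"`` both fixings are solved and the better
    objective kept; on a tie both solution sets are merged.
    """
    solver = {"milp": _solve_fixed_milp, "exhaustive": _solve_fixed_exhaustive}[backend]
    if instance.perturbation_sign == "free":
        up = solver(instance, 1, enumerate_cap)
        dn = solver(instance, -1, enumerate_cap)
        if not up and not dn:
            raise ValueError("infeasible instance")
        if not dn or (up and up[0].objective < dn[0].objective - _OBJ_TOL):
            return up
        if not up or dn[0].objective < up[0].objective - _OBJ_TOL:
            return dn
        return (up + dn)[:enumerate_cap]
    sols = solver(instance, instance.perturbation_sign, enumerate_cap)
    if not sols:
        raise ValueError("infeasible instance")
    return sols


# ---------------------------------------------------------------------------
# aggregation and export


@dataclass
class InferredNetwork:
    node_values: dict  # node -> int in [-100, 100]
    node_roles: dict  # node -> {"perturbation", "tf", "intermediate"}
    edges: list  # (source, sign, target, use_fraction)
    objective: float
    n_solutions: int

    def magnitude(self, node) -> int:
        return abs(self.node_values[node])


def aggregate_solutions(
    solutions: list[Solution],
    perturbation: str | None = None,
    tfs=(),
) -> InferredNetwork:
    """Fold an optimal-solution set into signed 0-100 node activations.

    ``value = round(100 * (n_up - n_down) / n_solutions)``; an edge is kept
    if used in any optimal solution, annotated with its use fraction.
    """
    if not solutions:
        raise ValueError("no solutions to aggregate")
    n_sol = len(solutions)
    nodes = list(solutions[0].states)
    values = {}
    for v in nodes:
        n_up = sum(1 for s in solutions if s.states[v] == 1)
        n_dn = sum(1 for s in solutions if s.states[v] == -1)
        values[v] = int(round(100.0 * (n_up - n_dn) / n_sol))
    edge_counts: dict = {}
    for s in solutions:
        for e in s.used_edges:
            edge_counts[e] = edge_counts.get(e, 0) + 1
    edges = [
        (src, sign, tgt, count / n_sol)
        for (src, sign, tgt), count in sorted(edge_counts.items())
    ]
    roles = {}
    tfs = set(tfs)
    for v in nodes:
        if v == perturbation:
            roles[v] = "perturbation"
        elif v in tfs:
            roles[v] = "tf"
        else:
            roles[v] = "intermediate"
    return InferredNetwork(
        node_values=values,
        node_roles=roles,
        edges=edges,
        objective=solutions[0].objective,
        n_solutions=n_sol,
    )


def export_network(net: InferredNetwork, sif_path, attrs_path) -> None:
    """Write the inferred network as SIF plus a node attribute TSV."""
    with open(sif_path, "w") as fh:
        for src, sign, tgt, _ in net.edges:
            fh.write(f"{src}\t{_SIGN_TO_REL[sign]}\t{tgt}\n")
    rows = [
        {
            "id": v,
            "value": net.node_values[v],
            "magnitude": abs(net.node_values[v]),
            "role": net.node_roles[v],
        }
        for v in net.node_values
    ]
    pd.DataFrame(rows, columns=["id", "value", "magnitude", "role"]).to_csv(
        attrs_path, sep="\t", index=False
    )
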