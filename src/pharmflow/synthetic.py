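"""Synthetic inputs with planted ground truth for every pipeline stage.

Everything is generated from a single global seed; each generator derives a
component child seed (see :func:`pharmflow._util.child_seed`) so stages can
be regenerated independently and reproducibly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import child_rng
from .causal import PriorKnowledgeNetwork, RegulonSet
from .connectivity import SignatureLibrary
from .dose_response import ExpressionMatrix
from .enrichment import GeneSetCollection

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_expression",
    "gen_gene_sets",
    "gen_signature_library",
    "gen_pkn",
    "gen_molecules",
    "MOLECULE_PANEL",
    "PLANTED_NEAR_DUPLICATES",
]


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    n_cell_systems: int = 4
    concentrations: tuple = (0.0, 100.0, 200.0, 300.0, 400.0)
    replicates_per_condition: int = 1
    n_responders: int = 50
    slope_range: tuple = (0.002, 0.008)  # expression units per µM, magnitude
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_cell_systems < 1 or self.replicates_per_condition < 1:
            raise ValueError("counts must be positive")
        if not self.concentrations:
            raise ValueError("empty concentration list")
        if 0.0 not in [float(c) for c in self.concentrations]:
            raise ValueError("concentrations must include the vehicle control 0")
        if len(set(self.concentrations)) < 2:
            raise ValueError("need at least 2 distinct concentrations")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("negative concentration")
        if self.n_responders < 0 or self.n_responders > self.n_genes:
            raise ValueError("n_responders must be in [0, n_genes]")
        lo, hi = self.slope_range
        if not (0 < lo <= hi):
            raise ValueError("slope_range must satisfy 0 < lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("negative noise_sd")


@dataclass
class GroundTruth:
    """Planted truth shared across generators (each fills its own fields)."""

    true_slopes: dict = field(default_factory=dict)
    responder_set: set = field(default_factory=set)
    planted_gene_sets: set = field(default_factory=set)
    mimic_perturbagens: dict = field(default_factory=dict)
    active_paths: dict = field(default_factory=dict)  # tf -> ordered node list
    active_tfs: dict = field(default_factory=dict)  # tf -> sign

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["responder_set"] = sorted(self.responder_set)
        payload["planted_gene_sets"] = sorted(self.planted_gene_sets)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["responder_set"] = set(payload["responder_set"])
        payload["planted_gene_sets"] = set(payload["planted_gene_sets"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# expression


def gen_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Linear concentration-response expression with per-cell-system intercepts.

    ``value(g, sample) = beta0(g, cell) + beta1(g) * conc + eps`` with iid
    Gaussian noise. Responder slopes are drawn uniformly from
    ``slope_range`` in magnitude with a random sign.
    """
    rng = child_rng(config.seed, "expression")
    width = max(4, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    systems = [f"cs{i}" for i in range(1, config.n_cell_systems + 1)]

    slopes = np.zeros(config.n_genes)
    responders = rng.choice(config.n_genes, size=config.n_responders, replace=False)
    lo, hi = config.slope_range
    magnitudes = rng.uniform(lo, hi, size=config.n_responders)
    signs = rng.choice([-1.0, 1.0], size=config.n_responders)
    slopes[responders] = magnitudes * signs

    beta0 = rng.uniform(6.0, 10.0, size=(config.n_genes, config.n_cell_systems))

    sample_ids, meta_rows, cols = [], [], []
    for si, system in enumerate(systems):
        for conc in config.concentrations:
            for rep in range(1, config.replicates_per_condition + 1):
                sid = f"{system}_c{conc:g}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"concentration": float(conc), "cell_system": system,
                     "time": "6h", "replicate": rep}
                )
                noise = (
                    rng.normal(0.0, config.noise_sd, size=config.n_genes)
                    if config.noise_sd > 0
                    else np.zeros(config.n_genes)
                )
                cols.append(beta0[:, si] + slopes * float(conc) + noise)

    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="feature_id"),
        columns=sample_ids,
    )
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    truth = GroundTruth(
        true_slopes={g: float(s) for g, s in zip(genes, slopes)},
        responder_set={genes[i] for i in responders},
    )
    return ExpressionMatrix(values=values, sample_meta=meta), truth


# ---------------------------------------------------------------------------
# gene sets


def gen_gene_sets(
    genes,
    n_sets: int,
    set_size_range: tuple,
    planted_fraction: float,
    ground_truth: GroundTruth,
    seed: int = 0,
    responder_fraction: float = 0.8,
) -> GeneSetCollection:
    """Random gene sets plus planted sets enriched among responders.

    A planted set draws at least ``responder_fraction`` of its members from
    responders whose slope signs agree; the rest (and all background sets)
    are uniform draws. Planted set names are recorded in the ground truth.
    """
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must be in [0, 1]")
    lo, hi = set_size_range
    genes = list(genes)
    if hi > len(genes):
        raise ValueError("set sizes exceed the gene universe")
    rng = child_rng(seed, "gene-sets")
    n_planted = int(round(planted_fraction * n_sets))

    pos = sorted(
        g for g in ground_truth.responder_set if ground_truth.true_slopes.get(g, 0) > 0
    )
    neg = sorted(
        g for g in ground_truth.responder_set if ground_truth.true_slopes.get(g, 0) < 0
    )
    non_responders = sorted(set(genes) - ground_truth.responder_set)

    sets = {}
    for i in range(n_planted):
        size = int(rng.integers(lo, hi + 1))
        sign_pool = pos if (pos and (i % 2 == 0 or not neg)) else neg
        # shrink oversized planted sets to what the same-sign pool supports
        max_supported = int(len(sign_pool) / responder_fraction)
        if max_supported < lo:
            raise ValueError(
                f"not enough same-sign responders ({len(sign_pool)}) for a "
                f"planted set of size >= {lo}"
            )
        size = min(size, max_supported)
        n_core = math.ceil(responder_fraction * size)
        core = rng.choice(len(sign_pool), size=n_core, replace=False)
        members = {sign_pool[j] for j in core}
        filler_pool = non_responders if non_responders else genes
        while len(members) < size:
            members.add(filler_pool[int(rng.integers(len(filler_pool)))])
        name = f"planted_set_{i + 1}"
        sets[name] = members
        ground_truth.planted_gene_sets.add(name)
    for i in range(n_sets - n_planted):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"bg_set_{i + 1}"] = {genes[j] for j in members}
    return GeneSetCollection(sets, label="synthetic")


# ---------------------------------------------------------------------------
# signature library


def _standardized_ranks(x: np.ndarray) -> np.ndarray:
    r = rankdata(x)
    r = r - r.mean()
    return r / np.linalg.norm(r)


def _measured_rho(sig: np.ndarray, zq: np.ndarray) -> float:
    return float(_standardized_ranks(sig) @ zq)


def gen_signature_library(
    n_perturbagens: int,
    conditions_per_perturbagen: int,
    n_genes: int,
    mimic_spec: dict,
    query_direction,
    seed: int = 0,
    rho_tol: float = 0.01,
) -> tuple[SignatureLibrary, GroundTruth]:
    """Random signatures plus mimics with calibrated rank correlation.

    ``mimic_spec`` maps perturbagen id -> target Spearman rho with the query.
    Mimics are built by blending the query's standardized ranks with
    independent noise; the mixing weight is calibrated by bisection until the
    achieved Spearman is within ``rho_tol`` of the target. A target of
    exactly +/-1 short-circuits to a monotone transform of the query.
    """
    query = np.asarray(query_direction, dtype=float)
    if query.size != n_genes:
        raise ValueError(
            f"query_direction has {query.size} genes, library expects {n_genes}"
        )
    for pert, rho in mimic_spec.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"target rho {rho} for {pert!r} outside [-1, 1]")

    rng = child_rng(seed, "signature-library")
    width = max(3, len(str(n_perturbagens)))
    valid = {f"pert{p:0{width}d}" for p in range(1, n_perturbagens + 1)}
    unknown = set(mimic_spec) - valid
    if unknown:
        raise ValueError(
            f"mimic_spec names unknown perturbagens: {sorted(unknown)} "
            f"(ids run pert{1:0{width}d}..pert{n_perturbagens:0{width}d})"
        )
    gene_ids = [f"g{i:0{max(4, len(str(n_genes)))}d}" for i in range(1, n_genes + 1)]
    zq = _standardized_ranks(query)

    def calibrated_mimic(target: float) -> np.ndarray:
        if abs(target) >= 1.0:
            # exact monotone (or anti-monotone) transform of the query
            r = rankdata(query)
            return np.sign(target) * (2.0 * r + 1.0)
        base = np.sign(target) * zq if target != 0 else zq
        noise = _standardized_ranks(rng.standard_normal(n_genes))
        lo_w, hi_w = 0.0, 1.0
        w = 0.5
        for _ in range(60):
            w = 0.5 * (lo_w + hi_w)
            sig = w * base + (1.0 - w) * noise
            got = _measured_rho(sig, zq)
            if abs(got - target) <= rho_tol * 0.5:
                break
            # rho moves monotonically toward sign(target) as w grows
            if (got < target) if target >= 0 else (got > target):
                lo_w = w
            else:
                hi_w = w
        return w * base + (1.0 - w) * noise

    names, meta_rows, cols = [], [], []
    for p in range(1, n_perturbagens + 1):
        pert = f"pert{p:0{width}d}"
        for ci in range(1, conditions_per_perturbagen + 1):
            sid = f"{pert}:c{ci}"
            names.append(sid)
            meta_rows.append(
                {"signature_id": sid, "perturbagen_id": pert, "condition": f"c{ci}"}
            )
            if pert in mimic_spec and ci == 1:
                cols.append(calibrated_mimic(float(mimic_spec[pert])))
            else:
                cols.append(rng.standard_normal(n_genes))

    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene_id"), columns=names
    )
    meta = pd.DataFrame(meta_rows).set_index("signature_id")
    truth = GroundTruth(mimic_perturbagens=dict(mimic_spec))
    return SignatureLibrary(values=values, signature_meta=meta), truth


# ---------------------------------------------------------------------------
# prior-knowledge network


def gen_pkn(
    n_nodes: int,
    edge_density: float,
    path_length: int,
    n_tfs: int,
    seed: int = 0,
    genes=None,
    ground_truth: GroundTruth | None = None,
    regulon_size: int = 5,
) -> tuple[PriorKnowledgeNetwork, RegulonSet, GroundTruth]:
    """Signed PKN with one planted path from the perturbation to each TF.

    The sign composition along each planted path determines the TF's planted
    sign. Distractor edges are added at ``edge_density`` among node pairs
    that cannot create alternative routes into planted nodes, so the planted
    paths remain the unique optimal explanation.  Each TF receives a regulon
    of ``regulon_size`` targets whose modes are concordant with its sign
    (drawn from the expression ground truth's responders when provided).
    """
    if path_length < 1:
        raise ValueError("path_length must be >= 1")
    if path_length >= n_nodes:
        raise ValueError("path_length must be < n_nodes")
    n_planted = 1 + n_tfs * path_length
    if n_planted > n_nodes:
        raise ValueError(
            f"need {n_planted} nodes for {n_tfs} planted paths of length "
            f"{path_length}, got {n_nodes}"
        )
    rng = child_rng(seed, "pkn")
    edges = []
    truth = GroundTruth()
    pert = "PERT"
    intermediates = 0
    for t in range(1, n_tfs + 1):
        tf = f"TF{t}"
        path_nodes = [pert]
        for _ in range(path_length - 1):
            intermediates += 1
            path_nodes.append(f"I{intermediates}")
        path_nodes.append(tf)
        sign_total = 1
        for a, b in zip(path_nodes[:-1], path_nodes[1:]):
            sign = int(rng.choice([-1, 1]))
            sign_total *= sign
            edges.append((a, sign, b))
        truth.active_paths[tf] = path_nodes
        truth.active_tfs[tf] = sign_total

    planted_nodes = {pert} | {
        v for nodes in truth.active_paths.values() for v in nodes
    }
    n_extra = n_nodes - len(planted_nodes)
    extra = [f"N{i}" for i in range(1, n_extra + 1)]
    # distractors may start anywhere but the perturbation and may only end on
    # filler nodes: no alternative route into a planted node can appear
    sources = sorted(planted_nodes - {pert}) + extra
    existing = {(a, b) for a, _, b in edges}
    for src in sources:
        for tgt in extra:
            if src == tgt or (src, tgt) in existing:
                continue
            if rng.random() < edge_density:
                edges.append((src, int(rng.choice([-1, 1])), tgt))
                existing.add((src, tgt))

    pkn = PriorKnowledgeNetwork(edges=edges)

    regulons = RegulonSet()
    pos, neg = [], []
    if ground_truth is not None:
        pos = sorted(
            g for g in ground_truth.responder_set
            if ground_truth.true_slopes.get(g, 0) > 0
        )
        neg = sorted(
            g for g in ground_truth.responder_set
            if ground_truth.true_slopes.get(g, 0) < 0
        )
        truth.true_slopes = ground_truth.true_slopes
        truth.responder_set = set(ground_truth.responder_set)
    used = set()
    for tf, sign in truth.active_tfs.items():
        for i in range(regulon_size):
            mode = int(rng.choice([-1, 1]))
            pool = pos if sign * mode > 0 else neg
            pool = [g for g in pool if (tf, g) not in used]
            if pool:
                target = pool[int(rng.integers(len(pool)))]
            else:
                mode = 1
                target = f"tg_{tf}_{i + 1}"
            used.add((tf, target))
            regulons.add(tf, target, mode, weight=1.0)
    return pkn, regulons, truth


# ---------------------------------------------------------------------------
# molecules


#: Built-in molecule panel: bicyclic pyridine-alkaloid scaffolds plus
#: chains, rings, aromatics and heteroatoms.  Nicotine and nornicotine
#: (differing by one N-methyl) are the planted near-duplicate pair.
MOLECULE_PANEL: dict = {
    "anatabine": "C1C=CC(NC1)c1cccnc1",
    "anabasine": "C1CCC(NC1)c1cccnc1",
    "nicotine": "CN1CCCC1c1cccnc1",
    "nornicotine": "C1CCC(N1)c1cccnc1",
    "pyridine": "c1ccncc1",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "furan": "c1ccoc1",
    "ethanol": "CCO",
    "acetic_acid": "CC(=O)O",
    "cyclohexane": "C1CCCCC1",
    "isopropylamine": "CC(N)C",
}

PLANTED_NEAR_DUPLICATES: tuple = ("nicotine", "nornicotine")


def gen_molecules() -> list[str]:
    """The fixed built-in SMILES panel (order matches MOLECULE_PANEL)."""
    return list(MOLECULE_PANEL.values())


def write_molecules(path) -> None:
    with open(path, "w") as fh:
        for name, smiles in MOLECULE_PANEL.items():
            fh.write(f"{smiles}\t{name}\n")
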