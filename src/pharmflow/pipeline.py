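"""End-to-end orchestration of the synthetic analysis pipeline.

Stage order: simulate -> dose -> {gsea, connect} -> network, with the
chemistry stage independent.  The perturbagen library is generated after the
dose fit so that mimic signatures can be calibrated against the actual query
(the fitted slope t-statistics).  Identical config + seed reproduces every
output byte for byte; a manifest records child seeds and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import child_seed
from . import synthetic
from .causal import (
    aggregate_solutions,
    build_ilp,
    export_network,
    solve,
    tf_activity,
    write_regulons,
    write_sif,
)
from .chem import read_smiles_file, similarity_matrix
from .connectivity import connectivity_analysis, top_hits
from .dose_response import ExpressionMatrix, fit_dose_response
from .enrichment import gsea, rank_genes, write_gmt

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

log = logging.getLogger("pharmflow.pipeline")

ALL_STAGES = ("simulate", "dose", "gsea", "connect", "network", "chem")


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # simulation
    n_genes: int = 300
    n_cell_systems: int = 2
    concentrations: tuple = (0.0, 100.0, 200.0, 300.0, 400.0)
    replicates_per_condition: int = 2
    n_responders: int = 40
    slope_range: tuple = (0.002, 0.008)
    noise_sd: float = 0.2
    # gene sets
    n_sets: int = 30
    set_size_range: tuple = (8, 20)
    planted_fraction: float = 0.1
    # signature library
    n_perturbagens: int = 120
    conditions_per_perturbagen: int = 2
    mimic_rhos: tuple = (0.6, 0.49, 0.4)
    # enrichment
    gsea_permutations: int = 500
    weight_exponent: float = 1.0
    min_set_size: int = 5
    max_set_size: int = 500
    # connectivity
    n_random: int = 50
    connectivity_threshold: float = 0.001
    top_k_hits: int = 15
    # network
    pkn_nodes: int = 20
    edge_density: float = 0.05
    path_length: int = 3
    n_tfs: int = 3
    top_k_tfs: int = 10
    tf_permutations: int = 500
    beta_factor: float = 0.1
    enumerate_cap: int = 100
    # chemistry
    chem_reference: str = "anatabine"
    descriptors: tuple = ("PathFp", "SphereFp", "FragFP")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        version = data.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema version {version}")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        for key in ("stages", "concentrations", "slope_range", "set_size_range",
                    "mimic_rhos", "descriptors"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        payload = {"schema_version": 1, **asdict(self)}
        for k, v in payload.items():
            if isinstance(v, tuple):
                payload[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        deps = {"dose": "simulate", "gsea": "dose", "connect": "dose",
                "network": "dose"}
        out = Path(self.out_dir)
        for stage, dep in deps.items():
            if stage in self.stages and dep not in self.stages:
                # upstream outputs must already exist on disk (fail fast)
                required = {
                    "simulate": ["matrix.tsv", "sample_meta.tsv"],
                    "dose": ["dose_stats.tsv"],
                }[dep]
                missing = [f for f in required if not (out / f).exists()]
                if missing:
                    raise ValueError(
                        f"stage {stage!r} requires outputs of {dep!r}: "
                        f"missing {missing}"
                    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def demo_config(out_dir, seed: int = 0) -> PipelineConfig:
    """The full synthetic acceptance scenario at demo scale."""
    return PipelineConfig(out_dir=str(out_dir), seed=seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "child_seeds": {},
        "stages": {},
    }
    written: dict[str, list[str]] = {}

    def record(stage: str, *paths: Path) -> None:
        written.setdefault(stage, []).extend(str(p.name) for p in paths)

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    matrix = truth = stats = None

    if "simulate" in config.stages:
        log.info("stage simulate: expression, gene sets, PKN, molecules")
        try:
            sim_cfg = synthetic.SimulationConfig(
                n_genes=config.n_genes,
                n_cell_systems=config.n_cell_systems,
                concentrations=config.concentrations,
                replicates_per_condition=config.replicates_per_condition,
                n_responders=config.n_responders,
                slope_range=config.slope_range,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            matrix, truth = synthetic.gen_expression(sim_cfg)
            matrix.to_tsv(out / "matrix.tsv", out / "sample_meta.tsv")
            collection = synthetic.gen_gene_sets(
                matrix.feature_ids, config.n_sets, config.set_size_range,
                config.planted_fraction, truth, seed=config.seed,
            )
            write_gmt(collection, out / "gene_sets.gmt")
            pkn, regulons, net_truth = synthetic.gen_pkn(
                config.pkn_nodes, config.edge_density, config.path_length,
                config.n_tfs, seed=config.seed,
                genes=matrix.feature_ids, ground_truth=truth,
            )
            truth.active_paths = net_truth.active_paths
            truth.active_tfs = net_truth.active_tfs
            write_sif(pkn, out / "pkn.sif")
            write_regulons(regulons, out / "regulons.tsv")
            synthetic.write_molecules(out / "molecules.smi")
            truth.to_json(out / "ground_truth.json")
            for comp in ("expression", "gene-sets", "pkn"):
                manifest["child_seeds"][comp] = child_seed(config.seed, comp)
            record("simulate", out / "matrix.tsv", out / "sample_meta.tsv",
                   out / "gene_sets.gmt", out / "pkn.sif", out / "regulons.tsv",
                   out / "molecules.smi", out / "ground_truth.json")
        except Exception as exc:  # noqa: BLE001
            fail("simulate", exc)

    if "dose" in config.stages:
        log.info("stage dose: per-feature linear concentration-response fit")
        try:
            if matrix is None:
                matrix = ExpressionMatrix.from_tsv(
                    out / "matrix.tsv", out / "sample_meta.tsv"
                )
            stats = fit_dose_response(
                matrix, adjust_for_cell_system=config.n_cell_systems > 1
            )
            stats.to_csv(out / "dose_stats.tsv", sep="\t")
            record("dose", out / "dose_stats.tsv")
        except Exception as exc:  # noqa: BLE001
            fail("dose", exc)

    if stats is None and any(
        s in config.stages for s in ("gsea", "connect", "network")
    ):
        stats = pd.read_csv(out / "dose_stats.tsv", sep="\t", index_col=0)

    if "gsea" in config.stages:
        log.info("stage gsea: weighted-KS enrichment")
        try:
            from .enrichment import read_gmt

            collection = read_gmt(out / "gene_sets.gmt")
            ranked = rank_genes(stats)
            res = gsea(
                ranked, collection,
                n_permutations=config.gsea_permutations,
                weight_exponent=config.weight_exponent,
                seed=child_seed(config.seed, "gsea-stage"),
                min_size=config.min_set_size, max_size=config.max_set_size,
            )
            res.to_csv(out / "gsea.tsv", sep="\t")
            manifest["child_seeds"]["gsea-stage"] = child_seed(config.seed, "gsea-stage")
            record("gsea", out / "gsea.tsv")
        except Exception as exc:  # noqa: BLE001
            fail("gsea", exc)

    if "connect" in config.stages:
        log.info("stage connect: signature library + connectivity scoring")
        try:
            query = stats["t_stat"]
            width = max(3, len(str(config.n_perturbagens)))
            mimic_spec = {
                f"pert{i + 1:0{width}d}": rho
                for i, rho in enumerate(config.mimic_rhos)
            }
            library, lib_truth = synthetic.gen_signature_library(
                config.n_perturbagens, config.conditions_per_perturbagen,
                len(query), mimic_spec, query.to_numpy(),
                seed=config.seed,
            )
            # library gene universe must match the measured genes
            library.values.index = stats.index
            library.to_tsv(out / "library.tsv", out / "library_meta.tsv")
            results = connectivity_analysis(
                query, library,
                n_random=config.n_random,
                threshold=config.connectivity_threshold,
                seed=config.seed,
            )
            results.to_csv(out / "connectivity.tsv", sep="\t")
            hits = top_hits(results, k=config.top_k_hits)
            hits.to_csv(out / "top_hits.tsv", sep="\t")
            if truth is not None:
                truth.mimic_perturbagens = lib_truth.mimic_perturbagens
                truth.to_json(out / "ground_truth.json")
            manifest["child_seeds"]["signature-library"] = child_seed(
                config.seed, "signature-library"
            )
            record("connect", out / "library.tsv", out / "library_meta.tsv",
                   out / "connectivity.tsv", out / "top_hits.tsv")
        except Exception as exc:  # noqa: BLE001
            fail("connect", exc)

    if "network" in config.stages:
        log.info("stage network: TF activity + ILP causal inference")
        try:
            from .causal import read_regulons, read_sif

            regulons = read_regulons(out / "regulons.tsv")
            pkn = read_sif(out / "pkn.sif")
            tf_table = tf_activity(
                stats, regulons,
                n_permutations=config.tf_permutations,
                seed=config.seed, top_k=config.top_k_tfs,
            )
            tf_table.to_csv(out / "tf_activity.tsv", sep="\t")
            selected = tf_table[tf_table["selected"]]
            measurements = {tf: int(s) for tf, s in selected["sign"].items()}
            weights = {tf: max(abs(z), 1e-6) for tf, z in selected["z_score"].items()}
            beta = config.beta_factor * float(np.mean(list(weights.values())))
            inst = build_ilp(pkn, "PERT", "free", measurements, weights, beta)
            sols = solve(inst, enumerate_cap=config.enumerate_cap)
            net = aggregate_solutions(sols, perturbation="PERT", tfs=measurements)
            export_network(net, out / "inferred_network.sif",
                           out / "node_attributes.tsv")
            with open(out / "solutions.json", "w") as fh:
                json.dump(
                    {
                        "objective": net.objective,
                        "n_solutions": net.n_solutions,
                        "solutions": [
                            {"states": s.states,
                             "used_edges": [list(e) for e in s.used_edges]}
                            for s in sols
                        ],
                    },
                    fh, indent=1, sort_keys=True,
                )
            record("network", out / "tf_activity.tsv",
                   out / "inferred_network.sif", out / "node_attributes.tsv",
                   out / "solutions.json")
        except Exception as exc:  # noqa: BLE001
            fail("network", exc)

    if "chem" in config.stages:
        log.info("stage chem: fingerprints + Tanimoto distances")
        try:
            smi = out / "molecules.smi"
            if not smi.exists():
                synthetic.write_molecules(smi)
            mols = read_smiles_file(smi)
            dist = similarity_matrix(
                mols, config.chem_reference, descriptors=config.descriptors
            )
            dist.to_csv(out / "chem_distances.tsv", sep="\t")
            record("chem", out / "chem_distances.tsv")
        except Exception as exc:  # noqa: BLE001
            fail("chem", exc)

    for stage, files in written.items():
        manifest["stages"][stage] = {
            "outputs": {f: _sha256(out / f) for f in sorted(files)}
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
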