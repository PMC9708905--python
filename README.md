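# pharmflow

A multi-omics systems-pharmacology analysis pipeline, exercised end-to-end on
synthetic data with planted ground truth. Five analysis stages plus a
generator and an orchestrating CLI:

| Module | What it does |
| --- | --- |
| `pharmflow.synthetic` | Generates every pipeline input with planted truth: linear concentration-response expression, enriched gene sets, a perturbagen signature library with calibrated rank-correlation mimics, a signed prior-knowledge network with planted causal paths, and a small-molecule SMILES panel. |
| `pharmflow.dose_response` | Per-feature OLS concentration-response fits (optionally with cell-system covariates), treatment-vs-vehicle contrasts, Benjamini-Hochberg adjustment, cross-omics Pearson profile correlation. |
| `pharmflow.enrichment` | Weighted Kolmogorov-Smirnov gene set enrichment on t-statistic-ranked genes, with a gene-permutation null, NES and sign-stratified FDR. |
| `pharmflow.connectivity` | Spearman matching of a query signature against a signature library, best-condition collapse per perturbagen, and an empirical permutation null for retention at p <= 0.001. |
| `pharmflow.chem` | SMILES parsing (restricted dialect, no stereo/isotopes, no aromaticity perception), hashed linear-path and circular-sphere 512-bit fingerprints, an open dictionary fragment fingerprint, and Tanimoto similarity/distance. |
| `pharmflow.causal` | Regulon-based TF activity scoring with a permutation z-score, then a CARNIVAL-style integer linear program over a signed directed network: minimal mismatch + node-penalty explanation of the TF signs, all-optima enumeration, and signed 0-100 activation values. |
| `pharmflow.pipeline` / `pharmflow.cli` | One-command orchestration with a YAML config, per-stage child seeds, and a checksummed run manifest. |

## CLI

```bash
pharmflow pipeline demo --seed 1 --out demo_out   # full synthetic run
pharmflow pipeline run --config config.yaml       # YAML-driven run

pharmflow dose    --matrix matrix.tsv --meta sample_meta.tsv --combined --out stats.tsv
pharmflow gsea    --stats stats.tsv --gmt sets.gmt --nperm 1000 --seed 1 --out gsea.tsv
pharmflow connect --query stats.tsv --library lib.tsv --meta lib_meta.tsv \
                  --nrandom 100 --alpha 0.001 --seed 1 --out connectivity.tsv
pharmflow chem    --smiles panel.smi --reference anatabine \
                  --descriptors pathfp,spherefp,fragfp --out distances.tsv
pharmflow network --pkn pkn.sif --regulons regulons.tsv --stats stats.tsv \
                  --perturbation PERT --sign free --topk 10 --out-dir net/
```

All file formats are plain text: TSV matrices and metadata, GMT gene sets,
SIF networks, regulon TSV, one-SMILES-per-line panels, JSON ground truth and
manifests. Identical config + seed reproduces every output byte for byte.

## Acceptance

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance contract is property-based (closed-form OLS equivalence,
brute-force enrichment-score equivalence, null calibrations, fingerprint
invariances, exhaustive ILP equivalence, planted-truth recovery,
determinism); each criterion is a test in `tests/test_acceptance.py`. There
are no numeric paper-level targets to recompute offline, so the script
writes an empty JSON object after running the full synthetic pipeline and
verifying its planted ground truth; a non-zero exit signals a regression.

## Notes

- Seeds: one global seed expands into per-component child seeds via
  `fnv1a_64(component) XOR seed` (see `pharmflow._util.child_seed`), so any
  stage can be regenerated independently.
- The fragment-string-to-bit mapping uses FNV-1a 64 modulo 512 and is
  deterministic across platforms; bit-compatibility with any third-party
  fingerprint software is a non-goal, as is its proprietary fragment
  dictionary (an open ~100-fragment dictionary ships instead).
- Inferred-network node values are signed (-100..100; sign carries the
  predicted direction); the unsigned magnitude is also emitted.
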