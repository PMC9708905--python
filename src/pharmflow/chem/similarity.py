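"""Tanimoto similarity/distance between binary fingerprints."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fingerprints import (
    Fingerprint,
    frag_fingerprint,
    path_fingerprint,
    sphere_fingerprint,
)
from .smiles import MolecularGraph

__all__ = ["tanimoto", "tanimoto_distance", "similarity_matrix", "DESCRIPTORS"]

DESCRIPTORS = {
    "PathFp": path_fingerprint,
    "SphereFp": sphere_fingerprint,
    "FragFP": frag_fingerprint,
}


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; two all-zero fingerprints compare as 1.0."""
    if fp_a.length != fp_b.length:
        raise ValueError("fingerprint length mismatch")
    if fp_a.descriptor_name != fp_b.descriptor_name:
        raise ValueError(
            f"descriptor mismatch: {fp_a.descriptor_name} vs {fp_b.descriptor_name}"
        )
    a, b = fp_a.as_array(), fp_b.as_array()
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return float(np.sum(a & b) / union)


def tanimoto_distance(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    return 1.0 - tanimoto(fp_a, fp_b)


def similarity_matrix(
    mols: dict[str, MolecularGraph],
    reference: str,
    descriptors=("PathFp", "SphereFp", "FragFP"),
) -> pd.DataFrame:
    """Tanimoto distance of each molecule to the reference, per descriptor.

    Returns a heat-map-ready DataFrame (molecules x descriptors).
    """
    if not mols:
        raise ValueError("no molecules")
    if reference not in mols:
        raise KeyError(f"reference molecule {reference!r} not in panel")
    unknown = [d for d in descriptors if d not in DESCRIPTORS]
    if unknown:
        raise ValueError(f"unknown descriptors: {unknown}")
    out = pd.DataFrame(index=list(mols), columns=list(descriptors), dtype=float)
    for desc in descriptors:
        fn = DESCRIPTORS[desc]
        ref_fp = fn(mols[reference])
        for name, mol in mols.items():
            out.loc[name, desc] = tanimoto_distance(fn(mol), ref_fp)
    out.index.name = "molecule"
    return out
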