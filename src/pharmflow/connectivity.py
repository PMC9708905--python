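"""Query-signature connectivity against a perturbagen signature library.

A query differential signature (gene scores) is compared with every library
signature by Spearman correlation, collapsed to the best condition per
perturbagen, and calibrated against an empirical null built from random
permutations of the query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import child_rng

__all__ = [
    "SignatureLibrary",
    "match_genes",
    "spearman",
    "score_library",
    "collapse_best",
    "empirical_null",
    "empirical_p",
    "connectivity_analysis",
    "top_hits",
]

_MIN_COMMON_DEFAULT = 100


@dataclass
class SignatureLibrary:
    """Measured-genes x signatures value matrix with per-signature metadata.

    ``values``: DataFrame (gene ids x signature ids).
    ``signature_meta``: DataFrame indexed by signature id with columns
    ``perturbagen_id`` and ``condition``.
    """

    values: pd.DataFrame
    signature_meta: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in library")
        missing = set(self.values.columns) - set(self.signature_meta.index)
        if missing:
            raise ValueError(f"signatures without metadata: {sorted(missing)[:5]}")
        if self.signature_meta["perturbagen_id"].isna().any():
            raise ValueError("every signature needs a perturbagen_id")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    def to_tsv(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        self.signature_meta.to_csv(meta_path, sep="\t", index_label="signature_id")

    @classmethod
    def from_tsv(cls, values_path, meta_path) -> "SignatureLibrary":
        return cls(
            values=pd.read_csv(values_path, sep="\t", index_col=0),
            signature_meta=pd.read_csv(meta_path, sep="\t", index_col=0),
        )


def match_genes(query: pd.Series, library: SignatureLibrary, min_common: int = _MIN_COMMON_DEFAULT):
    """Restrict query and library to their common genes, in library order.

    Returns ``(aligned_query, aligned_values, n_common)``.
    """
    common = [g for g in library.gene_ids if g in set(query.index)]
    n_common = len(common)
    if n_common == 0:
        raise ValueError("query and library share no genes")
    if n_common < min_common:
        warnings.warn(
            f"only {n_common} genes in common (< {min_common})", stacklevel=2
        )
    return query.loc[common], library.values.loc[common], n_common


def spearman(x, y) -> float:
    """Spearman rho: Pearson correlation of average-ranked values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d and equal length")
    if x.size < 3:
        raise ValueError("need length >= 3")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _rank_standardize(M: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, centered and L2-normalized.

    Constant columns come back as all-NaN so their correlations flag missing.
    """
    R = rankdata(M, axis=0)
    R = R - R.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(R, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norms > 0, R / norms, np.nan)


def score_library(query: pd.Series, values: pd.DataFrame) -> pd.Series:
    """Spearman rho of the query against every library signature column."""
    zq = _rank_standardize(query.to_numpy(dtype=float)[:, None])[:, 0]
    Z = _rank_standardize(values.to_numpy(dtype=float))
    rho = zq @ Z
    return pd.Series(rho, index=values.columns, name="rho")


def collapse_best(rho: pd.Series, signature_meta: pd.DataFrame) -> pd.DataFrame:
    """Best (highest) rho per perturbagen; ties break by condition label."""
    df = pd.DataFrame(
        {
            "rho": rho,
            "perturbagen_id": signature_meta.loc[rho.index, "perturbagen_id"],
            "condition": signature_meta.loc[rho.index, "condition"],
        }
    ).dropna(subset=["rho"])
    df = df.sort_values(
        ["perturbagen_id", "rho", "condition"], ascending=[True, False, True]
    )
    best = df.groupby("perturbagen_id", sort=True).first()
    return best.rename(columns={"rho": "best_rho", "condition": "best_condition"})


def empirical_null(
    query: pd.Series,
    library: SignatureLibrary,
    n_random: int = 100,
    seed: int = 0,
    mode: str = "permutation",
) -> np.ndarray:
    """Null pool of best-per-perturbagen rhos from random query signatures.

    Each random query is a uniform permutation of the real query's values
    (``mode="permutation"``, preserving its marginal distribution) or an iid
    Gaussian draw (``mode="gaussian"``).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = child_rng(seed, "connectivity-null")
    q, values, _ = match_genes(query, library, min_common=1)
    Z = _rank_standardize(values.to_numpy(dtype=float))
    meta = library.signature_meta
    pool = []
    base = q.to_numpy(dtype=float)
    for _ in range(n_random):
        if mode == "permutation":
            rand = rng.permutation(base)
        elif mode == "gaussian":
            rand = rng.standard_normal(base.size)
        else:
            raise ValueError(f"unknown null mode {mode!r}")
        zq = _rank_standardize(rand[:, None])[:, 0]
        rho = pd.Series(zq @ Z, index=values.columns)
        pool.append(collapse_best(rho, meta)["best_rho"].to_numpy())
    return np.concatenate(pool)


def empirical_p(best_rho: float, null_pool: np.ndarray, threshold: float = 0.001):
    """One-sided (high-rho) empirical tail p with a +1 pseudocount.

    ``p = (1 + #{pool >= best_rho}) / (1 + |pool|)``; retention at the
    default 0.001 threshold therefore requires a pool of >= 999.
    """
    pool = np.asarray(null_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty null pool")
    p = (1.0 + np.sum(pool >= best_rho)) / (1.0 + pool.size)
    return float(p), bool(p <= threshold)


def connectivity_analysis(
    query: pd.Series,
    library: SignatureLibrary,
    n_random: int = 100,
    threshold: float = 0.001,
    seed: int = 0,
    min_common: int = _MIN_COMMON_DEFAULT,
) -> pd.DataFrame:
    """Full connectivity pass: score, collapse, and calibrate every perturbagen."""
    q, values, n_common = match_genes(query, library, min_common=min_common)
    rho = score_library(q, values)
    best = collapse_best(rho, library.signature_meta)
    pool = empirical_null(query, library, n_random=n_random, seed=seed)
    if threshold > 0 and (1.0 / (1.0 + pool.size)) > threshold:
        warnings.warn(
            f"null pool of {pool.size} cannot reach p <= {threshold}; "
            "increase n_random or the library size",
            stacklevel=2,
        )
    pr = [empirical_p(r, pool, threshold) for r in best["best_rho"]]
    best["empirical_p"] = [p for p, _ in pr]
    best["retained"] = [r for _, r in pr]
    best.attrs["n_common"] = n_common
    best.attrs["null_pool_size"] = int(pool.size)
    return best


def top_hits(results: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Retained perturbagens sorted by best_rho descending, truncated to k."""
    if results.empty:
        raise ValueError("empty connectivity results")
    kept = results[results["retained"]].sort_values(
        ["best_rho", "best_condition"], ascending=[False, True]
    )
    return kept.head(k)
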