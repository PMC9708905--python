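"""Weighted Kolmogorov-Smirnov gene set enrichment on ranked gene lists.

The ranking statistic is the concentration-slope t-statistic; the null model
permutes gene labels (random same-size gene subsets), NES normalizes by the
mean same-sign null magnitude, and FDR follows the sign-stratified ratio
method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import child_rng

__all__ = [
    "RankedList",
    "GeneSetCollection",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class RankedList:
    """Gene ids ordered by decreasing ranking statistic, with the scores."""

    gene_ids: tuple
    scores: tuple

    def __post_init__(self):
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("ids and scores must align")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        if any(self.scores[i] < self.scores[i + 1] for i in range(len(self.scores) - 1)):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


class GeneSetCollection(dict):
    """Mapping set name -> frozenset of gene ids, with a collection label."""

    def __init__(self, sets=None, label: str = ""):
        super().__init__()
        self.label = label
        for name, members in (sets or {}).items():
            self[name] = frozenset(members)
            if not self[name]:
                raise ValueError(f"gene set {name!r} is empty")


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def rank_genes(stats: pd.DataFrame, stat_col: str = "t_stat") -> RankedList:
    """Order genes by the ranking statistic, descending.

    Ties break lexicographically by gene id so the result is deterministic
    regardless of input row order.  Degenerate zero-residual fits with a
    non-zero slope (flagged upstream; their t would be infinite) are
    resolved to finite scores beyond the finite-t range, ordered by |slope|,
    so the ranking stays total.
    """
    if stats.index.duplicated().any():
        raise ValueError("duplicate gene ids in stats")
    t = stats[stat_col].astype(float).copy()
    if "degenerate" in stats.columns and "beta1" in stats.columns:
        degen = stats["degenerate"].astype(bool) & (stats["beta1"].abs() > 0)
        if degen.any():
            finite = t[~degen].abs()
            base = max(float(finite.max()), 1.0) if len(finite) else 1.0
            bmax = float(stats.loc[degen, "beta1"].abs().max())
            t[degen] = (
                np.sign(stats.loc[degen, "beta1"])
                * base
                * (2.0 + stats.loc[degen, "beta1"].abs() / bmax)
            )
    if not np.isfinite(t).all():
        raise ValueError("non-finite ranking statistics")
    order = sorted(stats.index, key=lambda g: (-t.loc[g], g))
    return RankedList(
        gene_ids=tuple(order), scores=tuple(float(t.loc[g]) for g in order)
    )


def enrichment_score(
    ranked: RankedList, gene_set, weight_exponent: float = 1.0
):
    """Weighted KS enrichment score of one gene set.

    The running sum increments ``|score|^w / sum_hits |score|^w`` at each hit
    and decrements ``1/(N - |S|)`` at each miss; ES is the deviation of
    maximum magnitude. Returns ``(es, running_sum, leading_edge)``.
    """
    n = len(ranked)
    in_set = np.fromiter(
        (g in gene_set for g in ranked.gene_ids), dtype=bool, count=n
    )
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set has empty intersection with the ranked universe")
    if k == n:
        raise ValueError("gene set covers the whole universe")
    scores = np.asarray(ranked.scores, dtype=float)
    w = np.abs(scores) ** weight_exponent
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total <= 0:
        # all hit weights zero (e.g. exponent>0 with zero scores): fall back
        # to unweighted steps so the statistic stays defined
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / (n - k)
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = frozenset(
            g for g, hit in zip(ranked.gene_ids[: i_ext + 1], in_set[: i_ext + 1]) if hit
        )
    else:
        leading = frozenset(
            g for g, hit in zip(ranked.gene_ids[i_ext:], in_set[i_ext:]) if hit
        )
    return es, running, leading


def _null_es(weights: np.ndarray, k: int, n_perm: int, rng) -> np.ndarray:
    """Vectorized null ES for random same-size gene subsets.

    weights: |score|^w per rank position (length N). Returns n_perm ES values.
    """
    n = weights.size
    d = 1.0 / (n - k)
    # k distinct positions per permutation
    pos = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
    pos.sort(axis=1)
    hw = weights[pos]
    tot = hw.sum(axis=1, keepdims=True)
    zero_tot = tot[:, 0] <= 0
    if zero_tot.any():
        hw[zero_tot] = 1.0
        tot = hw.sum(axis=1, keepdims=True)
    cw = np.cumsum(hw, axis=1) / tot
    j = np.arange(k)
    # running sum immediately after hit i / immediately before hit i
    after = cw - (pos - j) * d
    before = after - hw / tot
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation GSEA over a collection.

    Null ES per set come from random same-size gene subsets;
    ``nes = es / mean(|null ES of the same sign|)``; nominal p is one-sided
    within the sign class with a +1 pseudocount; FDR by the sign-stratified
    ratio of null to observed NES tail fractions.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = child_rng(seed, "gsea")
    universe = set(ranked.gene_ids)
    weights = np.abs(np.asarray(ranked.scores, dtype=float)) ** weight_exponent

    rows = []
    null_nes_pos, null_nes_neg = [], []
    skipped = []
    for name in sorted(collection):
        members = collection[name] & universe
        k = len(members)
        if k < min_size or k > max_size or k == len(universe):
            skipped.append(name)
            continue
        es, _, leading = enrichment_score(ranked, members, weight_exponent)
        null = _null_es(weights, k, n_permutations, rng)
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan
        if es >= 0:
            nes = es / mean_pos if pos_null.size else np.nan
            p = (1.0 + np.sum(pos_null >= es)) / (1.0 + pos_null.size)
        else:
            nes = es / mean_neg if neg_null.size else np.nan
            p = (1.0 + np.sum(neg_null <= es)) / (1.0 + neg_null.size)
        null_nes_pos.append(pos_null / mean_pos if pos_null.size else np.empty(0))
        null_nes_neg.append(neg_null / mean_neg if neg_null.size else np.empty(0))
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "p_nominal": p,
                "size_used": k,
                "leading_edge": ",".join(sorted(leading)),
            }
        )

    if not rows:
        res = pd.DataFrame(
            columns=["set", "es", "nes", "p_nominal", "fdr", "size_used", "leading_edge"]
        ).set_index("set")
        res.attrs["skipped"] = skipped
        return res

    res = pd.DataFrame(rows).set_index("set")
    pool_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.empty(0)
    pool_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.empty(0)
    obs = res["nes"].to_numpy()
    fdr = np.empty(len(res))
    for i, nes in enumerate(obs):
        if np.isnan(nes):
            fdr[i] = np.nan
        elif nes >= 0:
            num = np.mean(pool_pos >= nes) if pool_pos.size else 0.0
            den = np.mean(obs[obs >= 0] >= nes)
            fdr[i] = min(1.0, num / den) if den > 0 else 1.0
        else:
            num = np.mean(pool_neg <= nes) if pool_neg.size else 0.0
            den = np.mean(obs[obs < 0] <= nes)
            fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    res["fdr"] = fdr
    res = res[["es", "nes", "p_nominal", "fdr", "size_used", "leading_edge"]]
    res.attrs["skipped"] = skipped
    return res
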