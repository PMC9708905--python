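"""Per-feature linear concentration-response modeling.

Fits, for every feature of an expression matrix, an ordinary-least-squares
model of the form

    value ~ beta0 + beta1 * concentration [+ cell-system indicators]

and derives two-sided t-test p-values for the concentration slope, adjusted
across features with the Benjamini-Hochberg step-up procedure.  Also provides
pairwise treatment-vs-vehicle contrasts (systems response profiles) and
cross-omics Pearson profile correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionMatrix",
    "DesignError",
    "fit_dose_response",
    "bh_adjust",
    "compute_srp",
    "correlate_features",
]

#: Residual-variance floor below which a fit is flagged degenerate.
_VAR_EPS = 1e-12


class DesignError(ValueError):
    """Raised when the regression design is rank deficient or too small."""


@dataclass
class ExpressionMatrix:
    """Feature-by-sample value matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_features, n_samples); index holds unique
        feature ids, columns are sample ids. Values are log-scale.
    sample_meta
        DataFrame indexed by sample id with at least columns
        ``concentration`` (real, µM), ``cell_system`` (categorical) and
        optionally ``time`` and ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.shape[1] != len(self.sample_meta):
            raise ValueError(
                f"column count {self.values.shape[1]} != sample metadata "
                f"length {len(self.sample_meta)}"
            )
        if not self.values.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if "concentration" not in self.sample_meta.columns:
            raise ValueError("sample metadata must carry a 'concentration' column")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, matrix_path, meta_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="feature_id")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, matrix_path, meta_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values=values, sample_meta=meta)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving with input positions; monotone after sorting by the raw
    p-value; capped at 1. ``q_(i) = min_{j >= i} p_(j) * m / j`` over the
    sorted sequence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if np.isnan(p).any():
        raise ValueError("NaN p-value in bh_adjust input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _design_matrix(meta: pd.DataFrame, adjust_for_cell_system: bool) -> np.ndarray:
    conc = meta["concentration"].to_numpy(dtype=float)
    cols = [np.ones_like(conc), conc]
    if adjust_for_cell_system:
        systems = pd.Categorical(meta["cell_system"])
        # reference-level coding: drop the first category
        for level in systems.categories[1:]:
            cols.append((systems == level).astype(float))
    return np.column_stack(cols)


def fit_dose_response(
    matrix: ExpressionMatrix, adjust_for_cell_system: bool = False
) -> pd.DataFrame:
    """OLS concentration-slope fit per feature.

    Returns a DataFrame indexed by feature id with columns ``beta0``,
    ``beta1``, ``beta1_se``, ``t_stat``, ``p_value``, ``fdr``, ``n_obs``
    and ``degenerate`` (True where residual variance is ~0; such features
    get p = 0 by convention so downstream ranking stays total).

    Features with missing values are fitted on their observed samples only,
    subject to the residual-degrees-of-freedom requirement.
    """
    meta = matrix.sample_meta
    n_conc = meta["concentration"].nunique()
    if not adjust_for_cell_system and n_conc < 3:
        raise DesignError(f"need >=3 distinct concentrations, got {n_conc}")
    if n_conc < 2:
        raise DesignError("design is rank deficient: a single concentration level")

    X_full = _design_matrix(meta, adjust_for_cell_system)
    n, p = X_full.shape
    if n - p < 1:
        raise DesignError(f"no residual degrees of freedom (n={n}, p={p})")
    if np.linalg.matrix_rank(X_full) < p:
        raise DesignError("rank-deficient design matrix")

    Y = matrix.values.to_numpy(dtype=float)
    n_features = Y.shape[0]
    beta0 = np.empty(n_features)
    beta1 = np.empty(n_features)
    se1 = np.empty(n_features)
    tstat = np.empty(n_features)
    pval = np.empty(n_features)
    nobs = np.empty(n_features, dtype=int)
    degen = np.zeros(n_features, dtype=bool)

    complete = ~np.isnan(Y).any(axis=1)

    def _fit_block(X: np.ndarray, Yb: np.ndarray):
        """OLS for a block of features sharing design X. Yb: (k, n)."""
        XtX_inv = np.linalg.inv(X.T @ X)
        B = Yb @ (XtX_inv @ X.T).T  # (k, p)
        resid = Yb - B @ X.T
        dof = X.shape[0] - X.shape[1]
        rss = np.einsum("ij,ij->i", resid, resid)
        sigma2 = rss / dof
        se = np.sqrt(np.maximum(sigma2, 0.0) * XtX_inv[1, 1])
        return B, se, rss, dof

    if complete.any():
        B, se, rss, dof = _fit_block(X_full, Y[complete])
        idx = np.flatnonzero(complete)
        beta0[idx] = B[:, 0]
        beta1[idx] = B[:, 1]
        se1[idx] = se
        nobs[idx] = n
        d = rss / dof < _VAR_EPS
        degen[idx] = d
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, B[:, 1] / se, 0.0)
        tstat[idx] = t
        pval[idx] = 2.0 * sps.t.sf(np.abs(t), dof)
        pval[idx[d]] = 0.0
        tstat[idx[d & (se < _VAR_EPS)]] = 0.0

    for i in np.flatnonzero(~complete):
        obs = ~np.isnan(Y[i])
        Xi = X_full[obs]
        if Xi.shape[0] - p < 1 or np.linalg.matrix_rank(Xi) < p:
            raise DesignError(
                f"feature {matrix.feature_ids[i]!r}: insufficient observed "
                "samples for the design"
            )
        B, se, rss, dof = _fit_block(Xi, Y[i, obs][None, :])
        beta0[i], beta1[i] = B[0, 0], B[0, 1]
        se1[i] = se[0]
        nobs[i] = int(obs.sum())
        if rss[0] / dof < _VAR_EPS:
            degen[i] = True
            pval[i] = 0.0
            tstat[i] = 0.0 if se[0] < _VAR_EPS else beta1[i] / se[0]
        else:
            tstat[i] = beta1[i] / se[0]
            pval[i] = 2.0 * sps.t.sf(abs(tstat[i]), dof)

    # exactly-constant features: slope 0, t 0, p 1 (not a dose effect)
    const = degen & (np.abs(beta1) < _VAR_EPS) & (np.abs(tstat) < _VAR_EPS)
    pval[const] = 1.0

    out = pd.DataFrame(
        {
            "beta0": beta0,
            "beta1": beta1,
            "beta1_se": se1,
            "t_stat": tstat,
            "p_value": pval,
            "fdr": bh_adjust(pval),
            "n_obs": nobs,
            "degenerate": degen,
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )
    return out


def compute_srp(
    matrix: ExpressionMatrix,
    treatment_level: float,
    control_level: float = 0.0,
) -> pd.DataFrame:
    """Treatment-vs-vehicle contrast per feature (systems response profile).

    ``log2_fc`` is the difference of group means (inputs are log2-scale);
    p-values come from the equal-variance two-sample t-test, BH-adjusted
    across features.
    """
    conc = matrix.sample_meta["concentration"].to_numpy(dtype=float)
    t_mask = conc == float(treatment_level)
    c_mask = conc == float(control_level)
    if not t_mask.any():
        raise ValueError(f"treatment level {treatment_level} absent from matrix")
    if not c_mask.any():
        raise ValueError(f"control level {control_level} absent from matrix")

    Y = matrix.values.to_numpy(dtype=float)
    yt, yc = Y[:, t_mask], Y[:, c_mask]
    nt, nc = yt.shape[1], yc.shape[1]
    log2_fc = yt.mean(axis=1) - yc.mean(axis=1)

    degen = np.zeros(Y.shape[0], dtype=bool)
    if nt >= 2 and nc >= 2:
        dof = nt + nc - 2
        sp2 = ((nt - 1) * yt.var(axis=1, ddof=1) + (nc - 1) * yc.var(axis=1, ddof=1)) / dof
        denom = np.sqrt(sp2 * (1.0 / nt + 1.0 / nc))
        degen = sp2 < _VAR_EPS
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, log2_fc / denom, 0.0)
        p = 2.0 * sps.t.sf(np.abs(t), dof)
        p[degen & (np.abs(log2_fc) >= _VAR_EPS)] = 0.0
        p[degen & (np.abs(log2_fc) < _VAR_EPS)] = 1.0
    else:
        # single replicate somewhere: fold change defined, p undefined
        t = np.full(Y.shape[0], np.nan)
        p = np.full(Y.shape[0], np.nan)

    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t_stat": t,
            "p_value": p,
            "fdr": bh_adjust(p) if not np.isnan(p).any() else p,
            "degenerate": degen,
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )
    out.attrs["contrast_label"] = f"{treatment_level} vs {control_level}"
    return out


def correlate_features(profile_a, profile_b) -> float:
    """Pearson correlation of two paired per-concentration profiles.

    Returns NaN (flagged missing) when either side has zero variance.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-d and of equal length")
    if a.size < 3:
        raise ValueError("need >=3 paired points")
    if a.std() < _VAR_EPS or b.std() < _VAR_EPS:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
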