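"""Indicator taxa per assemblage (Dufrêne–Legendre IndVal).

For taxon t and cluster c, specificity A_tc is the share of t's mean
abundance concentrated in c, fidelity B_tc the fraction of c's cells where
t occurs, and IV_tc = A_tc · B_tc (0–1 scale).  Significance of a taxon's
best IV comes from permuting cell labels (cluster sizes preserved), and the
per-taxon p-values are corrected for multiple testing by the
Benjamini–Hochberg step-up procedure.  Raw-scale bootstrap cell means are
the intended input: indicator status should reflect actual abundance, not
the variance-stabilized values used for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IndicatorTable",
    "indval",
    "indval_permutation",
    "bh_adjust",
    "indicator_lists",
    "indicator_table",
]


def _group_matrix(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    clusters = np.unique(labels)
    G = (labels[:, None] == clusters[None, :]).astype(float)
    sizes = G.sum(axis=0)
    if (sizes == 0).any():
        raise ValueError("every cluster must be non-empty")
    return clusters, G, sizes


def indval(
    X: pd.DataFrame, labels: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """A, B and IV per taxon × cluster, plus each taxon's best cluster.

    ``X`` is the cells × taxa matrix of raw-scale cell means.  An all-zero
    taxon has undefined A; its IV is reported as 0 for every cluster.
    Returns (A, B, IV, best) with clusters as columns; ``best`` holds the
    cluster label maximizing IV (ties to the lowest cluster index).
    """
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels must align with the matrix rows")
    clusters, G, sizes = _group_matrix(labels)
    M = X.to_numpy(dtype=float)
    if (M < 0).any():
        raise ValueError("abundances must be non-negative")
    cluster_mean = (G.T @ M) / sizes[:, None]  # clusters × taxa
    denom = cluster_mean.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, cluster_mean / np.where(denom > 0, denom, 1.0), 0.0)
    B = (G.T @ (M > 0)) / sizes[:, None]
    IV = A * B
    cols = X.columns
    A_df = pd.DataFrame(A.T, index=cols, columns=clusters)
    B_df = pd.DataFrame(B.T, index=cols, columns=clusters)
    IV_df = pd.DataFrame(IV.T, index=cols, columns=clusters)
    best = IV_df.idxmax(axis=1)  # first occurrence wins ties (lowest index)
    return A_df, B_df, IV_df, best


def _max_iv_batch(M: np.ndarray, perms: np.ndarray, G: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Best-cluster IV for each permutation (rows of ``perms`` index cells)."""
    P = perms.shape[0]
    out = np.empty((P, M.shape[1]))
    pres = (M > 0).astype(float)
    for p in range(P):
        Gp = G[perms[p]]
        cm = (Gp.T @ M) / sizes[:, None]
        denom = cm.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(denom > 0, cm / np.where(denom > 0, denom, 1.0), 0.0)
        B = (Gp.T @ pres) / sizes[:, None]
        out[p] = (A * B).max(axis=0)
    return out


def indval_permutation(
    X: pd.DataFrame, labels: np.ndarray, n_perm: int = 999, seed: int = 0
) -> pd.Series:
    """Permutation p-value of each taxon's best-cluster IV.

    Cell labels are permuted uniformly (cluster sizes preserved) and
    p = (1 + #{IV_perm ≥ IV_obs}) / (n_perm + 1).
    """
    labels = np.asarray(labels)
    clusters, G, sizes = _group_matrix(labels)
    M = X.to_numpy(dtype=float)
    _, _, IV_df, _ = indval(X, labels)
    observed = IV_df.max(axis=1).to_numpy()
    rng = np.random.default_rng(seed)
    n = len(labels)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    null = _max_iv_batch(M, perms, G, sizes)
    count = (null >= observed[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + count) / (n_perm + 1.0)
    return pd.Series(p, index=X.columns, name="p")


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass
class IndicatorTable:
    """Per-taxon indicator summary with the full A/B/IV breakdown."""

    summary: pd.DataFrame  # taxon-indexed: best_cluster, A, B, IV, p, p_adj, is_indicator
    A: pd.DataFrame
    B: pd.DataFrame
    IV: pd.DataFrame


def indicator_table(
    X: pd.DataFrame,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    iv_threshold: float = 0.25,
    alpha: float = 0.05,
) -> IndicatorTable:
    """Full IndVal analysis: statistics, permutation test, BH correction."""
    A, B, IV, best = indval(X, labels)
    p = indval_permutation(X, labels, n_perm=n_perm, seed=seed)
    p_adj = pd.Series(bh_adjust(p), index=p.index, name="p_adj")
    rows = []
    for taxon in X.columns:
        c = best[taxon]
        iv = float(IV.loc[taxon, c])
        rows.append(
            {
                "taxon": taxon,
                "best_cluster": c,
                "A": float(A.loc[taxon, c]),
                "B": float(B.loc[taxon, c]),
                "IV": iv,
                "p": float(p[taxon]),
                "p_adj": float(p_adj[taxon]),
                "is_indicator": bool(iv > iv_threshold and p_adj[taxon] < alpha),
            }
        )
    summary = pd.DataFrame(rows).set_index("taxon")
    return IndicatorTable(summary, A, B, IV)


def indicator_lists(
    table: IndicatorTable, iv_threshold: float = 0.25, alpha: float = 0.05
) -> dict[int | str, pd.DataFrame]:
    """Significant indicators grouped by best cluster, sorted by IV desc."""
    s = table.summary
    keep = s[(s["IV"] > iv_threshold) & (s["p_adj"] < alpha)]
    out: dict[int | str, pd.DataFrame] = {}
    for c, grp in keep.groupby("best_cluster"):
        out[c] = grp.sort_values("IV", ascending=False)
    return out
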