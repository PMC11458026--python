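"""Community matrices, fuzzy c-means clustering and k-selection diagnostics.

The cell × taxon matrix of log-mean abundances is Hellinger-transformed
(square root of relative abundance), so Euclidean distance between rows is
the Hellinger distance (bounded by √2).  Assemblages are found by fuzzy
c-means on that dissimilarity matrix, i.e. the Kaufman–Rousseeuw objective

    J(U) = Σ_c [ Σ_{i,j} u_ic^r u_jc^r d_ij ] / [ 2 Σ_j u_jc^r ],

minimized over membership rows that are non-negative and sum to one.  The
membership exponent r controls fuzziness (r → 1 gives crisp k-medoids-like
partitions).  The number of clusters is informed — never auto-chosen — by
three diagnostics: mean silhouette width, Mantel correlation between the
distance matrix and the crisp partition model matrix, and a
Kelly–Gardner–Sutcliffe-style penalty on an average-linkage cluster tree.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MembershipMatrix",
    "KSelectionTable",
    "split_dominant_secondary",
    "hellinger_transform",
    "hellinger_distance",
    "fanny_cluster",
    "max_membership_map",
    "silhouette",
    "mantel_correlation",
    "kgs_penalty",
    "select_k_table",
]


def split_dominant_secondary(
    mean_raw: pd.DataFrame, threshold: float = 0.005, exclusion: set[str] | None = None
) -> tuple[list[str], list[str], list[str]]:
    """Split taxa into dominant/secondary and derive the clustering set.

    A taxon is dominant when its share of the grand total of cell means
    exceeds ``threshold``.  The clustering set is the dominant taxa minus
    the exclusion list (broad aggregates); excluded and secondary taxa stay
    available for the indicator analysis.
    Returns (dominant, secondary, clustering) each sorted by total descending.
    """
    exclusion = set(exclusion or ())
    totals = mean_raw.sum(axis=0)
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("abundance matrix is identically zero")
    rel = totals / grand
    order = totals.sort_values(ascending=False).index
    dominant = [t for t in order if rel[t] > threshold]
    secondary = [t for t in order if rel[t] <= threshold]
    clustering = [t for t in dominant if t not in exclusion]
    return dominant, secondary, clustering


def hellinger_transform(X: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Row-wise square root of relative abundance.

    Rows with zero total become all-zero rows (flagged by the caller if
    needed); all other rows have unit Euclidean norm.
    """
    arr = np.asarray(X, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative abundances cannot be Hellinger-transformed")
    totals = arr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(totals > 0, arr / np.where(totals > 0, totals, 1.0), 0.0))
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


def hellinger_distance(Y: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between Hellinger-transformed rows (≤ √2)."""
    arr = np.asarray(Y, dtype=float)
    return squareform(pdist(arr, metric="euclidean"))


@dataclass
class MembershipMatrix:
    """Fuzzy memberships U (cells × k) with the achieved objective."""

    U: np.ndarray
    r: float
    k: int
    objective: float
    n_iter: int
    converged: bool
    cell_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.cell_ids if self.cell_ids is not None else range(len(self.U))
        return pd.DataFrame(
            self.U, index=idx, columns=[f"cluster_{c + 1}" for c in range(self.k)]
        )


def _fanny_objective(U: np.ndarray, D: np.ndarray, r: float) -> float:
    Ur = U**r
    num = np.einsum("ic,jc,ij->c", Ur, Ur, D)
    den = 2.0 * Ur.sum(axis=0)
    mask = den > 0
    return float(np.sum(num[mask] / den[mask]))


def _init_membership(
    n: int, k: int, seed: int, restart: int, cell_ids: list[str] | None
) -> np.ndarray:
    """Dirichlet(1) starting memberships, streamed per cell id when known.

    Keying the row streams by cell id (not row position) makes the restart
    sequence — and hence the fitted memberships — equivariant under row
    permutation of the input matrix.
    """
    if cell_ids is None:
        rng = np.random.default_rng(np.random.SeedSequence((seed, restart)))
        return rng.dirichlet(np.ones(k), size=n)
    U = np.empty((n, k))
    for i, cid in enumerate(cell_ids):
        key = zlib.crc32(str(cid).encode())
        rng = np.random.default_rng(np.random.SeedSequence((seed, key, restart)))
        U[i] = rng.dirichlet(np.ones(k))
    return U


def _fanny_once(
    D: np.ndarray, k: int, r: float, U: np.ndarray,
    maxit: int, tol: float,
) -> tuple[np.ndarray, float, int, bool]:
    n = D.shape[0]
    obj = _fanny_objective(U, D, r)
    converged = False
    it = 0
    for it in range(1, maxit + 1):
        Ur = U**r
        colsum = Ur.sum(axis=0)  # Σ_j u_jc^r
        colsum = np.maximum(colsum, 1e-300)
        DU = D @ Ur  # (i, c): Σ_j d_ij u_jc^r
        within = np.einsum("ic,ic->c", Ur, DU) / (2.0 * colsum**2)
        # a_ic = marginal cost of moving object i toward cluster c
        A = DU / colsum - within[None, :]
        U_new = np.empty_like(U)
        small = A <= 1e-12
        exp = 1.0 / (r - 1.0)
        with np.errstate(divide="ignore", over="ignore"):
            inv = np.where(small, 0.0, A) ** (-exp)
        inv[small] = 0.0
        for i in range(n):
            if small[i].any():
                # non-positive marginal cost: commit fully to the best cluster
                U_new[i] = 0.0
                U_new[i, int(np.argmin(A[i]))] = 1.0
            else:
                U_new[i] = inv[i] / inv[i].sum()
        obj_new = _fanny_objective(U_new, D, r)
        if obj_new > obj + 1e-12:
            # fixed-point step overshot a minimum: keep the previous U
            converged = True
            break
        U = U_new
        if obj - obj_new < tol * max(obj, 1e-300):
            obj = obj_new
            converged = True
            break
        obj = obj_new
    return U, obj, it, converged


def fanny_cluster(
    D: np.ndarray,
    k: int,
    r: float = 1.2,
    seed: int = 0,
    maxit: int = 500,
    tol: float = 1e-9,
    n_restarts: int = 5,
    cell_ids: list[str] | None = None,
) -> MembershipMatrix:
    """Fuzzy c-means on a dissimilarity matrix (FANNY).

    Runs ``n_restarts`` fixed-point iterations from Dirichlet(1) random
    memberships and keeps the solution with the lowest objective.  The
    recorded objective never increases across iterations of a run.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be a symmetric square matrix")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("D must have a zero diagonal")
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    if r <= 1:
        raise ValueError("membership exponent r must exceed 1")
    best: tuple[np.ndarray, float, int, bool] | None = None
    for restart in range(n_restarts):
        U0 = _init_membership(n, k, int(seed), restart, cell_ids)
        cand = _fanny_once(D, k, r, U0, maxit, tol)
        if best is None or cand[1] < best[1]:
            best = cand
    U, obj, it, converged = best
    return MembershipMatrix(U, r, k, obj, it, converged, cell_ids)


def max_membership_map(U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Crisp label (1-based, ties to the lowest cluster index) and max value."""
    U = np.asarray(U, dtype=float)
    labels = np.argmax(U, axis=1) + 1
    return labels, U.max(axis=1)


def silhouette(D: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Silhouette widths s_i = (b_i − a_i)/max(a_i, b_i) on a distance matrix.

    a_i is the mean distance to the object's own cluster (excluding itself),
    b_i the smallest mean distance to another cluster; members of singleton
    clusters get s_i = 0 by convention.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least two clusters")
    n = len(labels)
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in clusters}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = D[i, own[own != i]].mean()
        b = min(D[i, members[c]].mean() for c in clusters if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s, float(s.mean())


def mantel_correlation(D: np.ndarray, labels: np.ndarray) -> float:
    """Pearson correlation between D and the binary partition model matrix.

    The model matrix is 0 within clusters and 1 between; both matrices are
    compared over the strict lower triangle.  Higher values mean the
    partition explains more of the distance structure.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("Mantel correlation requires at least two clusters")
    iu = np.tril_indices(len(labels), k=-1)
    d = D[iu]
    m = (labels[iu[0]] != labels[iu[1]]).astype(float)
    if d.std() == 0 or m.std() == 0:
        raise ValueError("zero variance: Mantel correlation undefined")
    return float(np.corrcoef(d, m)[0, 1])


def _cluster_spread(D: np.ndarray, labels: np.ndarray) -> float:
    """Average over clusters of the mean pairwise within-cluster distance."""
    spreads = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            spreads.append(0.0)
        else:
            sub = D[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            spreads.append(float(sub[iu].mean()))
    return float(np.mean(spreads))


def kgs_penalty(D: np.ndarray, k_range: range | list[int]) -> pd.Series:
    """Kelly–Gardner–Sutcliffe-style penalty over candidate cluster counts.

    Cuts an average-linkage tree of D at each k, computes the average
    within-cluster spread, rescales the spread sequence linearly onto
    [1, max(k_range)], and adds k.  The minimum suggests a candidate k.
    """
    D = np.asarray(D, dtype=float)
    ks = list(k_range)
    Z = linkage(squareform(D, checks=False), method="average")
    spreads = []
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust")
        spreads.append(_cluster_spread(D, labels))
    spreads = np.asarray(spreads)
    lo, hi = spreads.min(), spreads.max()
    if hi - lo < 1e-15:
        rescaled = np.ones_like(spreads)
    else:
        rescaled = 1.0 + (spreads - lo) / (hi - lo) * (max(ks) - 1.0)
    return pd.Series(rescaled + np.asarray(ks, dtype=float), index=ks, name="kgs")


@dataclass
class KSelectionTable:
    table: pd.DataFrame  # index k; columns mean_silhouette, mantel_r, kgs_penalty


def select_k_table(
    D: np.ndarray,
    k_range: range | list[int],
    r: float = 1.2,
    seed: int = 0,
    cell_ids: list[str] | None = None,
) -> KSelectionTable:
    """Run fanny at each k and tabulate the three k-selection diagnostics.

    The table reports; it never chooses.  Crisp labels (max membership) feed
    the silhouette and Mantel statistics.
    """
    ks = list(k_range)
    kgs = kgs_penalty(D, ks)
    rows = []
    for k in ks:
        member = fanny_cluster(D, k, r, seed=seed, cell_ids=cell_ids)
        labels, _ = max_membership_map(member.U)
        if len(np.unique(labels)) < 2:
            sil, mantel = np.nan, np.nan
        else:
            _, sil = silhouette(D, labels)
            mantel = mantel_correlation(D, labels)
        rows.append({"k": k, "mean_silhouette": sil, "mantel_r": mantel})
    table = pd.DataFrame(rows).set_index("k")
    table["kgs_penalty"] = kgs
    return KSelectionTable(table)
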