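"""Environmental driver ordination and inter-annual comparison.

Two PCAs summarize the per-cell environment: one on log-transformed,
centered and scaled abiotic variables (temperature, salinity, depth,
NOx = NO₃⁻+NO₂⁻, NH₄⁺, PO₄³⁻, Si(OH)₄, POM, chlorophyll a) and one on
Hellinger-transformed phyto-microplankton group abundances.  The N/P ratio
(NO₂⁻+NO₃⁻+NH₄⁺)/PO₄³⁻ is projected as a supplementary variable (its
coordinate on a dimension is its correlation with that dimension's scores).
The leading dimensions, their pairwise products and the assemblage labels
are exported as a ready-made design table for external mixed-model fitting.

The inter-annual machinery restricts the analysis to a smaller shared
polygon, re-runs grid + clustering there, and compares years by per-cluster
means and per-cell differences of raw cell means, plus a simple anomaly
series (deviation from the multi-year mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblage import fanny_cluster, hellinger_transform, max_membership_map
from .gridding import CellTable, GridSpec, build_cell_table, build_grid

__all__ = [
    "PCAResult",
    "AnomalySeries",
    "np_ratio",
    "pca",
    "project_supplementary",
    "glmm_design_export",
    "restrict_and_recluster",
    "per_cluster_means",
    "cell_difference",
    "anomaly_series",
]

ABIOTIC_VARIABLES = (
    "temperature",
    "salinity",
    "depth",
    "nox",
    "nh4",
    "po4",
    "sioh4",
    "pom",
    "chla",
)

PHYTO_GROUPS = (
    "diatoms",
    "dinoflagellates",
    "flagellates",
    "nanoflagellates",
    "ciliates",
    "chlorophytes",
    "other_phyto",
)


def np_ratio(no2, no3, nh4, po4):
    """Dissolved nitrogen-to-phosphate ratio (NO₂⁻+NO₃⁻+NH₄⁺)/PO₄³⁻.

    Returns NaN when phosphate is non-positive or any input is missing;
    values near the Redfield ratio 16 indicate balanced nutrient supply.
    Accepts scalars or aligned arrays.
    """
    no2, no3, nh4, po4 = (np.asarray(v, dtype=float) for v in (no2, no3, nh4, po4))
    num = no2 + no3 + nh4
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(po4 > 0, num / np.where(po4 > 0, po4, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class PCAResult:
    loadings: pd.DataFrame       # variables × dims
    scores: pd.DataFrame         # cells × dims (Dim.1, Dim.2, ...)
    explained_var: pd.Series     # fraction per dim
    dropped_cells: list[str]
    supplementary: dict[str, pd.Series] | None = None


def pca(X: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """Principal components of a cells × variables table.

    With ``scale`` the decomposition is of the correlation matrix, otherwise
    of the covariance matrix.  Cells with any missing value are dropped and
    reported.  Sign convention: on each dimension the variable with the
    largest absolute loading gets a positive loading.
    """
    dropped = [str(i) for i in X.index[X.isna().any(axis=1)]]
    Xc = X.dropna(axis=0)
    if len(Xc) < 2:
        raise ValueError("need at least two complete cells for a PCA")
    M = Xc.to_numpy(dtype=float)
    if center:
        M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise ValueError(
                f"zero-variance column(s) cannot be scaled: "
                f"{', '.join(Xc.columns[zero])}"
            )
        M = M / sd
    # SVD of the prepared matrix; eigenvalues of the (co)variance matrix
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    eig = s**2 / (len(Xc) - 1)
    total = eig.sum()
    loadings = Vt.T
    # deterministic sign: largest-|loading| variable positive per dim
    for j in range(loadings.shape[1]):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
    scores = M @ loadings
    dims = [f"Dim.{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=Xc.columns, columns=dims),
        scores=pd.DataFrame(scores, index=Xc.index, columns=dims),
        explained_var=pd.Series(eig / total if total > 0 else eig, index=dims),
        dropped_cells=dropped,
    )


def project_supplementary(result: PCAResult, v: pd.Series, name: str = "supp") -> pd.Series:
    """Supplementary-variable coordinates: correlation with each dim's scores."""
    v = v.reindex(result.scores.index)
    keep = v.notna()
    vv = v[keep].to_numpy(dtype=float)
    if len(vv) < 3 or np.std(vv) == 0:
        raise ValueError("supplementary variable has (near) zero variance")
    coords = {}
    for dim in result.scores.columns:
        sc = result.scores.loc[keep, dim].to_numpy()
        if np.std(sc) == 0:
            coords[dim] = 0.0
        else:
            coords[dim] = float(np.corrcoef(vv, sc)[0, 1])
    out = pd.Series(coords, name=name)
    if result.supplementary is None:
        result.supplementary = {}
    result.supplementary[name] = out
    return out


def glmm_design_export(
    cells: CellTable,
    abiotic: PCAResult,
    biotic: PCAResult,
    labels: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Design table for external mixed-model fitting, plus cross-PCA checks.

    Columns: Dim.1abiotic, Dim.2abiotic, Dim.1biotic, the two interaction
    products, the cluster label (random-effect grouping) and every taxon's
    raw cell mean as candidate responses.  The second return value is the
    correlation matrix between the retained dimensions of the two PCAs
    (components of one PCA are orthogonal by construction; across PCAs they
    need checking).
    """
    idx = cells.mean_raw.index
    for name, res in (("abiotic", abiotic), ("biotic", biotic)):
        if not res.scores.index.isin(idx).all():
            raise ValueError(f"{name} PCA scores refer to unknown cells")
    design = pd.DataFrame(index=idx)
    design["Dim.1abiotic"] = abiotic.scores["Dim.1"]
    design["Dim.2abiotic"] = abiotic.scores["Dim.2"]
    design["Dim.1biotic"] = biotic.scores["Dim.1"]
    design["Dim.1abiotic:Dim.1biotic"] = design["Dim.1abiotic"] * design["Dim.1biotic"]
    design["Dim.2abiotic:Dim.1biotic"] = design["Dim.2abiotic"] * design["Dim.1biotic"]
    design["cluster"] = pd.Series(labels, index=idx)
    design = design.join(cells.mean_raw)
    shared = abiotic.scores.index.intersection(biotic.scores.index)
    cross = pd.DataFrame(
        np.corrcoef(
            np.column_stack(
                [
                    abiotic.scores.loc[shared, ["Dim.1", "Dim.2"]],
                    biotic.scores.loc[shared, ["Dim.1"]],
                ]
            ),
            rowvar=False,
        ),
        index=["Dim.1abiotic", "Dim.2abiotic", "Dim.1biotic"],
        columns=["Dim.1abiotic", "Dim.2abiotic", "Dim.1biotic"],
    )
    return design, cross


def restrict_and_recluster(
    datasets,
    polygon,
    cell_size_deg: float,
    k: int,
    r: float = 1.2,
    B: int = 10_000,
    seed: int = 0,
    clustering_taxa: list[str] | None = None,
    origin: tuple[float, float] | None = None,
):
    """Re-run grid → cell table → fuzzy clustering inside a restricted polygon.

    Used for the inter-annual comparison, where only the spatial overlap of
    two surveys is analyzed.  Returns (GridSpec, CellTable, MembershipMatrix,
    crisp labels as a Series).
    """
    grid = build_grid(polygon, cell_size_deg, origin)
    cells = build_cell_table(datasets, grid, polygon, B=B, seed=seed)
    X = cells.mean_log
    if clustering_taxa is not None:
        X = X[[t for t in clustering_taxa if t in X.columns]]
    Y = hellinger_transform(X)
    from .assemblage import hellinger_distance

    D = hellinger_distance(Y)
    member = fanny_cluster(D, k, r, seed=seed, cell_ids=list(X.index))
    crisp, _ = max_membership_map(member.U)
    labels = pd.Series(crisp, index=X.index, name="cluster")
    return grid, cells, member, labels


def per_cluster_means(cells: CellTable, labels: pd.Series) -> pd.DataFrame:
    """Arithmetic mean of raw cell means per cluster × taxon."""
    labels = labels.reindex(cells.mean_raw.index)
    if labels.isna().any():
        raise ValueError("labels must cover every cell")
    return cells.mean_raw.groupby(labels).mean()


def cell_difference(
    year_a: CellTable, year_b: CellTable
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Per-cell, per-taxon differences b − a on the shared grid.

    Returns (diff matrix on shared cells, per-cell total difference,
    {"only_a": [...], "only_b": [...]} for cells present in one year only).
    Taxa must be harmonized upstream; the union of columns is compared with
    missing columns treated as zero abundance.
    """
    a, b = year_a.mean_raw, year_b.mean_raw
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("the two cell tables share no grid cells")
    taxa = a.columns.union(b.columns)
    a_al = a.reindex(index=shared, columns=taxa, fill_value=0.0)
    b_al = b.reindex(index=shared, columns=taxa, fill_value=0.0)
    diff = b_al - a_al
    only = {
        "only_a": [c for c in a.index if c not in b.index],
        "only_b": [c for c in b.index if c not in a.index],
    }
    return diff, diff.sum(axis=1), only


@dataclass
class AnomalySeries:
    table: pd.DataFrame  # year-indexed: value, anomaly, standardized
    long_term_mean: float
    sd: float


def anomaly_series(values_by_year: pd.Series | dict[int, float]) -> AnomalySeries:
    """Anomalies relative to the mean over available years.

    standardized = anomaly / sample sd (n−1).  Years with missing values are
    omitted; at least two years are required.
    """
    s = pd.Series(values_by_year, dtype=float).dropna().sort_index()
    if len(s) < 2:
        raise ValueError("need at least two years with values")
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    anom = s - mean
    std = anom / sd if sd > 0 else anom * np.nan
    table = pd.DataFrame({"value": s, "anomaly": anom, "standardized": std})
    table.index.name = "year"
    return AnomalySeries(table, mean, sd)
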