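"""Pipeline configuration.

Every tunable threshold of the analysis is a named key with its standard
default: bootstrap iterations, fuzzy membership exponent, dominance cut-off
for the dominant/secondary taxon split, indicator-value threshold and the
FDR level for the permutation tests, plus the variogram/grid-search settings
used for optimal-cell-size selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Broad taxonomic aggregates excluded from clustering (they double-count
#: their member taxa) but retained for indicator analysis.
DEFAULT_EXCLUSION = ("Copepoda", "Calanoida", "Crustacea nauplius")


@dataclass
class PipelineConfig:
    """Bundle of all pipeline parameters.

    Parameters
    ----------
    seed : int
        Master seed; every random operation downstream derives its stream
        from this single value.
    bootstrap_B : int
        Bootstrap replicates per grid-cell mean.
    membership_exponent : float
        Fuzziness exponent ``r`` (> 1) of the fuzzy c-means objective.
    k : int
        Number of clusters for the final run (a configured judgement call;
        the tool never auto-selects).
    k_range : tuple[int, int]
        Inclusive range of cluster counts scanned by the k-selection table.
    dominance_threshold : float
        Relative-abundance fraction above which a taxon is "dominant".
    indval_threshold : float
        Minimum indicator value (0-1 scale) for a taxon to be reported.
    alpha : float
        FDR level applied to Benjamini-Hochberg adjusted permutation p-values.
    n_perm : int
        Label permutations for the indicator-value test.
    clustering_exclusion_list : tuple[str, ...]
        Taxa excluded from the clustering set even when dominant.
    variogram_family : str
        ``"spherical"`` or ``"exponential"``.
    trend_order : int
        Polynomial trend order (0, 1 or 2) removed before variography.
    lopt_search : tuple[float, float, float]
        ``(v_min, v_max, step)`` in km for the cell-size search.
    block_discretization : int
        Lattice side ``m`` used to regularize the variogram over a cell.
    min_stations_per_cell : int
        Minimum stations per cell, required of every dataset.
    """

    seed: int = 20080127
    bootstrap_B: int = 10_000
    membership_exponent: float = 1.2
    k: int = 5
    k_range: tuple[int, int] = (2, 8)
    dominance_threshold: float = 0.005
    indval_threshold: float = 0.25
    alpha: float = 0.05
    n_perm: int = 999
    clustering_exclusion_list: tuple[str, ...] = DEFAULT_EXCLUSION
    variogram_family: str = "spherical"
    trend_order: int = 0
    lopt_search: tuple[float, float, float] = (10.0, 200.0, 0.5)
    block_discretization: int = 10
    min_stations_per_cell: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.dominance_threshold < 1:
            raise ValueError("dominance_threshold must lie in (0, 1)")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.membership_exponent <= 1:
            raise ValueError("membership_exponent must exceed 1")
        if self.bootstrap_B < 1 or self.n_perm < 1:
            raise ValueError("bootstrap_B and n_perm must be positive")
        v_min, v_max, step = self.lopt_search
        if not (v_min < v_max and step > 0):
            raise ValueError("lopt_search requires v_min < v_max and step > 0")
        if self.variogram_family not in ("spherical", "exponential"):
            raise ValueError(f"unknown variogram family {self.variogram_family!r}")
        if self.trend_order not in (0, 1, 2):
            raise ValueError("trend_order must be 0, 1 or 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("k_range", "lopt_search", "clustering_exclusion_list"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
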