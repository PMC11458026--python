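"""End-to-end orchestration of the assemblage pipeline.

Order of operations: simulate (or load) surveys → per-taxon variograms and
information curves → consensus optimal cell size → grid + bootstrap cell
table → dominant/secondary split → Hellinger + fuzzy clustering with
k-selection diagnostics → indicator taxa → environmental driver PCAs and
design export → restricted-polygon re-clustering and inter-annual
difference tables.  Every stage is also callable on its own; this module
wires them with a single seed and writes the text artifacts the CLI exposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from . import assemblage as asm
from . import drivers as drv
from . import geostat as gs
from . import gridding as gr
from . import indicators as ind
from .config import PipelineConfig
from .geometry import km_to_degrees, lonlat_to_km, polygon_anchor, polygon_area_km2
from .surveys import SurveyDataset
from .synth import SyntheticScenario, SyntheticTruth, scenario_default, simulate_survey

__all__ = ["PipelineResult", "run_pipeline", "station_relative_abundance",
           "variogram_stage", "clustering_stage"]


def station_relative_abundance(datasets: list[SurveyDataset]) -> pd.Series:
    """Grand relative abundance per taxon over all stations of all datasets."""
    totals: dict[str, float] = {}
    for ds in datasets:
        frame = ds.to_frame()
        for t in ds.taxa:
            totals[t] = totals.get(t, 0.0) + float(frame[t].sum())
    s = pd.Series(totals)
    return s / s.sum()


def variogram_stage(
    datasets: list[SurveyDataset],
    polygon: Polygon,
    config: PipelineConfig,
    taxa: list[str] | None = None,
) -> tuple[dict[str, gs.VariogramModel], dict[str, gs.InformationCurve], gs.ConsensusLopt]:
    """Fit a variogram and information curve per taxon; take the consensus.

    Log(x+1) station abundances are the variography variable.  Each taxon
    uses the stations of the dataset that carries it (pooled when several
    do) and that dataset's station density inside the polygon.
    """
    anchor = polygon_anchor(polygon)
    area = polygon_area_km2(polygon)
    if taxa is None:
        rel = station_relative_abundance(datasets)
        taxa = sorted(rel.index[rel > config.dominance_threshold])
    models: dict[str, gs.VariogramModel] = {}
    curves: dict[str, gs.InformationCurve] = {}
    for taxon in taxa:
        carriers = [ds for ds in datasets if taxon in ds.taxa]
        if not carriers:
            continue
        pts_list, vals_list, n_st = [], [], 0
        for ds in carriers:
            frame = ds.to_frame()
            x, y = lonlat_to_km(
                frame["lon"].to_numpy(), frame["lat"].to_numpy(), *anchor
            )
            pts_list.append(np.column_stack([x, y]))
            vals_list.append(np.log1p(frame[taxon].to_numpy()))
            n_st += len(frame)
        pts = np.vstack(pts_list)
        vals = np.concatenate(vals_list)
        try:
            emp = gs.empirical_variogram(
                pts, vals, n_lags=15, trend_order=config.trend_order
            )
            model = gs.fit_variogram(emp, config.variogram_family, seed=config.seed)
        except (ValueError, RuntimeError):
            continue
        if model.partial_sill <= 1e-9:
            # pure nugget: no spatial structure to preserve, skip for Lopt
            models[taxon] = model
            continue
        density = n_st / area
        curves[taxon] = gs.information_curve(
            model, density, config.lopt_search, config.block_discretization
        )
        models[taxon] = model
    if not curves:
        raise RuntimeError("no taxon yielded a usable information curve")
    consensus = gs.consensus_lopt(curves)
    return models, curves, consensus


def clustering_stage(
    cells: gr.CellTable, config: PipelineConfig
) -> tuple[list[str], list[str], list[str], np.ndarray, asm.MembershipMatrix,
           pd.Series, asm.KSelectionTable]:
    """Dominance split, Hellinger distance, k-selection table, final fanny run."""
    dominant, secondary, clustering = asm.split_dominant_secondary(
        cells.mean_raw, config.dominance_threshold,
        set(config.clustering_exclusion_list),
    )
    X = cells.mean_log[clustering]
    Y = asm.hellinger_transform(X)
    D = asm.hellinger_distance(Y)
    cell_ids = list(X.index)
    k_lo, k_hi = config.k_range
    ktable = asm.select_k_table(
        D, range(k_lo, k_hi + 1), config.membership_exponent,
        seed=config.seed, cell_ids=cell_ids,
    )
    member = asm.fanny_cluster(
        D, config.k, config.membership_exponent, seed=config.seed, cell_ids=cell_ids
    )
    crisp, maxu = asm.max_membership_map(member.U)
    labels = pd.Series(crisp, index=cell_ids, name="cluster")
    return dominant, secondary, clustering, D, member, labels, ktable


@dataclass
class PipelineResult:
    config: PipelineConfig
    scenario: SyntheticScenario
    truth: SyntheticTruth
    datasets: dict[str, SurveyDataset]
    env: pd.DataFrame
    models: dict[str, gs.VariogramModel]
    curves: dict[str, gs.InformationCurve]
    consensus: gs.ConsensusLopt
    cell_size_deg: float
    grid: gr.GridSpec
    cells: gr.CellTable
    dominant: list[str]
    secondary: list[str]
    clustering_taxa: list[str]
    D: np.ndarray
    membership: asm.MembershipMatrix
    labels: pd.Series
    ktable: asm.KSelectionTable
    indicators: ind.IndicatorTable
    env_cells: pd.DataFrame
    abiotic_pca: drv.PCAResult
    biotic_pca: drv.PCAResult
    np_supplementary: pd.Series
    design: pd.DataFrame
    cross_pca_corr: pd.DataFrame
    inter: dict = field(default_factory=dict)


def _interannual_stage(result: "PipelineResult", config: PipelineConfig) -> dict:
    """Restricted-polygon re-clustering at k=2 and year-to-year differences.

    The comparison polygon is the southern part of the study area, chosen to
    straddle the two southernmost latent regions; the second year is the
    same scenario re-simulated with a shifted seed.
    """
    truth = result.truth
    centers = truth.region_centers
    lat_sorted = np.sort(centers[:, 1])
    cut = float((lat_sorted[1] + lat_sorted[2]) / 2.0) if len(lat_sorted) >= 3 else float(
        centers[:, 1].mean()
    )
    minx, miny, maxx, maxy = result.scenario.polygon.bounds
    south = result.scenario.polygon.intersection(box(minx, miny, maxx, cut))
    year_b_scenario = scenario_default(config.seed + 1) if isinstance(
        result.scenario, SyntheticScenario
    ) else None
    datasets_a = list(result.datasets.values())
    grid2, cells_a, member2, labels2 = drv.restrict_and_recluster(
        datasets_a, south, result.cell_size_deg, k=2,
        r=config.membership_exponent, B=config.bootstrap_B, seed=config.seed,
        clustering_taxa=result.clustering_taxa,
    )
    datasets_b_map, _, _ = simulate_survey(year_b_scenario)
    cells_b = gr.build_cell_table(
        list(datasets_b_map.values()), grid2, south,
        B=config.bootstrap_B, seed=config.seed + 1,
    )
    diff, total_diff, missing = drv.cell_difference(cells_a, cells_b)
    pcm_a = drv.per_cluster_means(cells_a, labels2)
    # multi-year anomaly input: a synthetic temperature series
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1998)))
    years = pd.Series(
        8.0 + 0.04 * np.arange(25) + rng.normal(0, 0.4, 25),
        index=range(1998, 2023),
    )
    anomalies = drv.anomaly_series(years)
    return {
        "polygon": south,
        "grid": grid2,
        "cells_a": cells_a,
        "cells_b": cells_b,
        "membership": member2,
        "labels": labels2,
        "diff": diff,
        "total_diff": total_diff,
        "missing_cells": missing,
        "per_cluster_means_a": pcm_a,
        "anomalies": anomalies,
    }


def run_pipeline(
    config: PipelineConfig | None = None,
    scenario: SyntheticScenario | None = None,
    with_interannual: bool = True,
) -> PipelineResult:
    """Run the full pipeline on a (default) synthetic scenario."""
    config = config or PipelineConfig()
    scenario = scenario or scenario_default(config.seed)
    datasets_map, env, truth = simulate_survey(scenario)
    datasets = list(datasets_map.values())
    polygon = scenario.polygon

    models, curves, consensus = variogram_stage(datasets, polygon, config)
    cell_size_deg = km_to_degrees(consensus.consensus)

    grid = gr.build_grid(polygon, cell_size_deg)
    for ds, (empty, _) in gr.empty_cell_report(grid, datasets, polygon).items():
        consensus.empty_cell_counts[ds] = empty
    cells = gr.build_cell_table(
        datasets, grid, polygon, B=config.bootstrap_B, seed=config.seed
    )

    dominant, secondary, clustering, D, member, labels, ktable = clustering_stage(
        cells, config
    )

    indicator_taxa = cells.mean_raw  # dominant + secondary + excluded aggregates
    itable = ind.indicator_table(
        indicator_taxa,
        labels.to_numpy(),
        n_perm=config.n_perm,
        seed=config.seed,
        iv_threshold=config.indval_threshold,
        alpha=config.alpha,
    )

    env_cells = gr.aggregate_env_table(
        env, grid, polygon, B=config.bootstrap_B, seed=config.seed,
        cells=cells.cell_ids,
    )
    abiotic_in = env_cells[["temperature", "salinity", "depth", "nh4", "po4",
                            "sioh4", "pom", "chla"]].copy()
    abiotic_in["nox"] = env_cells["no3"] + env_cells["no2"]
    abiotic_in = np.log1p(abiotic_in[list(drv.ABIOTIC_VARIABLES)])
    abiotic_pca = drv.pca(abiotic_in, center=True, scale=True)
    biotic_in = asm.hellinger_transform(env_cells[list(drv.PHYTO_GROUPS)])
    biotic_pca = drv.pca(biotic_in, center=True, scale=False)
    np_cell = pd.Series(
        drv.np_ratio(env_cells["no2"], env_cells["no3"], env_cells["nh4"],
                     env_cells["po4"]),
        index=env_cells.index, name="np_ratio",
    )
    np_supp = drv.project_supplementary(abiotic_pca, np_cell, name="np_ratio")
    design, cross = drv.glmm_design_export(cells, abiotic_pca, biotic_pca, labels)

    result = PipelineResult(
        config=config, scenario=scenario, truth=truth, datasets=datasets_map,
        env=env, models=models, curves=curves, consensus=consensus,
        cell_size_deg=cell_size_deg, grid=grid, cells=cells,
        dominant=dominant, secondary=secondary, clustering_taxa=clustering,
        D=D, membership=member, labels=labels, ktable=ktable,
        indicators=itable, env_cells=env_cells,
        abiotic_pca=abiotic_pca, biotic_pca=biotic_pca,
        np_supplementary=np_supp, design=design, cross_pca_corr=cross,
    )
    if with_interannual:
        result.inter = _interannual_stage(result, config)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the primary text artifacts of a pipeline run.

    Outputs are deterministic byte-for-byte for a fixed config and inputs:
    CSVs via pandas with fixed column order, JSON with sorted keys.
    """
    from .io import write_grid_geojson, write_polygon, write_survey_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ds in result.datasets.items():
        write_survey_csv(ds, outdir / f"stations_{name}.csv")
    result.env.to_csv(outdir / "environment.csv", index=False)
    write_polygon(result.scenario.polygon, outdir / "polygon.wkt")

    lopt = {
        "consensus_km": result.consensus.consensus,
        "consensus_deg": result.cell_size_deg,
        "max_relative_f_loss": result.consensus.max_relative_f_loss,
        "per_taxon_lopt_km": result.consensus.per_taxon_lopt,
        "empty_cells": result.consensus.empty_cell_counts,
    }
    (outdir / "lopt.json").write_text(json.dumps(lopt, indent=1, sort_keys=True) + "\n")

    curves_frames = []
    for taxon, c in sorted(result.curves.items()):
        frame = pd.DataFrame(
            {"taxon": taxon, "v_km": c.v, "n_bar": c.n_bar, "PN": c.PN,
             "PS": c.PS, "f": c.f}
        )
        curves_frames.append(frame)
    pd.concat(curves_frames, ignore_index=True).to_csv(
        outdir / "information_curves.csv", index=False
    )

    result.cells.mean_raw.rename_axis("cell_id").to_csv(outdir / "cell_means_raw.csv")
    result.cells.mean_log.rename_axis("cell_id").to_csv(outdir / "cell_means_log.csv")
    result.cells.frame.rename_axis("cell_id").to_csv(outdir / "cell_summary.csv")

    result.membership.to_frame().rename_axis("cell_id").to_csv(
        outdir / "membership.csv"
    )
    labels_frame = result.labels.to_frame()
    labels_frame["max_membership"] = result.membership.U.max(axis=1)
    labels_frame.rename_axis("cell_id").to_csv(outdir / "clusters.csv")
    result.ktable.table.to_csv(outdir / "k_selection.csv")
    write_grid_geojson(
        result.grid, result.cells,
        {c: int(v) for c, v in result.labels.items()},
        outdir / "grid_clusters.geojson",
        max_membership={c: float(v) for c, v in
                        zip(result.labels.index, result.membership.U.max(axis=1))},
    )

    result.indicators.summary.to_csv(outdir / "indicators.csv")

    result.abiotic_pca.loadings.rename_axis("variable").to_csv(
        outdir / "pca_abiotic_loadings.csv"
    )
    result.abiotic_pca.scores.rename_axis("cell_id").to_csv(
        outdir / "pca_abiotic_scores.csv"
    )
    result.biotic_pca.loadings.rename_axis("variable").to_csv(
        outdir / "pca_biotic_loadings.csv"
    )
    result.biotic_pca.scores.rename_axis("cell_id").to_csv(
        outdir / "pca_biotic_scores.csv"
    )
    pd.DataFrame(
        {
            "abiotic": result.abiotic_pca.explained_var,
            "biotic": result.biotic_pca.explained_var,
        }
    ).rename_axis("dim").to_csv(outdir / "pca_explained_variance.csv")
    result.np_supplementary.rename_axis("dim").to_frame().to_csv(
        outdir / "np_supplementary.csv"
    )
    result.design.rename_axis("cell_id").to_csv(outdir / "glmm_design.csv")
    result.cross_pca_corr.rename_axis("dim").to_csv(outdir / "cross_pca_corr.csv")

    if result.inter:
        inter = result.inter
        inter["diff"].rename_axis("cell_id").to_csv(outdir / "interannual_diff.csv")
        inter["total_diff"].rename("total_diff").rename_axis("cell_id").to_csv(
            outdir / "interannual_total_diff.csv"
        )
        inter["per_cluster_means_a"].rename_axis("cluster").to_csv(
            outdir / "interannual_cluster_means.csv"
        )
        inter["anomalies"].table.to_csv(outdir / "anomalies.csv")
        inter["labels"].rename_axis("cell_id").to_frame().to_csv(
            outdir / "interannual_clusters.csv"
        )
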