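"""Synthetic winter plankton surveys with known spatial structure.

The generator emulates the situation the pipeline is built for: several
point surveys of very different density and gear (sparse net stations for
mesozooplankton and fish larvae, a dense along-track egg pump), taken over
a shelf-sea polygon that is partitioned into K latent assemblage regions.

Abundance is log-normal with a multiplicative spatially-autocorrelated
field: for taxon t at station s in region g,

    N_ts = Bernoulli(1 − p0_t) · exp( μ_{t,g} + Z_t(s) ),

where Z_t is a zero-mean Gaussian random field whose covariance derives
from a semivariogram (nugget c0, partial sill c1, range a).  Planted
indicator taxa are hard-zero outside their home region, aggregate taxa
(Copepoda, Calanoida, Crustacea nauplius) are sums of their member taxa,
and environmental covariates are region-linked log-normal variables riding
on a shared field.  Every quantity a downstream stage estimates — regions,
variogram parameters, indicators — is returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import Point, Polygon

from .geometry import lonlat_to_km, polygon_anchor
from .geostat import VariogramModel
from .surveys import StationSample, SurveyDataset

__all__ = [
    "TaxonProfile",
    "DatasetSpec",
    "SyntheticScenario",
    "SyntheticTruth",
    "simulate_grf",
    "simulate_survey",
    "scenario_default",
    "DEFAULT_POLYGON_WKT",
]

DEFAULT_POLYGON_WKT = (
    "POLYGON ((-1 50.5, 0.5 49.5, 8 49.5, 8 55.5, -1 55.5, -1 50.5))"
)


@dataclass
class TaxonProfile:
    """Generating parameters of one taxon.

    ``log_mean`` is either a scalar (uniform across regions) or a per-region
    mapping {region (1-based) → μ}.  ``planted_indicator_for`` makes the
    taxon a hard zero outside that region.  ``members`` turns the taxon into
    an aggregate (sum of the listed taxa; no field of its own).
    ``log_sd`` rescales the spatial field to that standard deviation
    (None: use the variogram's own sill; 0: no spatial noise at all).
    """

    name: str
    log_mean: float | dict[int, float] = 0.0
    log_sd: float | None = None
    zero_inflation: float = 0.0
    planted_indicator_for: int | None = None
    members: tuple[str, ...] = ()
    dataset: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.zero_inflation < 1:
            raise ValueError(f"{self.name}: zero_inflation must lie in [0, 1)")
        if self.log_sd is not None and self.log_sd < 0:
            raise ValueError(f"{self.name}: log_sd must be >= 0")

    @property
    def is_aggregate(self) -> bool:
        return len(self.members) > 0

    def mu(self, region: int) -> float:
        if isinstance(self.log_mean, dict):
            return float(self.log_mean.get(region, -np.inf))
        return float(self.log_mean)


@dataclass
class DatasetSpec:
    name: str
    n_stations: int
    layout: str = "scatter"  # or "transect"

    def __post_init__(self) -> None:
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if self.layout not in ("scatter", "transect"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass
class SyntheticScenario:
    polygon: Polygon
    n_regions: int
    taxa: list[TaxonProfile]
    datasets: list[DatasetSpec]
    variogram: VariogramModel
    seed: int = 0
    env_stations_dataset: str | None = None  # default: first scatter dataset

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("need at least one region")
        names = {t.name for t in self.taxa}
        for t in self.taxa:
            for m in t.members:
                if m not in names:
                    raise ValueError(f"aggregate {t.name}: unknown member {m}")
        ds_names = {d.name for d in self.datasets}
        for t in self.taxa:
            if t.dataset is not None and t.dataset not in ds_names:
                raise ValueError(f"taxon {t.name}: unknown dataset {t.dataset}")


@dataclass
class SyntheticTruth:
    """Ground truth the pipeline is supposed to recover."""

    region_centers: np.ndarray  # (K, 2) lon/lat
    anchor: tuple[float, float]
    station_regions: dict[str, pd.Series]
    variogram: VariogramModel
    planted_indicators: dict[str, int]
    env_coefficients: dict[str, dict[str, float]]

    def region_of(self, lon, lat) -> np.ndarray:
        """1-based region label of arbitrary points (nearest Voronoi center)."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        x, y = lonlat_to_km(lon, lat, *self.anchor)
        cx, cy = lonlat_to_km(self.region_centers[:, 0], self.region_centers[:, 1], *self.anchor)
        d2 = (x[:, None] - cx[None, :]) ** 2 + (y[:, None] - cy[None, :]) ** 2
        return np.argmin(d2, axis=1) + 1


def simulate_grf(
    points_km: np.ndarray,
    model: VariogramModel,
    seed: int | np.random.Generator = 0,
    size: int = 1,
) -> np.ndarray:
    """Draw zero-mean Gaussian random field(s) at the given planar points.

    The covariance is C(h) = c1 − γ_struct(h) for h > 0 and c0 + c1 on the
    diagonal, i.e. the nugget appears as uncorrelated point-scale variance.
    Returns shape (n,) for size=1, else (size, n).  Deterministic given the
    seed; a jitter retry guards against numerically indefinite matrices.
    """
    pts = np.asarray(points_km, dtype=float)
    n = len(pts)
    if n > 2000:
        raise ValueError("simulate_grf supports at most 2000 points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model.sill == 0:
        out = np.zeros((size, n))
        return out[0] if size == 1 else out
    diff = pts[:, None, :] - pts[None, :, :]
    h = np.sqrt((diff**2).sum(axis=-1))
    C = model.partial_sill - model.gamma_struct(h)
    np.fill_diagonal(C, model.sill)
    L = None
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(C + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    if L is None:
        raise np.linalg.LinAlgError(
            "covariance matrix not positive definite even after jitter"
        )
    z = (L @ rng.standard_normal((n, size))).T
    return z[0] if size == 1 else z


def _region_centers(polygon: Polygon, K: int, rng: np.random.Generator) -> np.ndarray:
    """K well-spread Voronoi seed points: k-means centers of a uniform sample."""
    from sklearn.cluster import KMeans

    pts = _scatter_points(polygon, 2000, rng)
    if K == 1:
        return pts.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=K, n_init=4, random_state=int(rng.integers(2**31)))
    km.fit(pts)
    centers = km.cluster_centers_
    return centers[np.lexsort((centers[:, 1], centers[:, 0]))]


def _scatter_points(polygon: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = polygon.bounds
    out: list[tuple[float, float]] = []
    while len(out) < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(4 * n, 2))
        for lon, lat in cand:
            if polygon.covers(Point(lon, lat)):
                out.append((lon, lat))
                if len(out) == n:
                    break
    return np.asarray(out)


def _transect_points(polygon: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Dense stations along jittered east-west parallel tracks (pump-style)."""
    minx, miny, maxx, maxy = polygon.bounds
    n_tracks = max(3, int(round(np.sqrt(n / 6.0))))
    spacing = (maxy - miny) / n_tracks
    pool: list[tuple[float, float]] = []
    per_track = 40 * max(1, n // n_tracks)
    for i in range(n_tracks):
        lat0 = miny + (i + 0.5) * spacing + rng.uniform(-0.2, 0.2) * spacing
        lons = np.linspace(minx, maxx, per_track) + rng.uniform(
            -0.5, 0.5, per_track
        ) * (maxx - minx) / per_track
        lats = lat0 + rng.normal(0.0, 0.03 * spacing, per_track)
        for lon, lat in zip(lons, lats):
            if polygon.covers(Point(lon, lat)):
                pool.append((lon, lat))
    pool_arr = np.asarray(pool)
    if len(pool_arr) < n:
        extra = _scatter_points(polygon, n - len(pool_arr), rng)
        pool_arr = np.vstack([pool_arr, extra])
    idx = rng.choice(len(pool_arr), size=n, replace=False)
    return pool_arr[np.sort(idx)]


# region-linked log-normal environmental variables:
# log(value) = log_base + region_coef · (region score) + field_coef · F + noise_sd · ε
_ENV_SPEC: dict[str, dict[str, float]] = {
    "temperature": {"log_base": np.log(8.0), "region_coef": -0.08, "field_coef": 0.08, "noise_sd": 0.03},
    "salinity": {"log_base": np.log(34.0), "region_coef": 0.004, "field_coef": 0.004, "noise_sd": 0.002},
    "depth": {"log_base": np.log(45.0), "region_coef": 0.15, "field_coef": 0.10, "noise_sd": 0.10},
    "no3": {"log_base": np.log(8.0), "region_coef": 0.25, "field_coef": 0.20, "noise_sd": 0.15},
    "no2": {"log_base": np.log(0.4), "region_coef": 0.20, "field_coef": 0.15, "noise_sd": 0.15},
    "nh4": {"log_base": np.log(1.5), "region_coef": 0.18, "field_coef": 0.15, "noise_sd": 0.15},
    "po4": {"log_base": np.log(0.6), "region_coef": 0.12, "field_coef": 0.10, "noise_sd": 0.10},
    "sioh4": {"log_base": np.log(6.0), "region_coef": 0.22, "field_coef": 0.15, "noise_sd": 0.15},
    "pom": {"log_base": np.log(1.2), "region_coef": 0.15, "field_coef": 0.12, "noise_sd": 0.12},
    "chla": {"log_base": np.log(0.8), "region_coef": -0.20, "field_coef": 0.18, "noise_sd": 0.15},
}

PHYTO_GROUPS = (
    "diatoms",
    "dinoflagellates",
    "flagellates",
    "nanoflagellates",
    "ciliates",
    "chlorophytes",
    "other_phyto",
)


def simulate_survey(
    scenario: SyntheticScenario,
) -> tuple[dict[str, SurveyDataset], pd.DataFrame, SyntheticTruth]:
    """Generate all survey datasets, the environment table and the truth.

    A pure function of the scenario (including its seed): repeated calls
    return identical data.
    """
    master = np.random.SeedSequence(scenario.seed)
    ss_regions, ss_stations, ss_fields, ss_zero, ss_env = master.spawn(5)
    polygon = scenario.polygon
    anchor = polygon_anchor(polygon)
    K = scenario.n_regions

    centers = _region_centers(polygon, K, np.random.default_rng(ss_regions))
    truth = SyntheticTruth(
        region_centers=centers,
        anchor=anchor,
        station_regions={},
        variogram=scenario.variogram,
        planted_indicators={
            t.name: t.planted_indicator_for
            for t in scenario.taxa
            if t.planted_indicator_for is not None
        },
        env_coefficients={k: dict(v) for k, v in _ENV_SPEC.items()},
    )

    station_rngs = {d.name: np.random.default_rng(s) for d, s in
                    zip(scenario.datasets, ss_stations.spawn(len(scenario.datasets)))}
    field_seeds = ss_fields.spawn(len(scenario.datasets))
    zero_rngs = {d.name: np.random.default_rng(s) for d, s in
                 zip(scenario.datasets, ss_zero.spawn(len(scenario.datasets)))}

    sd_scale = None
    sill = scenario.variogram.sill
    datasets: dict[str, SurveyDataset] = {}
    env_positions: np.ndarray | None = None
    env_dataset = scenario.env_stations_dataset
    if env_dataset is None:
        scatter = [d for d in scenario.datasets if d.layout == "scatter"]
        env_dataset = (scatter[0] if scatter else scenario.datasets[0]).name

    for d_idx, dspec in enumerate(scenario.datasets):
        rng = station_rngs[dspec.name]
        if dspec.layout == "scatter":
            pos = _scatter_points(polygon, dspec.n_stations, rng)
        else:
            pos = _transect_points(polygon, dspec.n_stations, rng)
        regions = truth.region_of(pos[:, 0], pos[:, 1])
        sids = [f"{dspec.name}-{i:04d}" for i in range(dspec.n_stations)]
        truth.station_regions[dspec.name] = pd.Series(regions, index=sids)
        if dspec.name == env_dataset:
            env_positions = pos

        own_taxa = [
            t for t in scenario.taxa
            if not t.is_aggregate and (t.dataset is None or t.dataset == dspec.name)
        ]
        x, y = lonlat_to_km(pos[:, 0], pos[:, 1], *anchor)
        pts_km = np.column_stack([x, y])
        # one Cholesky per dataset, independent field per taxon
        taxon_field_seeds = field_seeds[d_idx].spawn(len(own_taxa))
        abund = {}
        zrng = zero_rngs[dspec.name]
        for t, fseed in zip(own_taxa, taxon_field_seeds):
            if t.log_sd == 0 or sill == 0:
                Z = np.zeros(dspec.n_stations)
            else:
                Z = simulate_grf(pts_km, scenario.variogram,
                                 np.random.default_rng(fseed))
                if t.log_sd is not None:
                    Z = Z * (t.log_sd / np.sqrt(sill))
            mu = np.array([t.mu(g) for g in regions])
            if t.planted_indicator_for is not None:
                mu = np.where(regions == t.planted_indicator_for, mu, -np.inf)
            keep = (
                zrng.random(dspec.n_stations) >= t.zero_inflation
                if t.zero_inflation > 0
                else np.ones(dspec.n_stations, dtype=bool)
            )
            with np.errstate(over="ignore"):
                vals = np.where(np.isneginf(mu), 0.0, np.exp(mu + Z)) * keep
            abund[t.name] = vals
        for t in scenario.taxa:
            if t.is_aggregate and (t.dataset is None or t.dataset == dspec.name):
                present = [m for m in t.members if m in abund]
                if present:
                    abund[t.name] = np.sum([abund[m] for m in present], axis=0)
        stations = [
            StationSample(
                sid,
                float(pos[i, 0]),
                float(pos[i, 1]),
                {name: float(vals[i]) for name, vals in abund.items()},
            )
            for i, sid in enumerate(sids)
        ]
        datasets[dspec.name] = SurveyDataset(dspec.name, stations)

    # environment: region-linked log-normal variables + a shared random field
    assert env_positions is not None
    env_rng = np.random.default_rng(ss_env)
    ex, ey = lonlat_to_km(env_positions[:, 0], env_positions[:, 1], *anchor)
    env_km = np.column_stack([ex, ey])
    shared_field = simulate_grf(env_km, scenario.variogram, env_rng)
    shared_field = shared_field / max(np.sqrt(sill), 1e-12)
    env_regions = truth.region_of(env_positions[:, 0], env_positions[:, 1])
    region_score = env_regions - (K + 1) / 2.0  # centered region index
    env_sids = [f"{env_dataset}-{i:04d}" for i in range(len(env_positions))]
    env = pd.DataFrame(
        {
            "station_id": env_sids,
            "lon": env_positions[:, 0],
            "lat": env_positions[:, 1],
        }
    )
    for var, spec in _ENV_SPEC.items():
        log_v = (
            spec["log_base"]
            + spec["region_coef"] * region_score
            + spec["field_coef"] * shared_field
            + spec["noise_sd"] * env_rng.standard_normal(len(env_positions))
        )
        env[var] = np.exp(log_v)
    # 7 phyto-microplankton groups, each preferring one or two regions
    for j, group in enumerate(PHYTO_GROUPS):
        pref = (j % K) + 1
        mu = np.where(env_regions == pref, 3.0, 1.5)
        log_v = mu + 0.3 * shared_field + 0.3 * env_rng.standard_normal(len(env_positions))
        env[group] = np.exp(log_v)
    return datasets, env, truth


def _default_taxa() -> list[TaxonProfile]:
    """Reference community: 12 mesozooplankton taxa, 5 planted indicator
    ichthyoplankton taxa spread over the three gears, 3 aggregates."""

    def pref(base: float, region: int, boost: float = 1.5) -> dict[int, float]:
        return {g: base + (boost if g == region else 0.0) for g in range(1, 6)}

    uniform = lambda base: {g: base for g in range(1, 6)}
    meso = "meso"
    taxa = [
        TaxonProfile("Temora longicornis", pref(4.0, 1), None, 0.05, dataset=meso),
        TaxonProfile("Pseudocalanus spp.", pref(3.5, 2), None, 0.05, dataset=meso),
        TaxonProfile("Acartia spp.", pref(3.5, 3), None, 0.05, dataset=meso),
        TaxonProfile("Centropages spp.", pref(2.5, 4), None, 0.10, dataset=meso),
        TaxonProfile("Calanus helgolandicus", pref(3.0, 5), None, 0.10, dataset=meso),
        TaxonProfile("Paracalanus spp.", pref(2.0, 2, 1.0), None, 0.10, dataset=meso),
        TaxonProfile("Oithona spp.", uniform(3.0), None, 0.05, dataset=meso),
        TaxonProfile("Copepoda nauplii", uniform(4.5), None, 0.02, dataset=meso),
        TaxonProfile("Cirripedia nauplii", pref(2.5, 1), None, 0.15, dataset=meso),
        TaxonProfile("Appendicularia", uniform(1.5), None, 0.20, dataset=meso),
        TaxonProfile("Chaetognatha", uniform(-1.5), None, 0.30, dataset=meso),
        TaxonProfile("Evadne spp.", uniform(-2.5), None, 0.30, dataset=meso),
        # planted indicators: hard zero outside their home region
        TaxonProfile("Clupea harengus larvae", 4.5, None, 0.0,
                     planted_indicator_for=1, dataset="larvae"),
        TaxonProfile("Gobiidae larvae", 4.0, None, 0.0,
                     planted_indicator_for=4, dataset="larvae"),
        TaxonProfile("Syngnathidae larvae", 4.2, None, 0.0,
                     planted_indicator_for=5, dataset="larvae"),
        TaxonProfile("Sardina pilchardus eggs", 5.5, None, 0.0,
                     planted_indicator_for=2, dataset="eggs"),
        TaxonProfile("Trisopterus luscus eggs", 4.5, None, 0.0,
                     planted_indicator_for=3, dataset="eggs"),
        # broad aggregates (standard exclusion-list names)
        TaxonProfile(
            "Calanoida",
            members=(
                "Temora longicornis",
                "Pseudocalanus spp.",
                "Acartia spp.",
                "Centropages spp.",
                "Calanus helgolandicus",
                "Paracalanus spp.",
            ),
            dataset=meso,
        ),
        TaxonProfile(
            "Copepoda",
            members=(
                "Temora longicornis",
                "Pseudocalanus spp.",
                "Acartia spp.",
                "Centropages spp.",
                "Calanus helgolandicus",
                "Paracalanus spp.",
                "Oithona spp.",
            ),
            dataset=meso,
        ),
        TaxonProfile(
            "Crustacea nauplius",
            members=("Copepoda nauplii", "Cirripedia nauplii"),
            dataset=meso,
        ),
    ]
    return taxa


def scenario_default(seed: int = 20080127) -> SyntheticScenario:
    """The documented reference scenario.

    Five contiguous Voronoi regions over a southern-North-Sea-like polygon,
    20 taxa (3 aggregates, 5 planted indicators, rank abundance spanning
    four orders of magnitude so the two rarest taxa fall below the 0.5%
    dominance threshold), a shared spherical variogram (c0 = 0.3, c1 = 1.0,
    a = 60 km) on the log scale, and three datasets: 140 and 130 scattered
    net stations and 860 dense along-track pump samples.
    """
    polygon = shapely_wkt.loads(DEFAULT_POLYGON_WKT)
    return SyntheticScenario(
        polygon=polygon,
        n_regions=5,
        taxa=_default_taxa(),
        datasets=[
            DatasetSpec("meso", 140, "scatter"),
            DatasetSpec("larvae", 130, "scatter"),
            DatasetSpec("eggs", 860, "transect"),
        ],
        variogram=VariogramModel("spherical", 0.3, 1.0, 60.0),
        seed=seed,
    )
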