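"""Synthetic landscapes with known ground truth.

Generates the inputs a presence-background species distribution analysis
assumes: spatially autocorrelated habitat layers (basal areas, m^2/ha,
zero-truncated), mutually correlated climate surfaces (temperature metrics
and winter snow indices), a random road network with derived road-density,
distance-to-major-road, housing-density and distance-to-conservation-land
layers, and occurrence points drawn from a Bernoulli point process whose
log-odds combine the covariates, an intercept, and a Matern Gaussian random
field. Ground-truth parameters are explicit so parameter-recovery and
model-selection consistency can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, kv
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union
import shapely

from .grids import GridGeometry

HABITAT_LAYERS = (
    "aspen_birch",
    "jack_pine_red_pine",
    "lowland_conifer",
    "lowland_riparian",
    "northern_hardwoods",
    "upland_spruce_fir",
    "oak_association",
)
CLIMATE_LAYERS = (
    "mean_annual_temp",
    "summer_temp",
    "winter_temp",
    "snow_season_length",
    "snow_variability",
    "frozen_ground",
)
ANTHROPOGENIC_LAYERS = (
    "housing_density",
    "road_density",
    "dist_major_roads",
    "dist_conservation",
)

# winter indices expressed as percentages are hard-bounded
_BOUNDED_0_100 = ("snow_variability", "frozen_ground")

_CLIMATE_UNITS = {
    "mean_annual_temp": "degC",
    "summer_temp": "degC",
    "winter_temp": "degC",
    "snow_season_length": "days",
    "snow_variability": "percent",
    "frozen_ground": "percent",
}
_ANTHRO_UNITS = {
    "housing_density": "households/km2",
    "road_density": "km/km2",
    "dist_major_roads": "km",
    "dist_conservation": "km",
}


def matern_correlation(d, range_km: float, nu: float = 1.0) -> np.ndarray:
    """Matern correlation at distance ``d`` under the range = sqrt(8 nu)/kappa
    convention (correlation ~= 0.13 at ``d == range_km`` for nu = 1)."""
    if range_km <= 0:
        raise ValueError("range must be positive")
    d = np.asarray(d, dtype=float)
    kappa = np.sqrt(8.0 * nu) / range_km
    x = kappa * d
    # nu = 1 closed form: rho(d) = (kappa d) K_1(kappa d); generic via kv
    from scipy.special import gamma as _gamma

    safe = np.where(x > 0, x, 1.0)
    rho = np.where(
        x > 0,
        (2.0 ** (1.0 - nu) / _gamma(nu)) * np.power(safe, nu) * kv(nu, safe),
        1.0,
    )
    return np.clip(rho, 0.0, 1.0)


def _matern_cov(coords: np.ndarray, range_km: float, sd: float) -> np.ndarray:
    d = cdist(coords, coords)
    return sd**2 * matern_correlation(d, range_km)


def simulate_grf(
    grid: GridGeometry,
    range_km: float,
    sd: float,
    seed: int | np.random.Generator,
    *,
    n_draws: int = 1,
) -> np.ndarray:
    """Exact draws of a zero-mean Matern (nu = 1) Gaussian random field.

    Uses a dense Cholesky factorisation of the cell-centre covariance, so the
    grid must stay small (<= ~4000 cells). Returns shape ``(ny, nx)`` for a
    single draw, else ``(n_draws, ny, nx)``.
    """
    if range_km <= 0:
        raise ValueError("range must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if grid.n_cells > 4096:
        raise ValueError(
            f"grid has {grid.n_cells} cells; dense GRF simulation supports <= 4096"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shape = (grid.ny, grid.nx)
    if sd == 0:
        out = np.zeros((n_draws,) + shape)
        return out[0] if n_draws == 1 else out
    cov = _matern_cov(grid.cell_centers(), range_km, sd)
    L = _chol_with_jitter(cov)
    z = rng.standard_normal((grid.n_cells, n_draws))
    draws = (L @ z).T.reshape(n_draws, *shape)
    return draws[0] if n_draws == 1 else draws


def simulate_grf_at(
    coords: np.ndarray,
    range_km: float,
    sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One exact GRF draw evaluated at arbitrary coordinates (dense, n <= ~4000)."""
    coords = np.asarray(coords, dtype=float)
    if sd == 0:
        return np.zeros(len(coords))
    if len(coords) > 4096:
        raise ValueError("dense GRF draw supports <= 4096 locations")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L = _chol_with_jitter(sd**2 * matern_correlation(cdist(coords, coords), range_km))
    return L @ rng.standard_normal(len(coords))


def _chol_with_jitter(cov: np.ndarray) -> np.ndarray:
    jitter = 1e-10 * float(np.mean(np.diag(cov)))
    for _ in range(6):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError(
        "covariance not positive definite after jitter up to "
        f"{jitter:.2e}; smallest eigenvalue {np.linalg.eigvalsh(cov)[0]:.3e}"
    )


def _default_climate_corr() -> np.ndarray:
    # single-factor structure: temperatures load positively, snow metrics
    # negatively on a 'warmth' factor -> PSD by construction
    loadings = np.array([0.85, 0.80, 0.75, -0.80, -0.55, 0.60])
    corr = np.outer(loadings, loadings)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class LandscapeConfig:
    """Stated world for the synthetic landscape.

    Defaults describe a 50 x 50 km managed-forest landscape: basal areas with
    ~10 km autocorrelation range and a long right tail with exact zeros,
    climate surfaces smooth at ~20 km and strongly cross-correlated, and a
    sparse rural road network (~3 mapped segments per 100 km^2).
    """

    extent_km: float = 50.0
    resolution_km: float = 1.0
    habitat_range_km: float = 10.0
    habitat_sd: float = 6.0  # m^2/ha
    habitat_mean: float = 6.0  # m^2/ha before zero-truncation
    climate_range_km: float = 20.0
    climate_means: tuple = (6.5, 18.0, -6.0, 140.0, 30.0, 20.0)
    climate_sds: tuple = (1.2, 1.5, 2.0, 25.0, 10.0, 8.0)
    climate_corr: np.ndarray = field(default_factory=_default_climate_corr)
    road_density_per_100km2: float = 3.0
    housing_mean: float = 8.0  # households/km2
    housing_sd: float = 10.0
    n_conservation_areas: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_km <= 0:
            raise ValueError("extent must be strictly positive")
        n = self.extent_km / self.resolution_km
        if abs(n - round(n)) > 1e-9:
            raise ValueError("resolution must divide extent")
        corr = np.asarray(self.climate_corr, dtype=float)
        if corr.shape != (6, 6):
            raise ValueError("climate correlation matrix must be 6x6")
        _validate_corr(corr, CLIMATE_LAYERS)

    @property
    def grid(self) -> GridGeometry:
        n = int(round(self.extent_km / self.resolution_km))
        return GridGeometry(0.0, 0.0, self.resolution_km, n, n)


def _validate_corr(corr: np.ndarray, names: Sequence[str]) -> None:
    off = np.abs(corr - corr.T)
    if off.max() > 1e-10:
        raise ValueError("correlation matrix must be symmetric")
    bad = np.argwhere(np.abs(corr) > 1.0 + 1e-12)
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"infeasible correlation matrix: |r| > 1 for pair ({names[i]}, {names[j]})"
        )
    eig = np.linalg.eigvalsh(corr)
    if eig[0] < -1e-10:
        od = np.abs(corr - np.eye(len(corr)))
        i, j = np.unravel_index(np.argmax(od), od.shape)
        raise ValueError(
            "infeasible (non positive semi-definite) correlation matrix; "
            f"largest off-diagonal entry at pair ({names[i]}, {names[j]})"
        )


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth Bernoulli point-process parameters.

    Coefficients are on the logit scale per scaled (z-score) unit of the
    named covariate layer. ``grf_sd = 0`` disables the latent field,
    ``detection_bias = 0`` disables roadside thinning of presences.
    """

    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    grf_range_km: float = 10.0
    grf_sd: float = 0.0
    detection_bias: float = 0.0  # per-km decay of presence retention near roads

    def __post_init__(self) -> None:
        if self.grf_range_km <= 0:
            raise ValueError("range must be positive")
        if self.grf_sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class CovariateStack:
    """Named raster layers sharing one grid geometry.

    ``layers`` maps layer name to a ``(ny, nx)`` array; ``classes`` assigns
    each layer to habitat | climate | anthropogenic; ``units`` records the
    raw physical units; ``scaling`` optionally holds per-layer (mean, sd)
    used when z-scoring at model time.
    """

    grid: GridGeometry
    layers: dict[str, np.ndarray]
    classes: dict[str, str]
    units: dict[str, str]
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    roads: list | None = None  # shapely LineStrings (all roads)
    major_roads: list | None = None
    conservation: list | None = None  # shapely polygons

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer '{name}' shape {arr.shape} does not match grid {self.grid.shape}"
                )
            if name not in self.classes:
                raise ValueError(f"layer '{name}' missing a semantic class")

    def names(self, semantic_class: str | None = None) -> list[str]:
        if semantic_class is None:
            return list(self.layers)
        return [n for n, c in self.classes.items() if c == semantic_class]

    def values_at(self, points: np.ndarray, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Raw layer values at points by nearest-cell lookup."""
        idx = self.grid.cell_index(points)
        names = list(self.layers) if names is None else list(names)
        return pd.DataFrame({n: self.layers[n].ravel()[idx] for n in names})


@dataclass
class OccurrenceSet:
    """Labelled point set: presence (1) and zero-labelled sites.

    ``role`` distinguishes how a zero arose (background pseudo-absence vs a
    surveyed nondetection); ``partition`` carries the train/test split.
    """

    points: pd.DataFrame  # columns x, y, label, role, partition

    def __post_init__(self) -> None:
        required = {"x", "y", "label", "role", "partition"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns {sorted(missing)}")
        labels = set(self.points["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be 0/1; found {sorted(labels - {0, 1})}")

    @property
    def coords(self) -> np.ndarray:
        return self.points[["x", "y"]].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.points["label"].to_numpy(dtype=int)

    def subset(self, partition: str) -> "OccurrenceSet":
        return OccurrenceSet(self.points[self.points["partition"] == partition].reset_index(drop=True))


def simulate_covariates(config: LandscapeConfig) -> CovariateStack:
    """Generate the full 17-layer covariate stack for one landscape.

    Seven zero-truncated basal-area layers, six cross-correlated climate
    layers, a random road network with derived density/distance layers,
    a housing-density layer loosely tied to the roads, and a
    distance-to-conservation-lands layer.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    layers: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    units: dict[str, str] = {}

    for name in HABITAT_LAYERS:
        f = simulate_grf(grid, config.habitat_range_km, config.habitat_sd, rng)
        layers[name] = np.maximum(config.habitat_mean + f, 0.0)
        classes[name] = "habitat"
        units[name] = "m2/ha"

    # climate: shared Matern structure, cross-correlated across layers.
    # The base draws are empirically whitened over cells before mixing so the
    # realized cell-wise Pearson correlations equal the target matrix.
    base = simulate_grf(grid, config.climate_range_km, 1.0, rng, n_draws=6)
    base = base.reshape(6, -1)
    base -= base.mean(axis=1, keepdims=True)
    L_emp = _chol_with_jitter(np.cov(base))
    white = np.linalg.solve(L_emp, base)
    white /= white.std(axis=1, keepdims=True)
    L = _chol_with_jitter(np.asarray(config.climate_corr, dtype=float))
    correlated = L @ white
    for i, name in enumerate(CLIMATE_LAYERS):
        vals = config.climate_means[i] + config.climate_sds[i] * correlated[i]
        if name in _BOUNDED_0_100:
            vals = np.clip(vals, 0.0, 100.0)
        layers[name] = vals.reshape(grid.shape)
        classes[name] = "climate"
        units[name] = _CLIMATE_UNITS[name]

    roads, major = _simulate_roads(config, rng)
    layers["road_density"] = _road_length_per_cell(grid, roads)
    layers["dist_major_roads"] = _distance_layer(grid, unary_union(major))

    hd = simulate_grf(grid, config.habitat_range_km, config.housing_sd, rng)
    road_z = layers["road_density"] - layers["road_density"].mean()
    rd_sd = layers["road_density"].std()
    if rd_sd > 0:
        road_z = road_z / rd_sd
    layers["housing_density"] = np.maximum(
        config.housing_mean + hd + 0.4 * config.housing_sd * road_z, 0.0
    )

    conservation = _simulate_conservation(config, rng)
    layers["dist_conservation"] = _distance_layer(grid, unary_union(conservation))
    for name in ANTHROPOGENIC_LAYERS:
        classes[name] = "anthropogenic"
        units[name] = _ANTHRO_UNITS[name]

    ordered = {n: layers[n] for n in HABITAT_LAYERS + CLIMATE_LAYERS + ANTHROPOGENIC_LAYERS}
    return CovariateStack(
        grid=grid,
        layers=ordered,
        classes=classes,
        units=units,
        roads=roads,
        major_roads=major,
        conservation=conservation,
    )


def _simulate_roads(config: LandscapeConfig, rng: np.random.Generator):
    if config.road_density_per_100km2 <= 0:
        raise ValueError(
            "road-density parameter is zero: no road network can be generated and "
            "the distance-to-major-road layer is undefined"
        )
    area = config.extent_km**2
    n_seg = max(1, int(rng.poisson(config.road_density_per_100km2 * area / 100.0)))
    domain = config.grid.polygon()
    roads, major = [], []
    for i in range(n_seg):
        p = rng.uniform(0, config.extent_km, size=2)
        theta = rng.uniform(0, np.pi)
        half = rng.uniform(0.3, 0.8) * config.extent_km
        d = np.array([np.cos(theta), np.sin(theta)]) * half
        seg = LineString([p - d, p + d]).intersection(domain)
        if seg.is_empty or seg.length == 0:
            continue
        geoms = list(seg.geoms) if seg.geom_type == "MultiLineString" else [seg]
        roads.extend(geoms)
        # roughly a quarter of segments are arterial; always at least one
        if i == 0 or rng.random() < 0.25:
            major.extend(geoms)
    return roads, major


def _road_length_per_cell(grid: GridGeometry, roads: list) -> np.ndarray:
    union = unary_union(roads)
    out = np.zeros(grid.shape)
    res = grid.resolution
    for r in range(grid.ny):
        y0 = grid.y0 + r * res
        row_band = union.intersection(box(grid.x0, y0, grid.x0 + grid.nx * res, y0 + res))
        if row_band.is_empty:
            continue
        for c in range(grid.nx):
            x0 = grid.x0 + c * res
            seg = row_band.intersection(box(x0, y0, x0 + res, y0 + res))
            out[r, c] = seg.length / res**2  # km of road per km^2
    return out


def _distance_layer(grid: GridGeometry, geom) -> np.ndarray:
    centers = grid.cell_centers()
    pts = shapely.points(centers[:, 0], centers[:, 1])
    return shapely.distance(pts, geom).reshape(grid.shape)


def _simulate_conservation(config: LandscapeConfig, rng: np.random.Generator) -> list:
    polys = []
    for _ in range(max(1, config.n_conservation_areas)):
        center = rng.uniform(0.1 * config.extent_km, 0.9 * config.extent_km, size=2)
        radius = rng.uniform(0.06, 0.15) * config.extent_km
        polys.append(Point(center).buffer(radius).intersection(config.grid.polygon()))
    return polys


def simulate_occurrences(
    stack: CovariateStack,
    truth: TrueModel,
    n_sites: int,
    seed: int,
) -> OccurrenceSet:
    """Draw labelled sites from the ground-truth Bernoulli point process.

    Sites are uniform over the domain; the log-odds of presence at a site
    combine the intercept, the z-scored covariates named by the truth, and a
    fresh Matern field draw. Presences may then be thinned with retention
    probability exp(-bias * distance to nearest major road), emulating the
    roadside accessibility bias of unstructured occurrence data. Zero-label
    sites are all retained and tagged ``nondetection``.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    unknown = [c for c in truth.coefficients if c not in stack.layers]
    if unknown:
        raise ValueError(f"truth references unknown layers {unknown}")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = stack.grid.extent
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n_sites), rng.uniform(ymin, ymax, n_sites)]
    )
    eta = np.full(n_sites, truth.intercept, dtype=float)
    if truth.coefficients:
        raw = stack.values_at(pts, list(truth.coefficients))
        for name, beta in truth.coefficients.items():
            layer = stack.layers[name]
            mu, sd = float(layer.mean()), float(layer.std())
            if sd == 0:
                raise ValueError(f"layer '{name}' is constant; cannot scale")
            eta += beta * (raw[name].to_numpy() - mu) / sd
    if truth.grf_sd > 0:
        fld = simulate_grf(stack.grid, truth.grf_range_km, truth.grf_sd, rng)
        eta += fld.ravel()[stack.grid.cell_index(pts)]
    z = (rng.random(n_sites) < expit(eta)).astype(int)

    keep = np.ones(n_sites, dtype=bool)
    if truth.detection_bias > 0:
        if stack.major_roads:
            d = shapely.distance(
                shapely.points(pts[:, 0], pts[:, 1]), unary_union(stack.major_roads)
            )
        else:
            d = stack.values_at(pts, ["dist_major_roads"])["dist_major_roads"].to_numpy()
        retain = np.exp(-truth.detection_bias * d)
        keep = (z == 0) | (rng.random(n_sites) < retain)

    pts, z = pts[keep], z[keep]
    if z.sum() == 0 or z.sum() == len(z):
        raise ValueError(
            "simulated outcome is all-0 or all-1; adjust the truth intercept "
            f"(current {truth.intercept})"
        )
    df = pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "label": z,
            "role": np.where(z == 1, "presence", "nondetection"),
            "partition": "train",
        }
    )
    return OccurrenceSet(df)


def make_ecoregions(grid: GridGeometry, k_regions: int, seed: int) -> list:
    """Partition the domain into k contiguous-ish polygons (seeded Voronoi
    on cell centres, so the union tiles the domain exactly)."""
    if k_regions < 1:
        raise ValueError("k_regions must be >= 1")
    if k_regions > grid.n_cells:
        raise ValueError(f"k_regions={k_regions} exceeds cell count {grid.n_cells}")
    if k_regions == 1:
        return [grid.polygon()]
    rng = np.random.default_rng(seed)
    centers = grid.cell_centers()
    seeds = centers[rng.choice(grid.n_cells, size=k_regions, replace=False)]
    assign = np.argmin(cdist(centers, seeds), axis=1)
    res = grid.resolution
    polys = []
    for r in range(k_regions):
        cells = [
            box(x - res / 2, y - res / 2, x + res / 2, y + res / 2)
            for x, y in centers[assign == r]
        ]
        polys.append(unary_union(cells))
    return polys
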