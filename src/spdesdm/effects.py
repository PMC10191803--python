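"""Effect reporting, prediction surfaces, validation, and ecoregion summaries.

Fixed-effect posteriors are reported as relative selection strengths
RSS = exp(beta): the multiplicative change in relative intensity of use per
one scaled unit of the covariate, all else equal. Prediction surfaces are
inverse-logit linear predictors on a regular grid (default 2 km), scaled to
[0, 1] by their maximum, produced both with the posterior-mean spatial field
(fitted) and without it (predicted). Validation finds the threshold
maximizing sensitivity + specificity on held-out points and reports AUC,
TSS, sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit
from scipy.stats import rankdata

from .grids import GridGeometry
from .landscape import CovariateStack, OccurrenceSet
from .mesh import SPDEModel, projector
from .model import NN_COLUMN, PosteriorFit

QUINTILE_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def rss(beta_mean: float, beta_lower: float, beta_upper: float) -> dict:
    """Relative selection strength: exponentiate the posterior mean and its
    credible bounds. Rounding is left to report time."""
    if not beta_lower <= beta_mean <= beta_upper:
        raise ValueError("require lower <= mean <= upper")
    return {
        "rss": float(np.exp(beta_mean)),
        "rss_lower": float(np.exp(beta_lower)),
        "rss_upper": float(np.exp(beta_upper)),
    }


def rss_table(fit: PosteriorFit, stack: CovariateStack | None = None) -> pd.DataFrame:
    """RSS per fixed effect (the intercept is excluded), with the raw-unit
    increment corresponding to one scaled unit (the layer sd) when the
    covariate scaling is known."""
    rows = {}
    for name, row in fit.beta.iterrows():
        if name == "intercept":
            continue
        entry = rss(row["mean"], row["q2.5"], row["q97.5"])
        entry["beta_mean"] = row["mean"]
        if fit.scaling and name in fit.scaling:
            entry["raw_unit_increment"] = fit.scaling[name][1]
        rows[name] = entry
    return pd.DataFrame(rows).T


@dataclass
class PredictionSurface:
    """Relative probability of presence on a regular grid, scaled to max 1."""

    grid: GridGeometry
    values: np.ndarray
    variant: str  # 'with-RF' | 'no-RF'
    divisor: float

    def __post_init__(self) -> None:
        if self.variant not in ("with-RF", "no-RF"):
            raise ValueError("variant must be 'with-RF' or 'no-RF'")


def predict_surface(
    fit: PosteriorFit,
    stack: CovariateStack,
    spde: SPDEModel | None = None,
    variant: str = "with-RF",
    resolution_km: float = 2.0,
    presence_coords: np.ndarray | None = None,
) -> PredictionSurface:
    """Relative probability of presence over the study area.

    The linear predictor at each cell centre uses the fit's stored covariate
    scaling; with ``variant='with-RF'`` the posterior-mean field is projected
    onto the cells (cells must lie inside the mesh). Values are inverse-logit
    probabilities divided by their maximum.
    """
    grid = stack.grid.coarsen_to(resolution_km)
    centers = grid.cell_centers()
    eta = np.full(grid.n_cells, fit.beta.loc["intercept", "mean"])
    cols = list(fit.spec.covariates)
    if cols:
        raw = stack.values_at(centers, cols)
        for c in cols:
            mu, sd = fit.scaling[c]
            eta += fit.beta.loc[c, "mean"] * (raw[c].to_numpy() - mu) / sd
    if fit.spec.include_nn:
        if presence_coords is None:
            raise ValueError("eNN model needs presence_coords to predict")
        from .model import nn_covariate

        mu, sd = fit.scaling[NN_COLUMN]
        eta += fit.beta.loc[NN_COLUMN, "mean"] * (
            nn_covariate(centers, presence_coords) - mu
        ) / sd
    if variant == "with-RF":
        if spde is None or fit.field_mean is None:
            raise ValueError("with-RF surface requires the SPDE model and a fitted field")
        A = projector(spde.mesh, centers)  # raises if a cell falls outside the mesh
        eta += A @ fit.field_mean
    elif variant != "no-RF":
        raise ValueError("variant must be 'with-RF' or 'no-RF'")
    prob = expit(eta)
    divisor = float(prob.max())
    return PredictionSurface(grid, (prob / divisor).reshape(grid.shape), variant, divisor)


def surface_values_at(surface: PredictionSurface, points: np.ndarray) -> np.ndarray:
    return surface.values.ravel()[surface.grid.cell_index(points)]


def split_data(
    occurrences: OccurrenceSet, fraction: float = 0.8, seed: int = 0
) -> OccurrenceSet:
    """Random train/test partition at the stated training fraction (exact
    counts via a seeded permutation)."""
    n = len(occurrences.points)
    if n < 5:
        raise ValueError("need at least 5 points to split")
    rng = np.random.default_rng(seed)
    n_train = int(round(fraction * n))
    perm = rng.permutation(n)
    partition = np.empty(n, dtype=object)
    partition[perm[:n_train]] = "train"
    partition[perm[n_train:]] = "test"
    df = occurrences.points.copy()
    df["partition"] = partition
    out = OccurrenceSet(df)
    for part in ("train", "test"):
        sub = df[df["partition"] == part]
        if sub["label"].nunique() < 2:
            import warnings

            warnings.warn(f"{part} split lacks one label class", stacklevel=2)
    return out


@dataclass
class ValidationReport:
    threshold: float
    auc: float
    tss: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.threshold <= 1.0
        assert abs(self.tss - (self.sensitivity + self.specificity - 1.0)) < 1e-12


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based concordance (Mann-Whitney) AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes required for AUC")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def validate(scores: np.ndarray, labels: np.ndarray, step: float = 0.001) -> ValidationReport:
    """Threshold-based goodness of fit on a held-out set.

    The threshold maximizes sensitivity + specificity over a regular grid
    (default step 0.001); a point is classified present when its score is
    >= the threshold. TSS = sensitivity + specificity - 1 exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels misaligned")
    pos = labels == 1
    if pos.all() or not pos.any():
        raise ValueError("test set contains a single label class")
    thresholds = np.arange(0.0, 1.0 + step / 2.0, step)
    pred = scores[None, :] >= thresholds[:, None]
    sens = (pred & pos).sum(axis=1) / pos.sum()
    spec = (~pred & ~pos).sum(axis=1) / (~pos).sum()
    best = int(np.argmax(sens + spec))
    return ValidationReport(
        threshold=float(thresholds[best]),
        auc=auc_score(scores, labels),
        tss=float(sens[best] + spec[best] - 1.0),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
    )


@dataclass
class EffectCurve:
    covariate: str
    grid: np.ndarray  # raw covariate values, strictly increasing
    fit: np.ndarray  # smoothed scaled relative probability, within [0, 1]
    lower: np.ndarray
    upper: np.ndarray


def effect_curve(
    fit: PosteriorFit,
    design_raw: pd.DataFrame,
    covariate: str,
    basis_dim: int = 4,
    n_grid: int = 100,
) -> EffectCurve:
    """Smoothed marginal response: scaled relative probability of presence at
    the available locations against the raw covariate, fitted with a
    penalized spline of basis dimension < 5 to avoid overparameterization.
    The band is +/- 2 pointwise standard errors of the smoother.
    """
    if basis_dim > 5:
        raise ValueError("basis dimension must be <= 5")
    if covariate not in fit.spec.covariates:
        raise ValueError(f"'{covariate}' is not in the fitted model")
    x = design_raw[covariate].to_numpy(dtype=float)
    if x.std() == 0:
        raise ValueError(f"covariate '{covariate}' is constant")
    prob = fit.fitted_probabilities
    y = prob / prob.max()

    from statsmodels.gam.api import BSplines, GLMGam

    bs = BSplines(x[:, None], df=[max(basis_dim, 3)], degree=[2])
    model = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs, alpha=[1.0])
    res = model.fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    basis_grid = bs.transform(grid[:, None])
    design_grid = np.column_stack([np.ones(len(grid)), basis_grid])
    mean = design_grid @ res.params
    cov = res.cov_params()
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", design_grid, cov, design_grid), 0, None))
    return EffectCurve(
        covariate=covariate,
        grid=grid,
        fit=np.clip(mean, 0.0, 1.0),
        lower=np.clip(mean - 2 * se, 0.0, 1.0),
        upper=np.clip(mean + 2 * se, 0.0, 1.0),
    )


def ecoregion_classes(surface: PredictionSurface, regions: list) -> pd.DataFrame:
    """Proportion of each ecoregion's cells in fixed-width occupancy classes
    (0-0.2], (0.2-0.4], (0.4-0.6], (0.6-0.8], (0.8-1.0]; zero falls in the
    first class."""
    centers = surface.grid.cell_centers()
    vals = surface.values.ravel()
    pts = shapely.points(centers[:, 0], centers[:, 1])
    classes = np.clip(np.ceil(vals / 0.2).astype(int), 1, 5)
    # each cell belongs to exactly one region; on shared boundaries the
    # first region listed wins
    assign = np.full(len(pts), -1)
    for i, poly in enumerate(regions):
        mask = (assign < 0) & shapely.intersects(poly, pts)
        assign[mask] = i
    out = {}
    for i in range(len(regions)):
        inside = assign == i
        if not inside.any():
            raise ValueError(f"ecoregion {i} contains no surface cells")
        counts = np.bincount(classes[inside], minlength=6)[1:]
        out[f"region_{i}"] = counts / counts.sum()
    return pd.DataFrame(out, index=[f"class_{k}" for k in range(1, 6)]).T
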