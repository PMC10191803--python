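"""End-to-end analysis: simulate/read inputs, build the mesh, run the
three-stage WAIC ladder, report effects, predict surfaces, validate, and
summarize ecoregions. Every artifact is written under the configured output
directory together with a run manifest (config hash, seeds, versions, wall
time); reruns with the same config are byte-identical except the manifest.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .config import RunConfig
from .effects import (
    ecoregion_classes,
    predict_surface,
    rss_table,
    split_data,
    surface_values_at,
    validate,
)
from .landscape import (
    CovariateStack,
    LandscapeConfig,
    OccurrenceSet,
    TrueModel,
    make_ecoregions,
    simulate_covariates,
    simulate_occurrences,
)
from .mesh import SPDEModel, background_points, build_mesh, projector
from .model import NN_COLUMN, PriorConfig, nn_covariate, scale_covariates, significance
from .model import DesignMatrix
from .selection import SelectionContext


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise StageError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def _hyper_grid(cfg: RunConfig, priors: PriorConfig):
    k = max(1, int(cfg.hyper_grid_size))
    if k == 1:
        return [(priors.range_median_km, priors.sd_median)]
    ranges = priors.range_median_km * np.exp(np.linspace(-1.5, 1.5, k))
    sds = priors.sd_median * np.exp(np.linspace(-1.5, 1.5, k))
    return [(r, s) for r in ranges for s in sds]


@_stage("inputs")
def _inputs(cfg: RunConfig, out: Path):
    if cfg.simulate:
        lc = LandscapeConfig(
            extent_km=cfg.extent_km,
            resolution_km=cfg.resolution_km,
            seed=cfg.seed_simulation,
        )
        stack = simulate_covariates(lc)
        truth = TrueModel(
            intercept=cfg.true_intercept,
            coefficients=dict(cfg.true_coefficients),
            grf_range_km=cfg.true_grf_range_km,
            grf_sd=cfg.true_grf_sd,
        )
        occ = simulate_occurrences(stack, truth, cfg.n_sites, cfg.seed_simulation + 1)
        regions = make_ecoregions(stack.grid, cfg.n_ecoregions, cfg.seed_simulation + 2)
        sio.write_stack(stack, out / "stack")
        sio.write_occurrences(occ, out / "occurrences.csv")
        sio.write_polygons(regions, out / "ecoregions.geojson")
        return stack, occ, regions
    cfg.validate_paths()
    stack = sio.read_stack(Path(cfg.stack_manifest))
    occ = sio.read_occurrences(Path(cfg.occurrences))
    regions = sio.read_polygons(Path(cfg.ecoregions))
    return stack, occ, regions


@_stage("mesh")
def _mesh(cfg: RunConfig, stack: CovariateStack):
    domain = stack.grid.polygon()
    diam = stack.grid.diameter
    max_edge = cfg.mesh_max_edge_km or diam / 25.0
    mesh = build_mesh(
        domain,
        max_edge,
        cutoff=cfg.mesh_cutoff_km,
        buffer=cfg.mesh_buffer_km or diam / 5.0,
    )
    bg = background_points(mesh, domain, cfg.background_spacing_km)
    return mesh, bg


@_stage("design")
def _design(cfg: RunConfig, stack: CovariateStack, occ: OccurrenceSet, bg):
    bg_df = pd.DataFrame(
        {
            "x": bg.coords[:, 0],
            "y": bg.coords[:, 1],
            "label": 0,
            "role": "background",
            "partition": "train",
        }
    )
    data = OccurrenceSet(
        pd.concat([occ.points, bg_df], ignore_index=True)
    )
    data = split_data(data, cfg.train_fraction, cfg.seed_split)
    candidates = (
        list(cfg.habitat_candidates)
        + list(cfg.climate_candidates)
        + list(cfg.anthropogenic_candidates)
    )
    raw = stack.values_at(data.coords, candidates)
    if cfg.include_nn:
        presences = data.coords[data.labels == 1]
        raw[NN_COLUMN] = nn_covariate(data.coords, presences, is_presence=data.labels == 1)
    train_mask = (data.points["partition"] == "train").to_numpy()
    # scaling computed on training rows only, then applied everywhere
    dm_train = scale_covariates(raw[train_mask])
    full = DesignMatrix(dm_train.apply(raw), dm_train.scaling)
    return data, full, train_mask


@_stage("selection")
def _selection(cfg, data, design, train_mask, spde, mesh, out: Path):
    train_coords = data.coords[train_mask]
    A = projector(mesh, train_coords)
    priors = PriorConfig(
        beta_sd=cfg.beta_prior_sd,
        range_median_km=cfg.prior_range_median_km or spde.range_km,
        sd_median=cfg.prior_sd_median,
    )
    train_design = DesignMatrix(design.values[train_mask].reset_index(drop=True), design.scaling)
    ctx = SelectionContext(
        design=train_design,
        z=data.labels[train_mask],
        spde=spde,
        A=A,
        priors=priors,
        include_nn=cfg.include_nn,
        hyper_grid=_hyper_grid(cfg, priors),
        n_draws=cfg.n_waic_draws,
        seed=cfg.seed_fit,
    )
    from .selection import collinearity_screen, stage_anthropogenic, stage_climate, stage_habitat

    candidates = (
        list(cfg.habitat_candidates)
        + list(cfg.climate_candidates)
        + list(cfg.anthropogenic_candidates)
    )
    forbidden = collinearity_screen(
        train_design.values[candidates], cfg.correlation_threshold
    )
    # the ledger is flushed after every stage so a later failure still
    # leaves the completed stages on disk
    ledger_path = out / "selection_ledger.csv"
    ledgers = []

    def flush(rows):
        ledgers.append(rows)
        pd.concat(ledgers, ignore_index=True).to_csv(ledger_path, index=False)

    s1, l1 = stage_habitat(ctx, cfg.habitat_candidates, forbidden)
    flush(l1)
    s2, l2 = stage_climate(ctx, s1, cfg.climate_candidates, forbidden)
    flush(l2)
    s3, l3 = stage_anthropogenic(ctx, s2, cfg.anthropogenic_candidates, forbidden)
    flush(l3)
    _, final_fit = ctx.fit_spec(list(s3.covariates))
    return s3, pd.concat(ledgers, ignore_index=True), final_fit, ctx


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of artifact paths."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    stack, occ, regions = _inputs(config, out)
    mesh, bg = _mesh(config, stack)
    sio.write_mesh(mesh, out / "mesh.json")
    data, design, train_mask = _design(config, stack, occ, bg)
    sio.write_occurrences(data, out / "model_data.csv")

    priors_range = config.prior_range_median_km or stack.grid.diameter / 5.0
    spde = SPDEModel.from_mesh(mesh, priors_range, config.prior_sd_median)

    final_spec, ledger, final_fit, ctx = _selection(
        config, data, design, train_mask, spde, mesh, out
    )
    sio.write_fit_summary(final_fit, out / "final_fit.json")

    try:
        rss_df = rss_table(final_fit, stack)
        sig = significance(final_fit)
        rss_df.to_csv(out / "rss_table.csv")
        sig.to_csv(out / "significance.csv")

        presence_coords = data.coords[(data.labels == 1)]
        surf_rf = predict_surface(
            final_fit, stack, spde, "with-RF",
            resolution_km=config.prediction_resolution_km,
            presence_coords=presence_coords,
        )
        surf_norf = predict_surface(
            final_fit, stack, None, "no-RF",
            resolution_km=config.prediction_resolution_km,
            presence_coords=presence_coords,
        )
        sio.write_ascii_grid(out / "surface_with_rf.asc", surf_rf.grid, surf_rf.values)
        sio.write_ascii_grid(out / "surface_no_rf.asc", surf_norf.grid, surf_norf.values)

        test_mask = ~train_mask
        test_pts = data.coords[test_mask]
        test_z = data.labels[test_mask]
        reports = {}
        for tag, surf in (("with_rf", surf_rf), ("no_rf", surf_norf)):
            rep = validate(surface_values_at(surf, test_pts), test_z)
            reports[tag] = {
                "threshold": rep.threshold,
                "auc": rep.auc,
                "tss": rep.tss,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
            }
        pd.DataFrame(reports).T.to_csv(out / "validation.csv")

        eco = ecoregion_classes(surf_rf, regions)
        eco.to_csv(out / "ecoregion_classes.csv")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"[report] {exc}") from exc

    manifest = {
        "config_hash": config.hash(),
        "seeds": config.seeds(),
        "final_model": final_spec.formula,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "wall_time_s": round(time.time() - t0, 3),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))

    for p in sorted(out.iterdir()):
        artifacts[p.name] = str(p)
    return artifacts
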