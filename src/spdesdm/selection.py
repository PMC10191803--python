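"""Three-stage WAIC model-selection ladder.

Stage 1 fits every allowed combination of habitat covariates; stage 2 adds
climate covariates univariately to the stage-1 winner (a no-climate null is
an explicit candidate and may win); stage 3 adds every subset of
anthropogenic covariates to the stage-2 winner. Candidate models containing
a pair of covariates with |Pearson r| above the collinearity threshold
(default 0.6) are dropped before fitting. Each stage is ranked by WAIC;
models within 2 WAIC of the stage winner are flagged as ties, but only the
top-ranked model moves forward. The spatial field and intercept are present
in every candidate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mesh import SPDEModel
from .model import DesignMatrix, ModelSpec, PosteriorFit, PriorConfig, fit

TIE_DELTA = 2.0
WAIC_TOL = 1e-6  # WAICs closer than this are 'equal' for tie-breaking


def collinearity_screen(
    design: pd.DataFrame | DesignMatrix, threshold: float = 0.6
) -> set[frozenset]:
    """Unordered covariate pairs with |Pearson r| > threshold; any candidate
    model containing such a pair is excluded before fitting."""
    df = design.values if isinstance(design, DesignMatrix) else design
    if df.shape[1] < 2:
        raise ValueError("need at least 2 columns to screen")
    sds = df.std()
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant columns cannot be screened: {constant}")
    corr = df.corr().to_numpy()
    names = list(df.columns)
    forbidden = set()
    for i, j in zip(*np.where(np.abs(np.triu(corr, 1)) > threshold)):
        forbidden.add(frozenset((names[i], names[j])))
    return forbidden


def _allowed(covs: Sequence[str], forbidden: set[frozenset]) -> bool:
    return not any(
        frozenset(p) in forbidden for p in itertools.combinations(sorted(covs), 2)
    )


@dataclass
class SelectionContext:
    """Everything a stage needs to fit a candidate: the full scaled design
    over all candidate columns, labels, the SPDE model and projector, priors,
    and fit settings (hyper grid, draw count, seed)."""

    design: DesignMatrix
    z: np.ndarray
    spde: SPDEModel | None = None
    A: sp.spmatrix | None = None
    priors: PriorConfig = dc_field(default_factory=PriorConfig)
    include_rf: bool = True
    include_nn: bool = False
    hyper_grid: Sequence[tuple[float, float]] | None = None
    n_draws: int = 200
    seed: int = 0
    # 0.0 = strict lowest-WAIC (the default rule). A positive band invokes
    # the parsimony convention: among models within `parsimony_band` dWAIC of
    # the stage best, prefer the one with fewest covariates (guards against
    # carrying uninformative parameters forward).
    parsimony_band: float = 0.0
    _cache: dict = dc_field(default_factory=dict, repr=False)

    def fit_spec(self, covariates: Sequence[str]) -> tuple[ModelSpec, PosteriorFit]:
        spec = ModelSpec(
            tuple(sorted(covariates)),
            include_rf=self.include_rf,
            include_nn=self.include_nn,
        )
        if spec not in self._cache:
            self._cache[spec] = fit(
                spec,
                self.design,
                self.z,
                self.spde,
                self.A,
                priors=self.priors,
                hyper_grid=self.hyper_grid,
                n_draws=self.n_draws,
                seed=self.seed,
            )
        return spec, self._cache[spec]


def _rank(stage: str, rows: list[tuple[ModelSpec, float]]) -> pd.DataFrame:
    """Sort candidates by WAIC with the deterministic tie-break: near-equal
    WAIC prefers fewer covariates, then lexicographic covariate names."""
    rows_sorted = sorted(
        rows,
        key=lambda it: (round(it[1] / WAIC_TOL), len(it[0].covariates), it[0].covariates),
    )
    best = rows_sorted[0][1]
    return pd.DataFrame(
        {
            "stage": stage,
            "model": [s.formula for s, _ in rows_sorted],
            "covariates": [",".join(s.covariates) for s, _ in rows_sorted],
            "waic": [w for _, w in rows_sorted],
            "delta_waic": [w - best for _, w in rows_sorted],
            "tie": [(w - best) <= TIE_DELTA for _, w in rows_sorted],
        }
    )


def _choose(ledger: pd.DataFrame, ctx: SelectionContext) -> ModelSpec:
    """Stage winner: the lowest-WAIC row, or — when the parsimony band is
    on — the fewest-covariate model among rows within the band."""
    row = ledger.iloc[0]
    if ctx.parsimony_band > 0:
        close = ledger[ledger["delta_waic"] <= ctx.parsimony_band]
        order = sorted(
            close["covariates"],
            key=lambda c: (len([x for x in c.split(",") if x]), c),
        )
        covs = order[0]
    else:
        covs = row["covariates"]
    return ModelSpec(
        tuple(x for x in covs.split(",") if x),
        include_rf=ctx.include_rf,
        include_nn=ctx.include_nn,
    )


def stage_habitat(
    ctx: SelectionContext, habitat: Sequence[str], forbidden: set[frozenset]
) -> tuple[ModelSpec, pd.DataFrame]:
    """All 2^k - 1 non-empty habitat subsets that pass the screen."""
    habitat = sorted(habitat)
    rows = []
    for r in range(1, len(habitat) + 1):
        for combo in itertools.combinations(habitat, r):
            if _allowed(combo, forbidden):
                spec, f = ctx.fit_spec(combo)
                rows.append((spec, f.waic))
    if not rows:
        raise ValueError("collinearity screen left no allowed habitat subsets")
    ledger = _rank("habitat", rows)
    return _choose(ledger, ctx), ledger


def stage_climate(
    ctx: SelectionContext,
    top: ModelSpec,
    climate: Sequence[str],
    forbidden: set[frozenset],
) -> tuple[ModelSpec, pd.DataFrame]:
    """Stage-1 winner + each climate covariate univariately, plus the
    no-climate null, which may win outright."""
    base = list(top.covariates)
    rows = []
    spec, f = ctx.fit_spec(base)  # null option, cached from stage 1
    rows.append((spec, f.waic))
    for c in sorted(climate):
        covs = base + [c]
        if _allowed(covs, forbidden):
            spec, f = ctx.fit_spec(covs)
            rows.append((spec, f.waic))
    ledger = _rank("climate", rows)
    return _choose(ledger, ctx), ledger


def stage_anthropogenic(
    ctx: SelectionContext,
    top: ModelSpec,
    anthropogenic: Sequence[str],
    forbidden: set[frozenset],
) -> tuple[ModelSpec, pd.DataFrame]:
    """Stage-2 winner + all 2^k subsets (including empty) of anthropogenic
    covariates that pass the screen."""
    base = list(top.covariates)
    rows = []
    anthropogenic = sorted(anthropogenic)
    for r in range(0, len(anthropogenic) + 1):
        for combo in itertools.combinations(anthropogenic, r):
            covs = base + list(combo)
            if _allowed(covs, forbidden):
                spec, f = ctx.fit_spec(covs)
                rows.append((spec, f.waic))
    ledger = _rank("anthropogenic", rows)
    return _choose(ledger, ctx), ledger


def run_selection(
    ctx: SelectionContext,
    habitat: Sequence[str],
    climate: Sequence[str],
    anthropogenic: Sequence[str],
    threshold: float = 0.6,
) -> tuple[ModelSpec, pd.DataFrame, PosteriorFit]:
    """Screen, run the three stages, and return the final spec, the stacked
    ledger, and the final fit."""
    all_cols = [c for c in ctx.design.columns if c in set(habitat) | set(climate) | set(anthropogenic)]
    forbidden = collinearity_screen(ctx.design.values[all_cols], threshold)
    s1, l1 = stage_habitat(ctx, habitat, forbidden)
    s2, l2 = stage_climate(ctx, s1, climate, forbidden)
    s3, l3 = stage_anthropogenic(ctx, s2, anthropogenic, forbidden)
    ledger = pd.concat([l1, l2, l3], ignore_index=True)
    _, final_fit = ctx.fit_spec(list(s3.covariates))
    return s3, ledger, final_fit
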