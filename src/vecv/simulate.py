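"""Simulated validation scenarios relating predictions to observations by a slope.

Four scenarios, each producing paired (observed, predicted) vectors whose
linear relationship has a configurable slope β:

1. ``predicted = β·x`` — proportional under/over-prediction through the origin.
2. ``predicted = β0 + β·x`` with ``β0 = (1 - β)·mean(x)`` — the prediction
   line pivots about the observed mean, so β = 0 is exactly the global-mean
   predictor and β = 1 the perfect one.
3. Scenario 1 plus i.i.d. Gaussian noise ε ~ N(0, σ²) in the predictions.
4. Scenario 2 plus the same noise.

The observed vector defaults to the integers 1..n (n = 30 by default),
which makes the noiseless accuracy curves closed-form:
scenario 1 has ``VEcv(β) = (1 - (1-β)²·Σx²/Σ(x-x̄)²)·100`` and
scenario 2 has ``VEcv(β) = (1 - (1-β)²)·100`` independent of x.
In the noiseless scenarios Pearson r is identically 1 for every β > 0 —
the pathology these simulations exist to expose.

Slope sweeps draw one noise vector per sweep (not per grid point), so a
noisy sweep traces a single smooth realization across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .metrics import MeasureReport, PairedData, full_report

__all__ = [
    "ScenarioSpec",
    "SweepResult",
    "make_observed",
    "simulate",
    "sweep",
    "default_grid",
    "SLOPE_RANGES",
    "HIGHLIGHT_SLOPES",
    "DEFAULT_N",
    "DEFAULT_NOISE_SD",
]

DEFAULT_N = 30
DEFAULT_NOISE_SD = 2.0

#: Permitted slope range per scenario: 0 (the global-mean predictor) is only
#: meaningful for the intercept scenarios 2 and 4.
SLOPE_RANGES = {1: (0.1, 1.2), 2: (0.0, 1.2), 3: (0.1, 1.2), 4: (0.0, 1.2)}

#: Slopes highlighted on the study figures and always present in default grids.
HIGHLIGHT_SLOPES = (0.3, 0.6, 0.9, 1.0)

DEFAULT_GRID_STEP = 0.01


def make_observed(x_spec="1..n", n: int = DEFAULT_N) -> np.ndarray:
    """Build the observed vector for a scenario.

    ``x_spec`` may be ``"1..n"`` (default: the integers 1..n), ``"uniform"``
    (an evenly spaced grid on [0, 1]), or an explicit vector (passed through,
    must have length n).
    """
    if n < 2:
        raise InputError("observed vector needs n >= 2")
    if isinstance(x_spec, str):
        if x_spec == "1..n":
            return np.arange(1, n + 1, dtype=float)
        if x_spec == "uniform":
            return np.linspace(0.0, 1.0, n)
        raise InputError(f"unknown x_spec {x_spec!r}; use '1..n', 'uniform' or a vector")
    x = np.asarray(x_spec, dtype=float)
    if x.ndim != 1 or x.shape[0] != n:
        raise InputError(f"supplied observed vector must be 1-D of length {n}")
    return x


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything that determines one simulated validation dataset."""

    scenario_id: int
    slope: float
    n: int = DEFAULT_N
    noise_sd: float = 0.0
    seed: int = 0
    x_spec: object = "1..n"

    def __post_init__(self):
        if self.scenario_id not in (1, 2, 3, 4):
            raise InputError(f"scenario_id must be 1-4, got {self.scenario_id}")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        if self.scenario_id in (1, 2) and self.noise_sd != 0:
            raise InputError("scenarios 1 and 2 are noiseless; use 3 or 4 for noise")
        lo, hi = SLOPE_RANGES[self.scenario_id]
        if not (lo <= self.slope <= hi):
            raise InputError(
                f"scenario {self.scenario_id} slope must lie in [{lo}, {hi}], got {self.slope}"
            )


def _predict(scenario_id: int, beta: float, x: np.ndarray, eps: np.ndarray | None) -> np.ndarray:
    if scenario_id in (1, 3):
        y = beta * x
    else:  # line through the observed mean: beta0 = (1 - beta) * mean(x)
        y = (1.0 - beta) * x.mean() + beta * x
    if eps is not None:
        y = y + eps
    return y


def simulate(spec: ScenarioSpec) -> PairedData:
    """Generate the paired data for one scenario specification.

    Deterministic: the same spec (including seed) always yields the same
    data.  Noise for scenarios 3/4 is drawn from a PCG64 generator seeded
    with ``spec.seed``.
    """
    x = make_observed(spec.x_spec, spec.n)
    eps = None
    if spec.scenario_id in (3, 4):
        rng = np.random.default_rng(spec.seed)
        eps = rng.normal(0.0, spec.noise_sd, size=spec.n)
    return PairedData(x, _predict(spec.scenario_id, spec.slope, x, eps))


def default_grid(scenario_id: int, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Default slope grid for a scenario: its full permitted range at ``step``
    resolution, with the highlighted slopes {0.3, 0.6, 0.9, 1.0} always included."""
    lo, hi = SLOPE_RANGES[scenario_id]
    grid = np.arange(lo, hi + step / 2, step)
    grid = np.union1d(np.round(grid, 10), HIGHLIGHT_SLOPES)
    return grid


@dataclass(frozen=True)
class SweepResult:
    """Per-slope measure reports for one scenario, one noise realization."""

    scenario_id: int
    grid: np.ndarray
    reports: Sequence[MeasureReport]
    n: int
    noise_sd: float
    seed: int
    x_spec: object = "1..n"
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per slope, columns = slope + every measure."""
        rows = [{"slope": s, **rep.to_dict()} for s, rep in zip(self.grid, self.reports)]
        return pd.DataFrame(rows)

    def column(self, measure: str) -> np.ndarray:
        vals = [getattr(rep, measure) for rep in self.reports]
        return np.array([np.nan if v is None else v for v in vals], dtype=float)


def sweep(
    scenario_id: int,
    grid=None,
    n: int = DEFAULT_N,
    noise_sd: float | None = None,
    seed: int = 0,
    x_spec="1..n",
) -> SweepResult:
    """Evaluate all measures along a slope grid for one scenario.

    For the noisy scenarios a single ε vector is drawn once and reused at
    every grid point, so the resulting curves are smooth functions of the
    slope within one realization.
    """
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_SD if scenario_id in (3, 4) else 0.0
    grid = default_grid(scenario_id) if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InputError("slope grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise InputError("slope grid must be strictly increasing")
    lo, hi = SLOPE_RANGES[scenario_id]
    if grid[0] < lo or grid[-1] > hi:
        raise InputError(f"grid outside scenario {scenario_id} slope range [{lo}, {hi}]")

    x = make_observed(x_spec, n)
    eps = None
    if scenario_id in (3, 4):
        if noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        eps = np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    reports = [
        full_report(PairedData(x, _predict(scenario_id, float(b), x, eps))) for b in grid
    ]
    return SweepResult(scenario_id, grid, reports, n, float(noise_sd), seed, x_spec)
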