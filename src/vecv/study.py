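"""Comparison study: how VEcv, E1, dr and r respond to slope, noise and sample size.

Runs slope sweeps over the four simulated scenarios and produces the
tables and figures that expose the divergence between correlation and
accuracy: measure-vs-slope curves per scenario, the r (and r²) vs VEcv
relationship, the VEcv vs E1 relationship under different sample sizes and
noise levels, bias tables (r on the percent scale minus VEcv), and
ranking-agreement checks between measures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .simulate import DEFAULT_N, DEFAULT_NOISE_SD, SweepResult, sweep

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_study",
    "bias_vs_slope",
    "rank_agreement",
    "zero_crossings",
]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the full comparison study.

    Defaults reproduce the reference setup: scenarios 1-4 with n = 30 and
    noise sd = 2 for the noisy scenarios, plus scenario-4 extensions at
    (n=30, sd=2), (n=300, sd=2) and (n=300, sd=3) for the VEcv-vs-E1
    relationship.
    """

    scenarios: Sequence[int] = (1, 2, 3, 4)
    n: int = DEFAULT_N
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    grids: dict = field(default_factory=dict)  # scenario_id -> explicit grid
    extensions: Sequence[tuple[int, float]] = ((30, 2.0), (300, 2.0), (300, 3.0))
    make_plots: bool = True


@dataclass(frozen=True)
class StudyResult:
    sweeps: dict  # scenario_id -> SweepResult
    r_vs_vecv: pd.DataFrame
    vecv_vs_e1: pd.DataFrame
    bias_tables: dict  # scenario_id -> DataFrame
    rank_agreement_vecv_e1: dict  # scenario_id -> float
    zero_crossings: dict  # scenario_id -> {measure: slope}
    config: StudyConfig


def bias_vs_slope(sw: SweepResult, r_scale: float = 100.0) -> pd.DataFrame:
    """Departure of r from VEcv along the slope grid.

    r is mapped onto the percent scale (×100 by default, configurable off
    with ``r_scale=1``) before differencing, since the two are compared on
    one axis.  The bias is 0 at slope 1 for noiseless scenarios and grows
    quadratically as the slope departs from 1.
    """
    r = sw.column("r") * r_scale
    vecv = sw.column("vecv_pct")
    return pd.DataFrame({"slope": sw.grid, "r_scaled": r, "vecv_pct": vecv, "bias": r - vecv})


def rank_agreement(
    sw: SweepResult, measure_a: str, measure_b: str, decimals: int | None = 9
) -> float:
    """Spearman rank correlation between two measure columns of a sweep.

    1.0 means the two measures order the simulated predictive models
    identically.  Columns are rounded to ``decimals`` before ranking
    (default 9 decimals of the percent scale) so that analytically tied
    values — e.g. the slopes 1±δ of a noiseless sweep, whose measures are
    equal functions of \\|1−β\\| — rank as ties instead of being broken by
    floating-point noise; pass ``decimals=None`` for raw ranking.  A
    constant column has no ranking; NaN is returned with a warning.
    """
    a, b = sw.column(measure_a), sw.column(measure_b)
    if a.size < 3:
        raise InputError("rank agreement needs at least 3 grid points")
    if decimals is not None:
        a, b = np.round(a, decimals), np.round(b, decimals)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(
            f"rank agreement undefined: {measure_a if np.ptp(a) == 0 else measure_b} "
            "is constant across the sweep",
            stacklevel=2,
        )
        return float("nan")
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    if np.array_equal(ra, rb):
        return 1.0  # identical orderings (incl. ties) — exactly 1 by definition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(a, b).statistic
    return float(rho)


def zero_crossings(sw: SweepResult, measures=("vecv_pct", "e1_pct", "dr_pct")) -> dict:
    """Slope at which each measure crosses 0%, by linear interpolation on the grid.

    Only the crossing nearest slope 1 from below is reported (the curves
    are monotone there); NaN if the measure never changes sign on the grid.
    """
    out = {}
    for m in measures:
        y = sw.column(m)
        sign_change = np.nonzero(np.diff(np.sign(y)) != 0)[0]
        if sign_change.size == 0:
            out[m] = float("nan")
            continue
        i = sign_change[-1]
        x0, x1, y0, y1 = sw.grid[i], sw.grid[i + 1], y[i], y[i + 1]
        out[m] = float(x0) if y1 == y0 else float(x0 - y0 * (x1 - x0) / (y1 - y0))
    return out


def _plot_sweep(sw: SweepResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for m, label in (("vecv_pct", "VEcv"), ("e1_pct", "E1"), ("dr_pct", "dr")):
        ax.plot(sw.grid, sw.column(m), label=label)
    ax.plot(sw.grid, sw.column("r") * 100, label="r (x100)", linestyle="--")
    ax.axhline(0, color="blue", lw=0.8)
    for s, style in ((1.0, "-"), (0.9, "--"), (0.6, "--"), (0.3, "--")):
        ax.axvline(s, lw=0.6, linestyle=style, color="grey")
    ax.set_xlabel("slope")
    ax.set_ylabel("measure (%)")
    ax.set_title(f"scenario {sw.scenario_id} (n={sw.n}, sd={sw.noise_sd})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_xy(df: pd.DataFrame, x: str, y: str, hue: str, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for key, grp in df.groupby(hue):
        ax.plot(grp[x], grp[y], marker=".", ms=3, lw=1, label=f"{hue}={key}")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_study(config: StudyConfig = StudyConfig(), out_dir=None) -> StudyResult:
    """Run the full comparison study; optionally write tables/plots to ``out_dir``.

    Emits (when ``out_dir`` is given): one sweep CSV per scenario, the
    r-vs-VEcv curve table, the VEcv-vs-E1 curve table across the noise/size
    extensions, and line plots.  The VEcv-vs-E1 *plot* keeps positive values
    only; the table keeps everything.  A JSON summary records the resolved
    configuration and seed so every run is reproducible.
    """
    sweeps, bias_tables, agreement, crossings = {}, {}, {}, {}
    for sc in config.scenarios:
        sd = config.noise_sd if sc in (3, 4) else 0.0
        sw = sweep(sc, grid=config.grids.get(sc), n=config.n, noise_sd=sd, seed=config.seed)
        sweeps[sc] = sw
        bias_tables[sc] = bias_vs_slope(sw)
        agreement[sc] = (
            rank_agreement(sw, "vecv_pct", "e1_pct") if sw.grid.size >= 3 else float("nan")
        )
        crossings[sc] = zero_crossings(sw)

    r_rows = []
    for sc, sw in sweeps.items():
        r = sw.column("r")
        r_rows.append(
            pd.DataFrame(
                {"scenario": sc, "slope": sw.grid, "r": r, "r2": r * r,
                 "vecv_pct": sw.column("vecv_pct")}
            )
        )
    r_vs_vecv = pd.concat(r_rows, ignore_index=True)

    ext_rows = []
    for n_ext, sd_ext in config.extensions:
        sw = sweep(4, n=n_ext, noise_sd=sd_ext, seed=config.seed)
        ext_rows.append(
            pd.DataFrame(
                {"n": n_ext, "noise_sd": sd_ext, "slope": sw.grid,
                 "vecv_pct": sw.column("vecv_pct"), "e1_pct": sw.column("e1_pct")}
            )
        )
    vecv_vs_e1 = (
        pd.concat(ext_rows, ignore_index=True)
        if ext_rows
        else pd.DataFrame(columns=["n", "noise_sd", "slope", "vecv_pct", "e1_pct"])
    )

    result = StudyResult(sweeps, r_vs_vecv, vecv_vs_e1, bias_tables, agreement, crossings, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sc, sw in sweeps.items():
            sw.to_frame().to_csv(out / f"sweep_scenario{sc}.csv", index=False)
            bias_tables[sc].to_csv(out / f"bias_scenario{sc}.csv", index=False)
        r_vs_vecv.to_csv(out / "r_vs_vecv.csv", index=False)
        vecv_vs_e1.to_csv(out / "vecv_vs_e1.csv", index=False)
        summary = {
            "config": {
                "scenarios": list(config.scenarios),
                "n": config.n,
                "noise_sd": config.noise_sd,
                "seed": config.seed,
                "extensions": [list(e) for e in config.extensions],
            },
            "rank_agreement_vecv_e1": agreement,
            "zero_crossings": crossings,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        if config.make_plots:
            for sc, sw in sweeps.items():
                _plot_sweep(sw, out / f"sweep_scenario{sc}.png")
            _plot_xy(r_vs_vecv, "vecv_pct", "r", "scenario", out / "r_vs_vecv.png",
                     "r vs VEcv")
            pos = vecv_vs_e1[(vecv_vs_e1.vecv_pct > 0) & (vecv_vs_e1.e1_pct > 0)].copy()
            pos["setting"] = pos.apply(lambda q: f"n={int(q.n)},sd={q.noise_sd:g}", axis=1)
            _plot_xy(pos, "e1_pct", "vecv_pct", "setting", out / "vecv_vs_e1.png",
                     "VEcv vs E1 (positive values)")
    return result
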