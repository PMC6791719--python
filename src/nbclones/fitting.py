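"""Grid-search fit of the two free parameters (P(c->cc), Ts).

All other parameters follow from the clone observations through
:func:`nbclones.algebra.reduce_parameters`. For every pixel of a
(P(c->cc), Ts) grid a cohort of clones is simulated and compared with the
observed cohort through two error metrics:

* **size error** — the sum of two-sample Kolmogorov-Smirnov distances between
  simulated and observed clone-size distributions over the 3 clone categories
  and the 4 observation stages (12 terms);
* **composition error** — the sum over the 4 stages of the Euclidean distance
  between the (CI, MIXED, SYP) proportion vectors (12 scalar terms).

Each error surface is min-max normalized over the grid (making the two
families commensurate and scale-free) and the combined error is their mean;
the fit is the argmin of the combined surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import ks_2samp

from .algebra import (
    InfeasibleParameterError,
    SingletonSummary,
    TwoCellSummary,
    feasible_region,
    reduce_parameters,
)
from .model import (
    CATEGORIES,
    CohortSummary,
    _record_steps,
    _simulate_block,
    summarize_states,
)

__all__ = ["ks_distance", "size_error", "composition_error", "grid_fit", "ErrorMap"]

DEFAULT_TS_RANGE = (0.25, 4.0)


def ks_distance(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup_x |F_a(x) - F_b(x)|.

    Empty-sample policy: a category absent from exactly one sample is maximal
    mismatch (1.0); absent from both, a vacuous match (0.0).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 and b.size == 0:
        return 0.0
    if a.size == 0 or b.size == 0:
        return 1.0
    with np.errstate(divide="ignore"):  # p-value internals choke on n=1; only
        return float(ks_2samp(a, b, method="asymp").statistic)  # the statistic is used


def _check_times(sim: CohortSummary, obs: CohortSummary) -> None:
    if len(sim.times) != len(obs.times) or not np.allclose(sim.times, obs.times):
        raise ValueError(
            f"timepoints differ between cohorts: {sim.times} vs {obs.times}"
        )


def size_error(sim: CohortSummary, obs: CohortSummary) -> float:
    """Sum of KS distances over categories x timepoints (12 terms for 4 stages)."""
    _check_times(sim, obs)
    total = 0.0
    for i in range(len(sim.times)):
        for cat in CATEGORIES:
            total += ks_distance(sim.sizes[i][cat], obs.sizes[i][cat])
    return total


def composition_error(sim: CohortSummary, obs: CohortSummary) -> float:
    """Sum over timepoints of the Euclidean distance between proportion vectors."""
    _check_times(sim, obs)
    for name, summary in (("sim", sim), ("obs", obs)):
        sums = summary.proportions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"{name} proportions do not sum to 1: {sums}")
    diff = sim.proportions - obs.proportions
    return float(np.sqrt((diff**2).sum(axis=1)).sum())


def _minmax(surface: np.ndarray) -> np.ndarray:
    """Min-max normalize over the finite (feasible) entries; infeasible
    pixels stay at +inf so they can never be the argmin."""
    finite = np.isfinite(surface)
    lo, hi = surface[finite].min(), surface[finite].max()
    out = np.full_like(surface, np.inf)
    if hi - lo <= 0:
        out[finite] = 0.0
    else:
        out[finite] = (surface[finite] - lo) / (hi - lo)
    return out


@dataclass(frozen=True)
class ErrorMap:
    """Error surfaces over the (P(c->cc), Ts) grid.

    ``err_size`` and ``err_comp`` are the raw summed errors; ``err_combined``
    is the mean of their min-max normalized versions. ``argmin`` indexes
    (row = P(c->cc), column = Ts) of the combined minimum; ties resolve to
    the lowest (row, column) in axis order.
    """

    pccc_axis: np.ndarray
    ts_axis: np.ndarray
    err_size: np.ndarray
    err_comp: np.ndarray
    err_combined: np.ndarray
    argmin: tuple[int, int]
    seed: int
    n_clones_per_pixel: int

    @property
    def best_pccc(self) -> float:
        return float(self.pccc_axis[self.argmin[0]])

    @property
    def best_ts(self) -> float:
        return float(self.ts_axis[self.argmin[1]])

    def save(self, outdir: str | Path) -> None:
        """Write the three surfaces as CSV matrices plus JSON metadata."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, mat in (
            ("err_size", self.err_size),
            ("err_comp", self.err_comp),
            ("err_combined", self.err_combined),
        ):
            np.savetxt(outdir / f"{name}.csv", mat, delimiter=",")
        meta = {
            "pccc_axis": self.pccc_axis.tolist(),
            "ts_axis": self.ts_axis.tolist(),
            "argmin": list(self.argmin),
            "best_pccc": self.best_pccc,
            "best_ts": self.best_ts,
            "seed": self.seed,
            "n_clones_per_pixel": self.n_clones_per_pixel,
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2))

    def plot(self, path: str | Path | None = None):
        """Heatmaps of the three error surfaces (matplotlib figure)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(13, 4), constrained_layout=True)
        extent = [
            self.ts_axis[0],
            self.ts_axis[-1],
            self.pccc_axis[0],
            self.pccc_axis[-1],
        ]
        for ax, (name, mat) in zip(
            axes,
            (
                ("size error", self.err_size),
                ("composition error", self.err_comp),
                ("combined error", self.err_combined),
            ),
        ):
            im = ax.imshow(mat, origin="lower", aspect="auto", extent=extent)
            ax.plot(self.best_ts, self.best_pccc, "r+", markersize=12)
            ax.set_xlabel("Ts (days)")
            ax.set_ylabel("P(c→cc)")
            ax.set_title(name)
            fig.colorbar(im, ax=ax)
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def grid_fit(
    obs: CohortSummary,
    two_cell: TwoCellSummary,
    singletons: SingletonSummary,
    tc: float,
    pccc_axis: np.ndarray | None = None,
    ts_axis: np.ndarray | None = None,
    shape: tuple[int, int] = (100, 100),
    n_clones_per_pixel: int = 1000,
    seed: int = 0,
    step_hours: float = 1.0,
) -> ErrorMap:
    """Exhaustive scan of the (P(c->cc), Ts) plane against an observed cohort.

    For each pixel the remaining parameters are reduced from the observed
    two-cell and singleton summaries, a cohort of ``n_clones_per_pixel``
    clones is simulated at the observation times of ``obs``, and both error
    metrics are evaluated. By default the P(c->cc) axis spans the feasible
    region implied by the summaries and the Ts axis spans 0.25–4 d.

    Randomness is drawn from one substream per P(c->cc) grid value, derived
    deterministically from ``seed``, so the map is reproducible given
    (seed, grid, n_clones_per_pixel).
    """
    if n_clones_per_pixel < 1:
        raise ValueError("n_clones_per_pixel must be at least 1")
    if pccc_axis is None:
        lo, hi = feasible_region(two_cell, singletons)
        pccc_axis = np.linspace(lo, hi, shape[0])
    else:
        pccc_axis = np.asarray(pccc_axis, dtype=float)
    if ts_axis is None:
        ts_axis = np.linspace(*DEFAULT_TS_RANGE, shape[1])
    else:
        ts_axis = np.asarray(ts_axis, dtype=float)

    times = obs.times
    record_steps = _record_steps(times, step_hours)
    step_days = step_hours / 24.0

    n_p, n_t = len(pccc_axis), len(ts_axis)
    err_size = np.empty((n_p, n_t))
    err_comp = np.empty((n_p, n_t))
    n_feasible = 0
    for i, pccc in enumerate(pccc_axis):
        try:
            params = reduce_parameters(two_cell, singletons, float(pccc), ts=ts_axis[0], tc=tc)
        except InfeasibleParameterError:
            err_size[i] = np.inf
            err_comp[i] = np.inf
            continue
        n_feasible += 1
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, i))))
        block = _simulate_block(
            params, ts_axis, n_clones_per_pixel, record_steps, step_days, rng
        )
        for j in range(n_t):
            sim = summarize_states(block[:, j], times)
            err_size[i, j] = size_error(sim, obs)
            err_comp[i, j] = composition_error(sim, obs)
    if n_feasible == 0:
        raise InfeasibleParameterError("no grid point lies in the feasible region")
    combined = 0.5 * (_minmax(err_size) + _minmax(err_comp))
    argmin = np.unravel_index(int(np.argmin(combined)), combined.shape)
    return ErrorMap(
        pccc_axis=pccc_axis,
        ts_axis=ts_axis,
        err_size=err_size,
        err_comp=err_comp,
        err_combined=combined,
        argmin=(int(argmin[0]), int(argmin[1])),
        seed=seed,
        n_clones_per_pixel=n_clones_per_pixel,
    )
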