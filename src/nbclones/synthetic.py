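"""Synthetic observation cohorts emulating the Flybow clonal experiment.

The original clone-by-clone data are not deposited; what is printed are
summary statistics (two-cell-clone composition, quiescent-singleton
frequencies, mean CI clone size at 2 d, per-timepoint clone counts) shipped
here as a versioned JSON fixture. :func:`generate_cohort` produces cohorts
with the structure of the experiment — cross-sectional sampling, with a fresh
set of clones scored at each timepoint, since each animal is dissected once —
by simulating from a known parameter set. Scoring is treated as exact: clone
sizes are cell counts and categories carry no misclassification noise, as in
the underlying model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .algebra import SingletonSummary, TwoCellSummary, reduce_parameters
from .model import (
    CATEGORIES,
    CohortSummary,
    DivisionParams,
    _as_rng,
    _record_steps,
    _simulate_block,
    cohort_table,
    summarize_states,
)

__all__ = ["ObservationDesign", "ClonalFixtures", "load_fixtures", "generate_cohort"]


@dataclass(frozen=True)
class ObservationDesign:
    """How many clones are scored at each observation time."""

    times: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("clone counts must be non-negative")
        if list(self.times) != sorted(self.times):
            raise ValueError("times must be sorted")


@dataclass(frozen=True)
class ClonalFixtures:
    """Printed summary statistics of the clonal experiment."""

    two_cell: TwoCellSummary
    singletons: SingletonSummary
    design: ObservationDesign
    mean_ci_size: float  #: mean size of CI clones at ``mean_ci_time``
    mean_ci_time: float  #: days after clonal induction
    best_pccc: float  #: best-fit P(c->cc)
    best_ts: float  #: best-fit Ts (days)
    tc: float  #: measured C division time (days)
    printed_reduction: dict[str, float]  #: the derived parameters as printed (2 d.p.)

    def fitted_params(self) -> DivisionParams:
        """The full best-fit parameter set, reduced exactly from the summaries."""
        return reduce_parameters(
            self.two_cell, self.singletons, self.best_pccc, ts=self.best_ts, tc=self.tc
        )


def load_fixtures() -> ClonalFixtures:
    """Load the shipped JSON fixture of printed clone statistics."""
    raw = json.loads(
        resources.files("nbclones").joinpath("data/fixtures.json").read_text()
    )
    return ClonalFixtures(
        two_cell=TwoCellSummary(
            raw["two_cell"]["p_cc"], raw["two_cell"]["p_cs"], raw["two_cell"]["p_ss"]
        ),
        singletons=SingletonSummary(
            raw["singletons"]["p_qc"], raw["singletons"]["p_qs"]
        ),
        design=ObservationDesign(
            times=tuple(raw["design"]["times_days"]),
            counts=tuple(raw["design"]["counts"]),
        ),
        mean_ci_size=raw["mean_ci_clone_size"]["value"],
        mean_ci_time=raw["mean_ci_clone_size"]["time_days"],
        best_pccc=raw["best_fit"]["p_ccc"],
        best_ts=raw["best_fit"]["ts_days"],
        tc=raw["best_fit"]["tc_days"],
        printed_reduction=dict(raw["printed_reduction"]),
    )


def generate_cohort(
    params: DivisionParams,
    design: ObservationDesign | None = None,
    rng: np.random.Generator | int | None = None,
    step_hours: float = 1.0,
    return_table: bool = False,
) -> CohortSummary | tuple[CohortSummary, pd.DataFrame]:
    """Simulate a cross-sectional observation cohort.

    For each timepoint ``design.times[i]`` an independent set of
    ``design.counts[i]`` clones is simulated up to that time and scored only
    there (different animals are dissected at different times). Returns the
    cohort summary and, optionally, the raw tidy clone table.
    """
    design = design or load_fixtures().design
    rng = _as_rng(rng)
    step_days = step_hours / 24.0
    per_time: list[CohortSummary] = []
    tables: list[pd.DataFrame] = []
    for t, n in zip(design.times, design.counts):
        if n == 0:
            per_time.append(
                CohortSummary(
                    times=(t,),
                    proportions=np.full((1, 3), np.nan),
                    sizes=({cat: np.array([], dtype=np.int64) for cat in CATEGORIES},),
                    n_clones=(0,),
                )
            )
            continue
        record_steps = _record_steps((t,), step_hours)
        states = _simulate_block(
            params, np.array([params.ts]), n, record_steps, step_days, rng
        )[:, 0]
        per_time.append(summarize_states(states, (t,)))
        if return_table:
            tables.append(cohort_table(states, (t,)))
    summary = CohortSummary(
        times=tuple(design.times),
        proportions=np.vstack([s.proportions for s in per_time]),
        sizes=tuple(s.sizes[0] for s in per_time),
        n_clones=tuple(s.n_clones[0] for s in per_time),
    )
    if return_table:
        columns = [
            "clone_id", "time_days", "n_c_active", "n_c_quiescent",
            "n_s_active", "n_s_quiescent", "size", "category",
        ]
        table = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=columns)
        )
        return summary, table
    return summary
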