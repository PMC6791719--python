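"""Stochastic two-type clone growth model for *Drosophila* neuroblast tumors.

Tumor neuroblasts (tNBs) come in two identities: early-like Chinmo+Imp+ cells
("C cells"), which sit at the top of the tumor hierarchy, and late-like
Syp+E93+ cells ("S cells"). A clone grows from a single founder cell. Time is
discretized in short steps (1 h by default); at each step every *active* cell
of type x divides independently with probability ``1 - exp(-dt/Tx)``, the
exact probability that an exponential clock with mean division time ``Tx``
fires within the step. A dividing cell is replaced by two daughters whose
joint type is drawn from the type's division-outcome distribution
(x -> CC / CS / SS), and every newly created cell of type y — including the
founder — is permanently quiescent with probability ``qy``. Quiescent cells
never divide but remain countable members of the clone; there is no cell
death, so clone size never decreases.

Clones are classified by composition: CI (C cells only), SYP (S cells only)
or MIXED (both), counting quiescent cells.

All division decisions within a step are made against the cell roster at the
start of the step; daughters first become eligible to divide in the next step
(synchronous update). Cohorts are simulated as vectorized compartment counts
(n_C_active, n_C_quiescent, n_S_active, n_S_quiescent): cells within a
compartment are exchangeable, so binomial and multinomial draws at the
compartment level realize exactly the same process law as per-cell draws.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CloneCategory",
    "CATEGORIES",
    "DivisionParams",
    "CloneState",
    "SimulationConfig",
    "CohortSummary",
    "DivisionTally",
    "step_probability",
    "classify",
    "simulate_clone",
    "simulate_cohort",
    "cohort_table",
]

_PROB_TOL = 1e-12

#: Default observation times (days): 8 h, 2 d, 4 d and 8 d after clonal induction.
DEFAULT_RECORD_TIMES = (1.0 / 3.0, 2.0, 4.0, 8.0)


class CloneCategory(str, enum.Enum):
    """Composition class of a clone (quiescent cells count)."""

    CI = "CI"  #: Chinmo+Imp+ (C) cells only
    MIXED = "MIXED"  #: both cell types present
    SYP = "SYP"  #: Syp+E93+ (S) cells only


CATEGORIES: tuple[CloneCategory, ...] = (
    CloneCategory.CI,
    CloneCategory.MIXED,
    CloneCategory.SYP,
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class DivisionParams:
    """Full parameterization of the division / quiescence rules.

    Parameters
    ----------
    pc : float
        Probability that the founder cell is a C cell (S with probability 1-pc).
    tc, ts : float
        Division times of C and S cells, in days (> 0). The division rates
        ``kc = 1/tc`` and ``ks = 1/ts`` are derived properties, never stored.
    p_ccc, p_ccs, p_css : float
        C-division outcome probabilities (C -> CC / CS / SS); must sum to 1.
    p_sss, p_scs, p_scc : float
        S-division outcome probabilities (S -> SS / CS / CC); must sum to 1.
    qc, qs : float
        Probability that a newly created C / S cell (founder included) is
        permanently quiescent.
    """

    pc: float
    tc: float
    ts: float
    p_ccc: float
    p_ccs: float
    p_css: float
    p_sss: float
    p_scs: float
    p_scc: float
    qc: float
    qs: float

    def __post_init__(self) -> None:
        for name in ("pc", "p_ccc", "p_ccs", "p_css", "p_sss", "p_scs", "p_scc", "qc", "qs"):
            _check_prob(name, getattr(self, name))
        if self.tc <= 0 or self.ts <= 0:
            raise ValueError(f"division times must be positive, got tc={self.tc}, ts={self.ts}")
        if abs(self.p_ccc + self.p_ccs + self.p_css - 1.0) > _PROB_TOL:
            raise ValueError("C-division outcome probabilities must sum to 1")
        if abs(self.p_sss + self.p_scs + self.p_scc - 1.0) > _PROB_TOL:
            raise ValueError("S-division outcome probabilities must sum to 1")

    @property
    def ps(self) -> float:
        """Probability that the founder is an S cell."""
        return 1.0 - self.pc

    @property
    def kc(self) -> float:
        """C division rate, 1/day."""
        return 1.0 / self.tc

    @property
    def ks(self) -> float:
        """S division rate, 1/day."""
        return 1.0 / self.ts

    def mirrored(self) -> "DivisionParams":
        """The same rules with the roles of C and S cells swapped."""
        return DivisionParams(
            pc=self.ps,
            tc=self.ts,
            ts=self.tc,
            p_ccc=self.p_sss,
            p_ccs=self.p_scs,
            p_css=self.p_scc,
            p_sss=self.p_ccc,
            p_scs=self.p_ccs,
            p_scc=self.p_css,
            qc=self.qs,
            qs=self.qc,
        )

    def with_reverse_division(self, epsilon: float) -> "DivisionParams":
        """Allow S -> CC reverse divisions with probability ``epsilon``.

        Sets ``p_scc = epsilon`` and ``p_sss = 1 - epsilon - p_scs``.
        """
        _check_prob("epsilon", epsilon)
        return replace(self, p_scc=epsilon, p_sss=1.0 - epsilon - self.p_scs)


@dataclass(frozen=True)
class CloneState:
    """Cell counts of one clone at one time point."""

    n_c_active: int
    n_c_quiescent: int
    n_s_active: int
    n_s_quiescent: int
    t: float = 0.0

    def __post_init__(self) -> None:
        counts = (self.n_c_active, self.n_c_quiescent, self.n_s_active, self.n_s_quiescent)
        if any(c < 0 for c in counts):
            raise ValueError(f"cell counts must be non-negative, got {counts}")

    @property
    def n_c(self) -> int:
        return self.n_c_active + self.n_c_quiescent

    @property
    def n_s(self) -> int:
        return self.n_s_active + self.n_s_quiescent

    @property
    def size(self) -> int:
        return self.n_c + self.n_s


@dataclass(frozen=True)
class SimulationConfig:
    """Time discretization and observation schedule.

    ``record_times`` (days) must be sorted, lie on the step grid and not
    exceed ``duration``.
    """

    step_hours: float = 1.0
    record_times: tuple[float, ...] = DEFAULT_RECORD_TIMES
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_hours <= 0:
            raise ValueError("step_hours must be positive")
        times = tuple(float(t) for t in self.record_times)
        if list(times) != sorted(times):
            raise ValueError("record_times must be sorted")
        if times and times[-1] > self.duration + 1e-9:
            raise ValueError("record_times must not exceed duration")
        object.__setattr__(self, "record_times", times)

    @property
    def step_days(self) -> float:
        return self.step_hours / 24.0

    def record_steps(self) -> tuple[int, ...]:
        """Step indices at which states are recorded."""
        return _record_steps(self.record_times, self.step_hours)


def _record_steps(times: tuple[float, ...], step_hours: float) -> tuple[int, ...]:
    steps = []
    for t in times:
        s = t * 24.0 / step_hours
        si = int(round(s))
        if abs(s - si) > 1e-6:
            raise ValueError(
                f"record time {t} d does not lie on the {step_hours} h step grid"
            )
        steps.append(si)
    return tuple(steps)


def step_probability(dt: float, t_div: float) -> float:
    """Probability that a cell divides within a step of length ``dt``.

    For an exponential division clock with mean time ``t_div`` this is the
    integral of the waiting-time density over the step, ``1 - exp(-dt/t_div)``.
    Both arguments are in days.
    """
    if t_div <= 0:
        raise ValueError(f"division time must be positive, got {t_div}")
    if dt < 0:
        raise ValueError(f"step length must be non-negative, got {dt}")
    return -math.expm1(-dt / t_div)


def classify(state: CloneState | tuple[int, int, int, int]) -> CloneCategory:
    """Classify a clone as CI, MIXED or SYP from its cell counts.

    Quiescent cells count toward the composition. An empty clone is invalid
    (every clone contains at least its founder).
    """
    if isinstance(state, CloneState):
        n_c, n_s = state.n_c, state.n_s
    else:
        ca, cq, sa, sq = state
        n_c, n_s = ca + cq, sa + sq
    if n_c + n_s < 1:
        raise ValueError("cannot classify an empty clone")
    if n_s == 0:
        return CloneCategory.CI
    if n_c == 0:
        return CloneCategory.SYP
    return CloneCategory.MIXED


@dataclass
class DivisionTally:
    """Event counts accumulated during a simulation (diagnostics)."""

    n_c_divisions: int = 0
    n_s_divisions: int = 0
    c_outcomes: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))
    s_outcomes: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))
    n_c_created: int = 0
    n_s_created: int = 0
    n_c_quiescent: int = 0
    n_s_quiescent: int = 0


@dataclass(frozen=True)
class CohortSummary:
    """Per-timepoint category proportions and per-category size samples.

    ``proportions`` has one row per time in ``times`` and columns ordered
    (CI, MIXED, SYP); rows sum to 1. ``sizes[i][cat]`` holds the sorted total
    cell counts of the clones in category ``cat`` at ``times[i]``.
    """

    times: tuple[float, ...]
    proportions: np.ndarray
    sizes: tuple[dict[CloneCategory, np.ndarray], ...]
    n_clones: tuple[int, ...]

    def proportion(self, time: float, category: CloneCategory) -> float:
        i = self.times.index(time)
        return float(self.proportions[i, CATEGORIES.index(category)])

    def to_frame(self) -> pd.DataFrame:
        """Category proportions as a tidy DataFrame."""
        return pd.DataFrame(
            self.proportions,
            index=pd.Index(self.times, name="time_days"),
            columns=[c.value for c in CATEGORIES],
        ).reset_index()


def _as_rng(rng: np.random.Generator | int | None, fallback_seed: int = 0) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = fallback_seed
    return np.random.default_rng(rng)


def _simulate_block(
    params: DivisionParams,
    ts_values: np.ndarray,
    n_clones: int,
    record_steps: tuple[int, ...],
    step_days: float,
    rng: np.random.Generator,
    tally: DivisionTally | None = None,
) -> np.ndarray:
    """Simulate ``len(ts_values) x n_clones`` clones sharing all parameters
    except the S division time, which varies per row.

    Returns an int64 array of shape ``(n_times, n_ts, n_clones, 4)`` holding
    (n_C_active, n_C_quiescent, n_S_active, n_S_quiescent) at each recorded
    step.
    """
    m = len(ts_values)
    n = n_clones
    pv_c = np.array([params.p_ccc, params.p_ccs, params.p_css])
    pv_c = pv_c / pv_c.sum()
    pv_s = np.array([params.p_sss, params.p_scs, params.p_scc])
    pv_s = pv_s / pv_s.sum()
    p_div_c = step_probability(step_days, params.tc)
    p_div_s = np.array([step_probability(step_days, t) for t in ts_values])[:, None]

    # Founder: type with probability pc, quiescence with the type's q.
    is_c = rng.random((m, n)) < params.pc
    qdraw = rng.random((m, n))
    fq = np.where(is_c, qdraw < params.qc, qdraw < params.qs)
    ca = (is_c & ~fq).astype(np.int64)
    cq = (is_c & fq).astype(np.int64)
    sa = (~is_c & ~fq).astype(np.int64)
    sq = (~is_c & fq).astype(np.int64)
    if tally is not None:
        tally.n_c_created += int(is_c.sum())
        tally.n_s_created += int((~is_c).sum())
        tally.n_c_quiescent += int(cq.sum())
        tally.n_s_quiescent += int(sq.sum())

    record = {s: i for i, s in enumerate(record_steps)}
    n_steps = max(record_steps) if record_steps else 0
    out = np.empty((len(record_steps), m, n, 4), dtype=np.int64)
    if 0 in record:
        out[record[0]] = np.stack([ca, cq, sa, sq], axis=-1)

    for step in range(1, n_steps + 1):
        div_c = rng.binomial(ca, p_div_c)
        out_c = rng.multinomial(div_c, pv_c)
        div_s = rng.binomial(sa, p_div_s)
        out_s = rng.multinomial(div_s, pv_s)
        # daughters: C-division CC gives 2 C, CS one of each, SS 2 S;
        # S-division SS gives 2 S, CS one of each, CC 2 C.
        new_c = 2 * out_c[..., 0] + out_c[..., 1] + out_s[..., 1] + 2 * out_s[..., 2]
        new_s = out_c[..., 1] + 2 * out_c[..., 2] + 2 * out_s[..., 0] + out_s[..., 1]
        nq_c = rng.binomial(new_c, params.qc)
        nq_s = rng.binomial(new_s, params.qs)
        ca = ca - div_c + new_c - nq_c
        sa = sa - div_s + new_s - nq_s
        cq = cq + nq_c
        sq = sq + nq_s
        if tally is not None:
            tally.n_c_divisions += int(div_c.sum())
            tally.n_s_divisions += int(div_s.sum())
            tally.c_outcomes += out_c.sum(axis=(0, 1))
            tally.s_outcomes += out_s.sum(axis=(0, 1))
            tally.n_c_created += int(new_c.sum())
            tally.n_s_created += int(new_s.sum())
            tally.n_c_quiescent += int(nq_c.sum())
            tally.n_s_quiescent += int(nq_s.sum())
        if step in record:
            out[record[step]] = np.stack([ca, cq, sa, sq], axis=-1)
    return out


def summarize_states(states: np.ndarray, times: tuple[float, ...]) -> CohortSummary:
    """Build a :class:`CohortSummary` from a ``(n_times, n_clones, 4)`` array."""
    n_times, n_clones, _ = states.shape
    proportions = np.empty((n_times, 3))
    sizes: list[dict[CloneCategory, np.ndarray]] = []
    for i in range(n_times):
        n_c = states[i, :, 0] + states[i, :, 1]
        n_s = states[i, :, 2] + states[i, :, 3]
        size = n_c + n_s
        is_ci = n_s == 0
        is_syp = n_c == 0
        is_mixed = ~is_ci & ~is_syp
        masks = (is_ci, is_mixed, is_syp)
        proportions[i] = [m.sum() / n_clones for m in masks]
        sizes.append(
            {cat: np.sort(size[mask]) for cat, mask in zip(CATEGORIES, masks)}
        )
    return CohortSummary(
        times=tuple(times),
        proportions=proportions,
        sizes=tuple(sizes),
        n_clones=(n_clones,) * n_times,
    )


def simulate_clone(
    params: DivisionParams,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[CloneState]:
    """Simulate a single clone, returning its state at each record time."""
    config = config or SimulationConfig()
    rng = _as_rng(rng, config.seed)
    states = _simulate_block(
        params, np.array([params.ts]), 1, config.record_steps(), config.step_days, rng
    )
    return [
        CloneState(*(int(v) for v in states[i, 0, 0]), t=t)
        for i, t in enumerate(config.record_times)
    ]


def simulate_cohort(
    params: DivisionParams,
    n_clones: int,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
    return_states: bool = False,
    tally: DivisionTally | None = None,
) -> CohortSummary | tuple[CohortSummary, np.ndarray]:
    """Simulate ``n_clones`` independent clones and summarize them.

    All clones are followed longitudinally and recorded at every time in
    ``config.record_times``. With ``return_states=True`` the raw
    ``(n_times, n_clones, 4)`` count array is returned alongside the summary.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be at least 1")
    config = config or SimulationConfig()
    rng = _as_rng(rng, config.seed)
    states = _simulate_block(
        params,
        np.array([params.ts]),
        n_clones,
        config.record_steps(),
        config.step_days,
        rng,
        tally=tally,
    )[:, 0]
    summary = summarize_states(states, config.record_times)
    if return_states:
        return summary, states
    return summary


def cohort_table(states: np.ndarray, times: tuple[float, ...]) -> pd.DataFrame:
    """Tidy per-clone table from a ``(n_times, n_clones, 4)`` count array.

    Columns: clone_id, time_days, n_c_active, n_c_quiescent, n_s_active,
    n_s_quiescent, size, category.
    """
    n_times, n_clones, _ = states.shape
    rows = []
    for i, t in enumerate(times):
        n_c = states[i, :, 0] + states[i, :, 1]
        n_s = states[i, :, 2] + states[i, :, 3]
        size = n_c + n_s
        cat = np.where(n_s == 0, CloneCategory.CI.value,
                       np.where(n_c == 0, CloneCategory.SYP.value, CloneCategory.MIXED.value))
        rows.append(pd.DataFrame({
            "clone_id": np.arange(n_clones),
            "time_days": t,
            "n_c_active": states[i, :, 0],
            "n_c_quiescent": states[i, :, 1],
            "n_s_active": states[i, :, 2],
            "n_s_quiescent": states[i, :, 3],
            "size": size,
            "category": cat,
        }))
    return pd.concat(rows, ignore_index=True)
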