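"""Reduction of the division-scheme parameters from clone observations.

The general model has 9 independent parameters (pc, Tc, Ts, the division
outcome probabilities and the quiescence probabilities qc, qs). Three kinds of
printed clone measurements pin most of them down under the strict-hierarchy
assumption (S cells never produce C cells: P(s->ss)=1, P(s->cs)=P(s->cc)=0):

* Two-cell clones at 2 d reveal the first-division outcome mix:
  P(CC) = pc P(c->cc),  P(CS) = pc P(c->cs),  P(SS) = 1 - P(CC) - P(CS).
* Single-cell clones at 8 d are quiescent founders:
  P(QC) = pc qc,  P(QS) = (1-pc) qs.
* Clones still purely C grow as N(t) = e^{t/Tc}, so the mean CI clone size at
  time t gives Tc = t / ln(mean size).

Given the observed summaries and a value for P(c->cc), everything but Ts
follows algebraically; P(c->cc) and Ts remain the two free parameters that the
grid search (:mod:`nbclones.fitting`) fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import DivisionParams

__all__ = [
    "TwoCellSummary",
    "SingletonSummary",
    "InfeasibleParameterError",
    "estimate_division_time",
    "reduce_parameters",
    "feasible_region",
]

_SUM_TOL = 1e-9


class InfeasibleParameterError(ValueError):
    """A solved parameter falls outside [0, 1]."""


@dataclass(frozen=True)
class TwoCellSummary:
    """Observed composition frequencies of two-cell clones."""

    p_cc: float
    p_cs: float
    p_ss: float

    def __post_init__(self) -> None:
        for name in ("p_cc", "p_cs", "p_ss"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.p_cc + self.p_cs + self.p_ss - 1.0) > _SUM_TOL:
            raise ValueError("two-cell composition frequencies must sum to 1")


@dataclass(frozen=True)
class SingletonSummary:
    """Observed frequencies of single-cell (quiescent-founder) clones at 8 d."""

    p_qc: float
    p_qs: float

    def __post_init__(self) -> None:
        for name in ("p_qc", "p_qs"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_qc + self.p_qs > 1.0 + _SUM_TOL:
            raise ValueError("singleton frequencies must sum to at most 1")


def estimate_division_time(mean_size: float, t: float) -> float:
    """Division time implied by exponential clone growth N(t) = e^{t/T}.

    Parameters
    ----------
    mean_size : float
        Mean clone size (> 1) of purely self-renewing clones at time ``t``.
    t : float
        Elapsed time in days (> 0).

    Returns
    -------
    float
        ``t / ln(mean_size)`` in days.
    """
    if t <= 0:
        raise ValueError(f"time must be positive, got {t}")
    if mean_size <= 1:
        raise ValueError(
            f"mean size must exceed 1 (no growth, division time undefined), got {mean_size}"
        )
    return t / math.log(mean_size)


def _solve(two_cell: TwoCellSummary, singletons: SingletonSummary, p_ccc: float):
    """Solve the reduction equations; returns (pc, p_ccs, p_css, qc, qs) or
    raises :class:`InfeasibleParameterError` naming the violated constraint."""
    if not (0.0 < p_ccc <= 1.0):
        raise InfeasibleParameterError(f"P(c->cc) must lie in (0, 1], got {p_ccc}")
    if two_cell.p_cc == 0.0:
        # No CC pairs observed: founders are never C unless P(CS) vanishes too.
        pc = 0.0
        if two_cell.p_cs > 0:
            raise InfeasibleParameterError(
                "P(CS) > 0 is impossible with pc = 0 under strict hierarchy"
            )
        if singletons.p_qc > 0:
            raise InfeasibleParameterError("P(QC) > 0 is impossible with pc = 0")
        p_ccs, qc = 0.0, 0.0
    else:
        pc = two_cell.p_cc / p_ccc
        if pc > 1.0 + 1e-12:
            raise InfeasibleParameterError(
                f"pc = P(CC)/P(c->cc) = {pc:.6g} exceeds 1 (P(c->cc) too small)"
            )
        pc = min(pc, 1.0)
        p_ccs = two_cell.p_cs / pc
        qc = singletons.p_qc / pc
    p_css = 1.0 - p_ccc - p_ccs
    if p_ccs > 1.0 + 1e-12:
        raise InfeasibleParameterError(f"P(c->cs) = {p_ccs:.6g} exceeds 1")
    if p_css < -1e-12:
        raise InfeasibleParameterError(
            f"P(c->ss) = 1 - P(c->cc) - P(c->cs) = {p_css:.6g} is negative"
        )
    if qc > 1.0 + 1e-12:
        raise InfeasibleParameterError(f"qc = P(QC)/pc = {qc:.6g} exceeds 1")
    ps = 1.0 - pc
    # compare before dividing: ps = 1 - pc is known only to ~1 ulp of 1, so a
    # ratio test on qs would blow rounding up by 1/ps near the pc -> 1 boundary
    if singletons.p_qs > ps + 5e-16:
        raise InfeasibleParameterError(
            f"qs = P(QS)/(1-pc) exceeds 1 (P(QS)={singletons.p_qs:.6g}, 1-pc={ps:.6g})"
        )
    qs = 0.0 if ps == 0.0 else min(singletons.p_qs / ps, 1.0)
    clip = lambda v: min(max(v, 0.0), 1.0)
    return clip(pc), clip(p_ccs), clip(p_css), clip(qc), clip(qs)


def reduce_parameters(
    two_cell: TwoCellSummary,
    singletons: SingletonSummary,
    p_ccc: float,
    ts: float,
    tc: float,
) -> DivisionParams:
    """Build the full parameter set from observations plus (P(c->cc), Ts, Tc).

    Applies the strict hierarchy (P(s->ss)=1) and solves

    * ``pc   = P(CC) / P(c->cc)``
    * ``P(c->cs) = P(CS) / pc``
    * ``P(c->ss) = 1 - P(c->cc) - P(c->cs)``
    * ``qc   = P(QC) / pc``
    * ``qs   = P(QS) / (1 - pc)``

    Raises
    ------
    InfeasibleParameterError
        If any solved quantity falls outside [0, 1]; the message names the
        violated constraint.
    """
    if ts <= 0 or tc <= 0:
        raise ValueError(f"division times must be positive, got ts={ts}, tc={tc}")
    pc, p_ccs, p_css, qc, qs = _solve(two_cell, singletons, p_ccc)
    # renormalize away rounding residue so DivisionParams invariants hold exactly
    p_css = max(0.0, 1.0 - p_ccc - p_ccs)
    p_ccs = 1.0 - p_ccc - p_css
    return DivisionParams(
        pc=pc,
        tc=tc,
        ts=ts,
        p_ccc=p_ccc,
        p_ccs=p_ccs,
        p_css=p_css,
        p_sss=1.0,
        p_scs=0.0,
        p_scc=0.0,
        qc=qc,
        qs=qs,
    )


def feasible_region(
    two_cell: TwoCellSummary, singletons: SingletonSummary
) -> tuple[float, float]:
    """Maximal interval of P(c->cc) values for which the reduction succeeds.

    The bounds follow from requiring every solved parameter to lie in [0, 1]:

    * ``pc <= 1``            gives ``P(c->cc) >= P(CC)``
    * ``qs <= 1``            gives ``P(c->cc) >= P(CC) / (1 - P(QS))``
    * ``P(c->ss) >= 0``      gives ``P(c->cc) <= P(CC) / (P(CC) + P(CS))``
    * ``qc <= 1``            gives ``P(c->cc) <= P(CC) / P(QC)``

    Returns
    -------
    (lo, hi) : tuple of float
        Closed interval; ``reduce_parameters`` succeeds for every value inside.

    Raises
    ------
    InfeasibleParameterError
        If the interval is empty.
    """
    p_cc, p_cs = two_cell.p_cc, two_cell.p_cs
    if p_cc == 0.0:
        if p_cs > 0 or singletons.p_qc > 0:
            raise InfeasibleParameterError(
                "no P(c->cc) is feasible: P(CS) or P(QC) positive while P(CC) = 0"
            )
        return (0.0, 1.0)  # pc = 0; the C-division scheme is unconstrained
    lo = p_cc
    if singletons.p_qs > 0:
        if singletons.p_qs >= 1.0:
            raise InfeasibleParameterError("P(QS) = 1 forces pc = 0, but P(CC) > 0")
        lo = max(lo, p_cc / (1.0 - singletons.p_qs))
    hi = 1.0
    if p_cs > 0:
        hi = min(hi, p_cc / (p_cc + p_cs))
    if singletons.p_qc > 0:
        hi = min(hi, p_cc / singletons.p_qc)
    if lo > hi + 1e-12:
        raise InfeasibleParameterError(
            f"empty feasible region for P(c->cc): lo={lo:.6g} > hi={hi:.6g}"
        )
    return (lo, max(lo, hi))
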