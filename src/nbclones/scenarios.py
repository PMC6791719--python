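"""Preset division schemes and clone-category dynamics curves.

Four simplified scenarios probe the hierarchy question with quiescence and
asymmetric divisions switched off and equal division times:

* ``no_hierarchy`` — both types convert symmetrically (C->CC/C->SS and
  S->SS/S->CC each 50/50); every clone rapidly becomes MIXED.
* ``strict_1``     — C cells duplicate or convert (50/50), S cells only
  self-renew; SYP clones persist while CI clones decay (the scheme the clone
  data support).
* ``strict_2``     — the C<->S mirror of strict_1.
* ``plastic``      — strict_1 plus a small S->CC reverse-division probability
  epsilon (default 1%), which destroys SYP-clone persistence.

``fitted`` is the full parameter set obtained by reducing the observed clone
summaries at the best-fit (P(c->cc), Ts); an optional epsilon adds reverse
divisions to it for perturbation experiments.

The founder-type probability and the common division time of the four extreme
scenarios are not constrained by the clone data; defaults are pc = 0.5 and
Tc = Ts = 1.6 d (the measured C division time). Scenario panels compare
curve shapes, not absolute levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_RECORD_TIMES,
    DivisionParams,
    SimulationConfig,
    simulate_cohort,
)

__all__ = ["PRESETS", "preset", "category_dynamics"]

PRESETS = ("no_hierarchy", "strict_1", "strict_2", "plastic", "fitted")

#: Division time (days) used by the four extreme scenarios.
SCENARIO_DIVISION_TIME = 1.6


def preset(
    name: str,
    epsilon: float | None = None,
    pc: float = 0.5,
    tc: float = SCENARIO_DIVISION_TIME,
) -> DivisionParams:
    """Return the :class:`DivisionParams` of a named scenario.

    ``epsilon`` sets the S->CC reverse-division probability for the
    ``plastic`` preset (default 0.01) and may also perturb ``fitted``;
    it is rejected for the other presets.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown scenario {name!r}; choose from {PRESETS}")
    if name == "fitted":
        from .synthetic import load_fixtures

        params = load_fixtures().fitted_params()
        if epsilon is not None:
            params = params.with_reverse_division(epsilon)
        return params
    if epsilon is not None and name != "plastic":
        raise ValueError(f"epsilon only applies to the 'plastic' or 'fitted' presets")
    base = dict(pc=pc, tc=tc, ts=tc, p_ccs=0.0, p_scs=0.0, qc=0.0, qs=0.0)
    if name == "no_hierarchy":
        return DivisionParams(p_ccc=0.5, p_css=0.5, p_sss=0.5, p_scc=0.5, **base)
    if name == "strict_1":
        return DivisionParams(p_ccc=0.5, p_css=0.5, p_sss=1.0, p_scc=0.0, **base)
    if name == "strict_2":
        return DivisionParams(p_ccc=1.0, p_css=0.0, p_sss=0.5, p_scc=0.5, **base)
    eps = 0.01 if epsilon is None else epsilon
    return DivisionParams(p_ccc=0.5, p_css=0.5, p_sss=1.0 - eps, p_scc=eps, **base)


def category_dynamics(
    params: DivisionParams,
    n_clones: int = 1000,
    times: tuple[float, ...] = DEFAULT_RECORD_TIMES,
    rng: np.random.Generator | int | None = None,
    step_hours: float = 1.0,
) -> pd.DataFrame:
    """Proportion of CI / MIXED / SYP clones at each time.

    Thin wrapper over :func:`nbclones.model.simulate_cohort`; returns a tidy
    DataFrame with columns (time_days, CI, MIXED, SYP).
    """
    config = SimulationConfig(
        step_hours=step_hours, record_times=tuple(times), duration=max(times)
    )
    summary = simulate_cohort(params, n_clones, config, rng=rng)
    return summary.to_frame()
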