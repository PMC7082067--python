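"""tMRCA densities implied by piecewise-constant coalescence-rate tables.

For a step-function hazard ``lambda(t)`` the coalescence-time density is
the piecewise exponential ``f(t) = lambda(t) * exp(-int_0^t lambda)``,
with the integral accumulated exactly segment by segment.  The last
segment of a rate table is open-ended, so the density has an analytic
exponential tail and integrates to 1 whenever all rates are positive.
"""

from __future__ import annotations

import numpy as np

from imtracer.io_msmc import RateTable
from imtracer.im_model import StartState

_COLUMN_OF_STATE = {StartState.S11: 0, StartState.S12: 1, StartState.S22: 2}


def _rates_for_state(rates: RateTable, s0: StartState) -> np.ndarray:
    if rates.n_lambda == 1:
        return rates.lambdas[:, 0]
    return rates.lambdas[:, _COLUMN_OF_STATE[s0]]


def cumulative_hazard(rates: RateTable, s0: StartState, eval_times,
                      mu: float) -> np.ndarray:
    """Integral of the step hazard from 0 to each time (times in
    generations, exact segment-wise accumulation)."""
    t = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if np.any(t < 0):
        raise ValueError("evaluation times must be nonnegative")
    lam = _rates_for_state(rates, s0) * mu  # per generation
    bounds = rates.boundaries_gens(mu)
    widths = np.diff(bounds)
    cum = np.concatenate([[0.0], np.cumsum(lam[:-1] * widths[:-1])])
    seg = np.clip(np.searchsorted(bounds[:-1], t, side="right") - 1, 0,
                  rates.n_segments - 1)
    return cum[seg] + lam[seg] * (t - bounds[seg])


def msmc_tmrca_density(rates: RateTable, s0: StartState, eval_times,
                       mu: float) -> np.ndarray:
    """Density f(t|s0) per generation implied by the rate table.

    ``s0`` selects the within-1, cross or within-2 column of a three-rate
    table; single-rate tables ignore ``s0``.  Rates must be nonnegative
    (zero rates give zero density; negative rates are rejected by
    :class:`RateTable` itself).
    """
    t = np.atleast_1d(np.asarray(eval_times, dtype=float))
    lam = _rates_for_state(rates, s0) * mu
    bounds = rates.boundaries_gens(mu)
    seg = np.clip(np.searchsorted(bounds[:-1], t, side="right") - 1, 0,
                  rates.n_segments - 1)
    return lam[seg] * np.exp(-cumulative_hazard(rates, s0, t, mu))


def msmc_survival(rates: RateTable, s0: StartState, eval_times,
                  mu: float) -> np.ndarray:
    """P(tMRCA > t) implied by the rate table."""
    return np.exp(-cumulative_hazard(rates, s0, eval_times, mu))
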