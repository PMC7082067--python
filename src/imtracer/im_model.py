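"""The two-island isolation-migration Markov process with time-dependent
parameters.

A pair of lineages sampled from two islands is tracked by a four-state
continuous-time Markov chain with states (S11, S12, S22, C): both lineages
in island 1, one in each, both in island 2, and coalesced.  With symmetric
per-lineage migration rate ``m`` (per generation) and diploid island sizes
``N1``, ``N2``, the off-diagonal rates are::

    S11 -> S12: 2m      S11 -> C: 1/(2 N1)
    S12 -> S11: m       S12 -> S22: m
    S22 -> S12: 2m      S22 -> C: 1/(2 N2)

Parameters are piecewise constant on the parameter segments of a
:class:`~imtracer.timegrid.TimeGrid`; state occupancies are propagated by
chaining per-segment matrix exponentials.  The coalescence-time density
for a start state s0 is ``f(t|s0) = P(S11 at t|s0)/(2 N1) +
P(S22 at t|s0)/(2 N2)``, and the cumulative migration probability of a
cross-population pair is ``M(t) = 1 - exp(-2 * integral of m)`` (either
lineage migrating mixes the pair; see :func:`cumulative_migration`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.linalg import expm

from imtracer.timegrid import TimeGrid

N_CAP = 10_000_000.0  # population sizes are restricted to this cap


class StartState(Enum):
    S11 = 0
    S12 = 1
    S22 = 2


@dataclass(frozen=True)
class IMParams:
    """Per-segment diploid sizes and symmetric migration rate on a grid.

    ``N1``, ``N2`` are diploid sizes in (0, 1e7]; ``m`` is the symmetric
    per-lineage migration rate per generation, ``m >= 0``.
    """

    grid: TimeGrid
    N1: np.ndarray
    N2: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_segments
        for name in ("N1", "N2", "m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per segment ({n})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.N1 <= 0) or np.any(self.N2 <= 0):
            raise ValueError("population sizes must be positive")
        if np.any(self.N1 > N_CAP) or np.any(self.N2 > N_CAP):
            raise ValueError(f"population sizes exceed the cap of {N_CAP:.0f}")
        if np.any(self.m < 0):
            raise ValueError("migration rates must be nonnegative")


def build_generator(m: float, N1: float, N2: float) -> np.ndarray:
    """4x4 generator of the IM chain, states ordered (S11, S12, S22, C)."""
    for val, name in ((m, "m"), (N1, "N1"), (N2, "N2")):
        if not np.isfinite(val):
            raise ValueError(f"non-finite parameter {name}")
    c1, c2 = 1.0 / (2.0 * N1), 1.0 / (2.0 * N2)
    Q = np.array([
        [-(2 * m + c1), 2 * m, 0.0, c1],
        [m, -2 * m, m, 0.0],
        [0.0, 2 * m, -(2 * m + c2), c2],
        [0.0, 0.0, 0.0, 0.0],
    ])
    return Q


def _segment_propagators(params: IMParams) -> np.ndarray:
    """Matrix exponentials over each closed parameter segment, as one
    stacked (n_segments-1, 4, 4) array.

    The absorbing structure lets the transient 3x3 block be exponentiated
    by batched eigendecomposition (the coalesced column is one minus the
    row sums); segments where that decomposition is ill-conditioned fall
    back to a dense Pade exponential.
    """
    bounds = params.grid.segment_boundaries_gens
    n = params.grid.n_segments
    dt = np.diff(bounds)[:n - 1]
    m, c1, c2 = (params.m[:n - 1], 1.0 / (2 * params.N1[:n - 1]),
                 1.0 / (2 * params.N2[:n - 1]))
    Q = np.zeros((n - 1, 4, 4))
    Q[:, 0, 1] = 2 * m
    Q[:, 0, 3] = c1
    Q[:, 0, 0] = -(2 * m + c1)
    Q[:, 1, 0] = m
    Q[:, 1, 2] = m
    Q[:, 1, 1] = -2 * m
    Q[:, 2, 1] = 2 * m
    Q[:, 2, 3] = c2
    Q[:, 2, 2] = -(2 * m + c2)
    Q3 = Q[:, :3, :3] * dt[:, None, None]
    P = np.empty((n - 1, 4, 4))
    with np.errstate(all="ignore"):
        try:
            w, V = np.linalg.eig(Q3)
            P3 = np.real((V * np.exp(w)[:, None, :]) @ np.linalg.inv(V))
        except np.linalg.LinAlgError:
            P3 = np.full((n - 1, 3, 3), np.nan)
    # a probability block must stay inside [0, 1]; excursions flag a
    # degenerate eigendecomposition
    bad = (~np.isfinite(P3).all(axis=(1, 2))
           | (P3 < -1e-9).any(axis=(1, 2))
           | (P3 > 1.0 + 1e-9).any(axis=(1, 2)))
    P[:, :3, :3] = np.clip(P3, 0.0, 1.0)
    P[:, 3, :3] = 0.0
    P[:, :, 3] = 1.0 - P[:, :, :3].sum(axis=2)
    P[:, 3, 3] = 1.0
    for i in np.nonzero(bad)[0]:
        P[i] = expm(Q[i] * dt[i])
    return P


def _state_probs_at_boundaries(params: IMParams) -> np.ndarray:
    """Occupancy vectors for the 3 start states at every segment left
    boundary; shape (n_segments, 3, 4)."""
    n = params.grid.n_segments
    out = np.empty((n, 3, 4))
    P = np.eye(4)[:3]  # rows: start states S11, S12, S22
    out[0] = P
    for i, prop in enumerate(_segment_propagators(params)):
        P = P @ prop
        out[i + 1] = P
    return out


def _occupancy_at(params: IMParams, t: np.ndarray) -> np.ndarray:
    """State occupancy (3 starts x 4 states) at arbitrary times
    (generations); shape (len(t), 3, 4)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("evaluation times must be nonnegative")
    bounds = params.grid.segment_boundaries_gens
    at_bounds = _state_probs_at_boundaries(params)
    seg = np.clip(np.searchsorted(bounds[:-1], t, side="right") - 1, 0,
                  params.grid.n_segments - 1)
    out = np.empty((len(t), 3, 4))
    for k, (ti, si) in enumerate(zip(t, seg)):
        dt = ti - bounds[si]
        if dt == 0.0:
            out[k] = at_bounds[si]
        else:
            Q = build_generator(params.m[si], params.N1[si], params.N2[si])
            out[k] = at_bounds[si] @ expm(Q * dt)
    return out


def im_density(params: IMParams, s0: StartState, eval_times) -> np.ndarray:
    """Coalescence-time density f(t|s0) per generation at ``eval_times``
    (generations)."""
    occ = _occupancy_at(params, eval_times)[:, s0.value, :]
    t = np.atleast_1d(np.asarray(eval_times, dtype=float))
    bounds = params.grid.segment_boundaries_gens
    seg = np.clip(np.searchsorted(bounds[:-1], t, side="right") - 1, 0,
                  params.grid.n_segments - 1)
    c1 = 1.0 / (2.0 * params.N1[seg])
    c2 = 1.0 / (2.0 * params.N2[seg])
    return occ[:, 0] * c1 + occ[:, 2] * c2


def im_survival(params: IMParams, s0: StartState, eval_times) -> np.ndarray:
    """P(not yet coalesced by t | s0)."""
    occ = _occupancy_at(params, eval_times)[:, s0.value, :]
    return occ[:, :3].sum(axis=1)


#: Exponent multiplier in M(t): a cross-population pair has mixed as soon
#: as either of its two lineages migrates, so the pair-level mixing hazard
#: is twice the per-lineage migration rate m.
PAIR_MIXING_FACTOR = 2.0


def migration_integral(params: IMParams, eval_times) -> np.ndarray:
    """Integral of m from 0 to t, exact over the piecewise-constant
    segments (per-lineage units)."""
    t = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if np.any(t < 0):
        raise ValueError("evaluation times must be nonnegative")
    bounds = params.grid.segment_boundaries_gens
    widths = np.diff(bounds)
    cum = np.concatenate([[0.0], np.cumsum(params.m[:-1] * widths[:-1])])
    seg = np.clip(np.searchsorted(bounds[:-1], t, side="right") - 1, 0,
                  params.grid.n_segments - 1)
    return cum[seg] + params.m[seg] * (t - bounds[seg])


def cumulative_migration(params: IMParams, eval_times) -> np.ndarray:
    """Cumulative migration probability M(t) of a cross-population pair.

    M(t) = 1 - exp(-2 * integral of m from 0 to t): the probability that
    at least one of the two lineages has migrated by time t, i.e. the
    proportion of cross-population ancestry already merged.  M(0) = 0,
    M is nondecreasing and bounded in [0, 1).
    """
    return -np.expm1(-PAIR_MIXING_FACTOR * migration_integral(params, eval_times))


def im_implied_coalrates(params: IMParams, rate_cap: float = 1.0,
                         refine: int = 1):
    """Hazard rates lambda(t|s0) implied by the IM model, as a rate table.

    Returns a mutation-scaled three-column :class:`RateTable` with columns
    (S11, S12, S22) on the parameter-segment grid, each closed segment
    optionally subdivided into ``refine`` equal pieces.  The hazard on a
    (sub)segment is the segment-averaged value ``-ln(S(t_{i+1})/S(t_i))/dt``
    (the hazard conversion ``lambda = f/S`` averaged over the segment), so
    the piecewise-exponential density rebuilt from these rates reproduces
    the IM survival function exactly at every boundary and converges to the
    IM density within segments as ``refine`` grows.  The open-ended final
    segment carries the instantaneous hazard ``f/S`` at its left boundary.
    Where survival has vanished the rate is reported as the documented cap
    ``rate_cap`` (per generation).
    """
    from imtracer.io_msmc import RateTable

    if refine < 1:
        raise ValueError("refine must be >= 1")
    grid = params.grid
    seg_bounds = grid.segment_boundaries_gens
    pieces = [np.linspace(seg_bounds[i], seg_bounds[i + 1], refine + 1)[:-1]
              for i in range(grid.n_segments - 1)]
    bounds = np.concatenate(pieces + [seg_bounds[-2:]])
    surv = _occupancy_at(params, bounds)[:, :, :3].sum(axis=2)  # (n_b, 3)
    n = len(bounds) - 1
    lam = np.empty((n, 3))
    dt = np.diff(bounds)
    for i in range(n - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(surv[i] > 0, surv[i + 1] / surv[i], 0.0)
        lam[i] = np.where(ratio > 0, -np.log(ratio) / dt[i], rate_cap)
        lam[i] = np.where(surv[i] > 0, lam[i], rate_cap)
    # open-ended final segment: instantaneous hazard at its left boundary
    occ = _occupancy_at(params, bounds[-2:-1])[0]
    dens = occ[:, 0] / (2.0 * params.N1[-1]) + occ[:, 2] / (2.0 * params.N2[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        lam[-1] = np.where(surv[-2] > 0, dens / surv[-2], rate_cap)
    lam = np.minimum(lam, rate_cap)
    bounds_scaled = bounds * grid.mu
    return RateTable(
        left_boundaries=bounds_scaled[:-1],
        right_boundaries=bounds_scaled[1:],
        lambdas=lam / grid.mu,
    )
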