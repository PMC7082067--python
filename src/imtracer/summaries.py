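"""Derived quantities from a fitted migration profile: M(t) percentiles,
deep-ancestry fractions and migration-pulse detection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from imtracer.fit import FitResult
from imtracer.im_model import cumulative_migration


@dataclass(frozen=True)
class Pulse:
    """A contiguous run of migration activity.

    ``t_start``/``t_end`` bound the run in generations; ``delta_M`` is its
    increment of the cumulative migration probability and ``t_mean`` the
    delta-M-weighted mean time (log-scale segment midpoints)."""

    t_start: float
    t_end: float
    delta_M: float
    t_mean: float
    segments: tuple[int, ...]


def m_percentiles(result: FitResult, levels) -> np.ndarray:
    """Times (generations) where M(t) first reaches each level.

    Interpolation within a segment is linear on the -log(1-M) scale, which
    is exact for piecewise-constant m.  Levels beyond the maximum attained
    M are reported as NaN (unattained).
    """
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    if np.any((levels <= 0) | (levels >= 1)):
        raise ValueError("percentile levels must be in (0, 1)")
    grid = result.params.grid
    bounds = grid.segment_boundaries_gens
    M = np.minimum(result.M_at_boundaries(), 1.0 - 1e-15)
    neglog = -np.log1p(-M)  # pair-mixing integral, exact
    out = np.full(len(levels), np.nan)
    target = -np.log1p(-levels)
    for k, v in enumerate(target):
        if v > neglog[-1]:
            # may still be attained inside the open-ended final segment
            m_last = result.params.m[-1]
            if m_last > 0:
                from imtracer.im_model import PAIR_MIXING_FACTOR

                out[k] = bounds[-2] + (v - neglog[-2]) / (
                    PAIR_MIXING_FACTOR * m_last)
            continue
        i = int(np.searchsorted(neglog, v, side="left"))
        if i == 0:
            out[k] = bounds[0]
            continue
        lo, hi = neglog[i - 1], neglog[i]
        frac = 0.0 if hi == lo else (v - lo) / (hi - lo)
        out[k] = bounds[i - 1] + frac * (bounds[i] - bounds[i - 1])
    return out


def deep_ancestry_fraction(result: FitResult, t_stars) -> np.ndarray:
    """1 - M(t*) for each requested time (generations): the fraction of
    ancestry from lineages diverged deeper than t*."""
    t = np.atleast_1d(np.asarray(t_stars, dtype=float))
    M = cumulative_migration(result.params, t)
    return 1.0 - M


def detect_pulses(result: FitResult, floor_frac: float = 0.01) -> list[Pulse]:
    """Contiguous runs of segments with appreciable migration.

    A segment is active when its per-segment M increment exceeds
    ``floor_frac`` times the largest per-segment increment; consecutive
    active segments form one pulse.  Conservation holds: the M increments
    of all pulses plus those of the plateaus sum to the final M.
    """
    grid = result.params.grid
    bounds = grid.segment_boundaries_gens
    M = result.M_at_boundaries()
    inc = np.diff(M)
    if np.all(inc <= 0):
        return []
    floor = floor_frac * inc.max()
    active = inc > floor
    pulses: list[Pulse] = []
    i = 0
    n = len(inc)
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and active[j + 1]:
            j += 1
        segs = tuple(range(i, j + 1))
        dM = float(inc[i:j + 1].sum())
        mids = np.array([_log_mid(bounds[k], bounds[k + 1]) for k in segs])
        t_mean = float((mids * inc[i:j + 1]).sum() / dM)
        pulses.append(Pulse(t_start=float(bounds[i]), t_end=float(bounds[j + 1]),
                            delta_M=dM, t_mean=t_mean, segments=segs))
        i = j + 1
    return pulses


def _log_mid(a: float, b: float) -> float:
    if a <= 0:
        return 0.5 * (a + b)
    return float(np.sqrt(a * b))


def plot_profile(result: FitResult, target=None, ax=None,
                 generation_time: float | None = None):
    """Step plot of m(t) and M(t), with an rCCR overlay when the fitted
    rate table is supplied.  Requires matplotlib; returns the axes pair."""
    import matplotlib.pyplot as plt

    from imtracer.fit import masked_migration, rccr

    grid = result.params.grid
    gt = generation_time or grid.generation_time
    bounds = grid.segment_boundaries_gens * gt
    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
    ax_m, ax_M = ax
    m = masked_migration(result)
    ax_m.step(bounds[:-1], m, where="post", color="tab:red")
    ax_m.set_ylabel("m(t) per generation")
    ax_m.set_xscale("log")
    M = result.M_at_boundaries()
    ax_M.plot(bounds, M, color="tab:blue", label="M(t)")
    if target is not None:
        ax_M.step(bounds[:-1], rccr(target), where="post", ls="--",
                  color="gray", label="rCCR")
    ax_M.set_xlabel("years ago")
    ax_M.set_ylabel("cumulative migration probability")
    ax_M.set_xscale("log")
    ax_M.legend()
    return ax
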