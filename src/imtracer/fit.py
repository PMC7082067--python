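"""The two-island IM estimator: fit {N1(t), N2(t), m(t)} to rate tables.

The fit minimizes a regularized chi-square discrepancy between the
coalescence-time distribution of the IM chain and the one implied by the
measured rate tables, summed over the ``n_T`` time segments and the
three start states::

    chi2 = sum_i [ sum_s0 (P_IM(i|s0) - P_MSMC(i|s0))^2 / P_MSMC(i|s0)
                   + beta1 * m_i * dt_i
                   + beta2 * ((N1_i - N2_i)/(N1_i + N2_i))^2 ]

``P(i|s0)`` is by default the probability mass of segment ``i`` (binned
Pearson statistic, including the open-ended final segment whose mass
carries the never-coalesced remainder); point densities at the segment
left boundaries are available as an alternative residual.  ``beta1``
penalizes the total migration integral (the per-segment terms sum to
``beta1 * int m dt``); ``beta2`` shrinks the two population sizes toward
each other.  Terms whose target falls below a configurable floor are
skipped (the cross term is exactly zero in recent segments for cleanly
separated populations).  Optimization is bounded quasi-Newton in
log-parameter space with deterministic starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from imtracer.io_msmc import RateTable, _FLOAT_FMT
from imtracer.im_model import (
    IMParams,
    StartState,
    N_CAP,
    _state_probs_at_boundaries,
    cumulative_migration,
)
from imtracer.msmc_density import msmc_tmrca_density
from imtracer.timegrid import TimeGrid, make_time_grid

_M_EPS = 1e-12  # offset for the log(m + eps) parameterization


@dataclass(frozen=True)
class FitConfig:
    """Settings of the IM fit.

    beta1, beta2
        Regularization weights on migration and on the relative size
        difference (defaults 1e-8 and 1e-6).
    N_max, N_min
        Bounds on the diploid sizes; N_max defaults to 10,000,000.
    M_report_cap
        Reporting cut-off: migration rates after M(t) first exceeds this
        value (default 0.999) are masked in summaries, as the model is
        overspecified once the populations have fully mixed.
    density_floor
        Floor below which target terms are skipped in the residual (the
        cross term is exactly zero in recent segments of cleanly separated
        populations).
    residual
        "mass" (default) compares per-segment tMRCA probability masses
        (binned Pearson chi-square, including the open-ended final
        segment, whose mass carries the not-yet-coalesced remainder);
        "density" compares point densities at the segment left boundaries.
    init_policy
        "from-rccr" seeds the migration profile from the relative
        cross-coalescence rate; "constant" uses ``m_init`` everywhere;
        "multi" (default) optimizes from both deterministic seeds and
        keeps the lower chi-square.
    """

    beta1: float = 1e-8
    beta2: float = 1e-6
    N_max: float = N_CAP
    N_min: float = 10.0
    M_report_cap: float = 0.999
    density_floor: float = 1e-12
    residual: str = "mass"
    init_policy: str = "multi"
    m_init: float = 1e-5
    m_max: float = 1.0
    maxiter: int = 2000
    gtol: float = 1e-10
    ftol: float = 1e-12

    def __post_init__(self) -> None:
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.init_policy not in ("multi", "from-rccr", "constant"):
            raise ValueError(f"unknown init_policy {self.init_policy!r}")
        if self.residual not in ("mass", "density"):
            raise ValueError(f"unknown residual mode {self.residual!r}")


@dataclass
class FitResult:
    """Fitted parameters plus a fit report."""

    params: IMParams
    chi2: float
    chi2_init: float
    n_iterations: int
    converged: bool
    message: str
    config: FitConfig = field(default_factory=FitConfig)

    @property
    def grid(self) -> TimeGrid:
        return self.params.grid

    def M_at_boundaries(self) -> np.ndarray:
        """M(t) at the n_segments + 1 parameter-segment boundaries."""
        return cumulative_migration(
            self.params, self.params.grid.segment_boundaries_gens)

    def to_table(self) -> str:
        """Tab-separated report: time_index, left boundary in generations,
        N1, N2, m, M (M evaluated at the left boundary)."""
        grid = self.params.grid
        lefts = grid.segment_boundaries_gens[:-1]
        M = self.M_at_boundaries()[:-1]
        lines = ["time_index\tleft_time_boundary\tim_N1\tim_N2\tim_m\tM"]
        for i in range(grid.n_segments):
            lines.append("\t".join([
                str(i), _FLOAT_FMT % lefts[i],
                _FLOAT_FMT % self.params.N1[i], _FLOAT_FMT % self.params.N2[i],
                _FLOAT_FMT % self.params.m[i], _FLOAT_FMT % M[i],
            ]))
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_table())


def rccr(target: RateTable) -> np.ndarray:
    """Relative cross-coalescence rate 2*l12/(l11+l22) per segment."""
    if target.n_lambda != 3:
        raise ValueError("rccr requires a three-rate table")
    l11, l12, l22 = target.lambdas.T
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(l11 + l22 > 0, 2.0 * l12 / (l11 + l22), 0.0)
    return out


_START_STATES = (StartState.S11, StartState.S12, StartState.S22)


def _target_densities(target: RateTable, grid: TimeGrid) -> np.ndarray:
    """P_MSMC(t_i|s0) at the segment left boundaries; shape (n_seg, 3)."""
    t = grid.segment_boundaries_gens[:-1]
    return np.column_stack([
        msmc_tmrca_density(target, s0, t, grid.mu) for s0 in _START_STATES
    ])


def _target_masses(target: RateTable, grid: TimeGrid) -> np.ndarray:
    """P(tMRCA in segment i | s0) under the target rates; shape (n_seg, 3).
    The open-ended final segment receives all remaining mass, so columns
    sum to 1."""
    from imtracer.msmc_density import msmc_survival

    t = grid.segment_boundaries_gens[:-1]
    surv = np.column_stack([
        msmc_survival(target, s0, t, grid.mu) for s0 in _START_STATES
    ])
    return surv - np.vstack([surv[1:], np.zeros((1, 3))])


def _im_densities_at_boundaries(params: IMParams) -> np.ndarray:
    """P_IM(t_i|s0) at segment left boundaries; shape (n_seg, 3)."""
    occ = _state_probs_at_boundaries(params)[:, :, :]  # (n_seg, 3 starts, 4)
    c1 = 1.0 / (2.0 * params.N1)
    c2 = 1.0 / (2.0 * params.N2)
    return occ[:, :, 0] * c1[:, None] + occ[:, :, 2] * c2[:, None]


def _im_masses(params: IMParams) -> np.ndarray:
    """P(coalescence in segment i | s0) under the IM chain; shape
    (n_seg, 3); the final segment gets all remaining mass."""
    occ = _state_probs_at_boundaries(params)  # (n_seg, 3 starts, 4)
    surv = occ[:, :, :3].sum(axis=2)
    return surv - np.vstack([surv[1:], np.zeros((1, 3))])


def chi_square(params: IMParams, target: RateTable,
               config: FitConfig = FitConfig(),
               _precomputed_target: np.ndarray | None = None) -> float:
    """Regularized chi-square discrepancy between model and target.

    With ``config.residual == "mass"`` this is the binned Pearson statistic
    over the per-segment coalescence-time masses for the three start
    states; with ``"density"`` it compares point densities at the segment
    left boundaries.  Both add the migration penalty ``beta1 * m_i * dt_i``
    (summing to ``beta1`` times the migration integral) and the size
    penalty ``beta2 * ((N1-N2)/(N1+N2))^2`` per segment.
    """
    grid = params.grid
    if _precomputed_target is None and (
            target.n_segments != grid.n_segments or not np.allclose(
            target.left_boundaries, grid.segment_boundaries_scaled[:-1],
            rtol=1e-9, atol=1e-15)):
        raise ValueError("target table and parameter grid do not match")
    if _precomputed_target is not None:
        p_target = _precomputed_target
        p_im = (_im_masses(params) if config.residual == "mass"
                else _im_densities_at_boundaries(params))
    elif config.residual == "mass":
        p_target = _target_masses(target, grid)
        p_im = _im_masses(params)
    else:
        p_target = _target_densities(target, grid)
        p_im = _im_densities_at_boundaries(params)
    mask = p_target > config.density_floor
    resid = np.where(mask, (p_im - p_target) ** 2 /
                     np.where(mask, p_target, 1.0), 0.0)
    dt = np.diff(grid.segment_boundaries_gens)
    mig_pen = config.beta1 * params.m * dt
    size_pen = config.beta2 * ((params.N1 - params.N2) /
                               (params.N1 + params.N2)) ** 2
    return float(resid.sum() + mig_pen.sum() + size_pen.sum())


def _initial_params(target: RateTable, grid: TimeGrid,
                    config: FitConfig) -> IMParams:
    """Deterministic start: N from inverse within-rates, m either a small
    constant or seeded from the rCCR profile (both deterministic)."""
    lam_gen = target.lambdas * grid.mu
    with np.errstate(divide="ignore"):
        N1 = np.clip(1.0 / (2.0 * lam_gen[:, 0]), config.N_min, config.N_max)
        N2 = np.clip(1.0 / (2.0 * lam_gen[:, 2]), config.N_min, config.N_max)
    N1 = np.where(np.isfinite(N1), N1, config.N_max)
    N2 = np.where(np.isfinite(N2), N2, config.N_max)
    dt = np.diff(grid.segment_boundaries_gens)
    if config.init_policy == "constant":
        m = np.full(grid.n_segments, config.m_init)
    else:
        # M(t) is numerically close to the rCCR; invert the pair-mixing
        # relation M = 1 - exp(-2 int m) on the rCCR profile for a starting
        # migration rate per segment.
        r = np.clip(rccr(target), 0.0, 1.0 - 1e-6)
        r = np.maximum.accumulate(r)  # enforce monotonicity of the seed
        neglog = -np.log1p(-r)
        inc = np.diff(np.concatenate([[0.0], neglog])) / 2.0
        m = np.clip(inc / dt, config.m_init, config.m_max)
    return IMParams(grid=grid, N1=N1, N2=N2, m=m)


def _pack(params: IMParams) -> np.ndarray:
    return np.concatenate([
        np.log(params.N1), np.log(params.N2), np.log(params.m + _M_EPS)])


def _unpack(x: np.ndarray, grid: TimeGrid, config: FitConfig) -> IMParams:
    n = grid.n_segments
    N1 = np.clip(np.exp(x[:n]), config.N_min, config.N_max)
    N2 = np.clip(np.exp(x[n:2 * n]), config.N_min, config.N_max)
    m = np.clip(np.exp(x[2 * n:]) - _M_EPS, 0.0, config.m_max)
    return IMParams(grid=grid, N1=N1, N2=N2, m=m)


def fit_im(target: RateTable, config: FitConfig = FitConfig(),
           grid: TimeGrid | None = None) -> FitResult:
    """Fit the two-island IM model to a three-rate table.

    The fit is deterministic given (target, config): fixed initialization,
    bounded L-BFGS-B in log-parameter space.  The returned chi-square never
    exceeds the chi-square at initialization; population sizes respect
    ``config.N_max`` and migration rates are nonnegative.  Non-convergence
    is reported via ``converged``/``message`` with best-so-far parameters.
    """
    if target.n_lambda != 3:
        raise ValueError("fit_im requires a three-rate (combined) table")
    if grid is None:
        grid = _grid_from_table(target)
    policies = (("from-rccr", "constant") if config.init_policy == "multi"
                else (config.init_policy,))
    p_target = (_target_masses(target, grid) if config.residual == "mass"
                else _target_densities(target, grid))
    n = grid.n_segments
    bounds = ([(np.log(config.N_min), np.log(config.N_max))] * (2 * n) +
              [(np.log(_M_EPS), np.log(config.m_max + _M_EPS))] * n)
    best = None
    for policy in policies:
        cfg_seed = replace(config, init_policy=policy)
        x0 = _pack(_initial_params(target, grid, cfg_seed))
        chi2_init = chi_square(_unpack(x0, grid, config), target, config,
                               _precomputed_target=p_target)
        # normalize so tolerances act on the relative scale; raw
        # chi-squares of well-matched targets are O(1e-6) and would drown
        # in float rounding otherwise
        scale = max(chi2_init, np.finfo(float).tiny)

        def objective(x: np.ndarray) -> float:
            return chi_square(_unpack(x, grid, config), target, config,
                              _precomputed_target=p_target) / scale

        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": config.maxiter,
                                "ftol": config.ftol, "gtol": config.gtol,
                                "maxfun": 10 ** 6, "eps": 1e-5})
        fun = float(res.fun) * scale
        x_best = res.x if fun <= chi2_init else x0
        result = FitResult(
            params=_unpack(x_best, grid, config),
            chi2=min(fun, chi2_init),
            chi2_init=chi2_init,
            n_iterations=int(res.nit),
            converged=bool(res.success),
            message=str(res.message),
            config=config,
        )
        if best is None or result.chi2 < best.chi2:
            best = result
    return best


def _grid_from_table(target: RateTable,
                     mu: float = None) -> TimeGrid:
    """Reconstruct a TimeGrid whose parameter segments are the table rows
    (identity pattern), for fitting tables of unknown provenance."""
    from imtracer.timegrid import DEFAULT_MU, TimePattern

    mu = DEFAULT_MU if mu is None else mu
    pattern = TimePattern(((target.n_segments, 1),))
    return TimeGrid(pattern=pattern, boundaries_scaled=target.boundaries(),
                    mu=mu)


def load_fit_result(path: str | Path, mu: float = None,
                    generation_time: float = None) -> FitResult:
    """Read a fit report table back into a FitResult (parameters only;
    the chi-square fields are not stored in the report and read as NaN)."""
    from imtracer.timegrid import (
        DEFAULT_GENERATION_TIME, DEFAULT_MU, TimePattern,
    )

    mu = DEFAULT_MU if mu is None else mu
    generation_time = (DEFAULT_GENERATION_TIME if generation_time is None
                       else generation_time)
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    rows = [l.split("\t") for l in lines[1:]]
    lefts = np.array([float(r[1]) for r in rows])
    N1 = np.array([float(r[2]) for r in rows])
    N2 = np.array([float(r[3]) for r in rows])
    m = np.array([float(r[4]) for r in rows])
    # reconstruct an identity-pattern grid; the open-ended last segment's
    # stored cap extends the final finite span
    last_span = lefts[-1] - lefts[-2] if len(lefts) > 1 else 1.0
    bounds_gens = np.append(lefts, lefts[-1] + 2 * last_span)
    grid = TimeGrid(pattern=TimePattern(((len(rows), 1),)),
                    boundaries_scaled=bounds_gens * mu, mu=mu,
                    generation_time=generation_time)
    params = IMParams(grid=grid, N1=N1, N2=N2, m=m)
    return FitResult(params=params, chi2=float("nan"), chi2_init=float("nan"),
                     n_iterations=0, converged=True, message="loaded")


def masked_migration(result: FitResult) -> np.ndarray:
    """Migration rates with every segment at or beyond the first time
    M(t) >= M_report_cap masked as NaN (estimates there are arbitrary:
    lineages have fully mixed)."""
    M = result.M_at_boundaries()[:-1]
    m = result.params.m.astype(float).copy()
    cap = result.config.M_report_cap
    beyond = np.nonzero(M >= cap)[0]
    if len(beyond):
        m[beyond[0]:] = np.nan
    return m
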