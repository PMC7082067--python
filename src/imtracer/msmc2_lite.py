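"""Pairwise SMC' coalescence-rate estimation (the MSMC2 core, lite).

The hidden state at each called site is the discretized tMRCA interval of
one haplotype pair.  Emissions give the heterozygosity probability as a
function of the interval's representative time and the mutation rate;
transitions between adjacent sites follow the SMC' recombination process
with piecewise-constant coalescence rates: a recombination event at
uniform height on the branch detaches a lineage which re-coalesces either
below the old tMRCA (with the other branch, giving a younger tMRCA; or
back onto its own branch, restoring it) or above it.  All segment
integrals of this kernel are closed-form for step-function rates.

Runs of homozygous called sites between segregating-site records are
handled exactly by diagonalizing the (transition x hom-emission) matrix
once per iteration and raising its eigenvalues to the run length, so a
chromosome is processed in one vectorized forward/backward sweep over
records, batched across all selected haplotype pairs (composite
likelihood: posterior statistics are summed over pairs).

Rates are re-estimated each iteration by matching the piecewise-constant
coalescent prior to the aggregated posterior tMRCA distribution (the
stationary law of the SMC' kernel equals that prior); every update is
accepted only if it does not decrease the composite log-likelihood, with
a geometric line search toward the proposal otherwise, so the
log-likelihood trace is nondecreasing by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from imtracer.io_msmc import MultihetsepRecord, RateTable
from imtracer.timegrid import TimeGrid, make_time_grid

_RANGE_PAIR = re.compile(r"^(\d+)-(\d+)$")


@dataclass(frozen=True)
class PairSelection:
    """An explicit list of haplotype index pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("empty pair selection")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a},{b}) not allowed")
            if a < 0 or b < 0:
                raise ValueError("negative haplotype index")

    def validate(self, n_haplotypes: int) -> None:
        hi = max(max(p) for p in self.pairs)
        if hi >= n_haplotypes:
            raise ValueError(
                f"pair index {hi} out of range for {n_haplotypes} haplotypes")

    def __len__(self) -> int:
        return len(self.pairs)


def expand_pair_spec(spec_text: str) -> PairSelection:
    """Expand an ``-I``-style pair specification.

    A comma list of indices (``"0,1,2,3"``) denotes all k(k-1)/2 pairs
    among them (within-population form); a comma list of dash-pairs
    (``"0-4,0-5,..."``) lists cross pairs verbatim.  Mixing the two forms
    is an error.
    """
    tokens = [t.strip() for t in spec_text.strip().split(",") if t.strip()]
    if not tokens:
        raise ValueError("empty pair specification")
    dash = [_RANGE_PAIR.match(t) for t in tokens]
    if all(m is not None for m in dash):
        pairs = tuple((int(m.group(1)), int(m.group(2))) for m in dash)
        return PairSelection(pairs)
    if any(m is not None for m in dash):
        raise ValueError("cannot mix index and dash-pair forms")
    try:
        idx = [int(t) for t in tokens]
    except ValueError:
        raise ValueError(f"malformed pair specification {spec_text!r}") from None
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate haplotype index")
    if len(idx) < 2:
        raise ValueError("need at least two haplotypes")
    pairs = tuple((idx[i], idx[j]) for i in range(len(idx))
                  for j in range(i + 1, len(idx)))
    return PairSelection(pairs)


@dataclass(frozen=True)
class HMMConfig:
    """Settings of the SMC' HMM and its EM loop."""

    grid: TimeGrid = field(default_factory=make_time_grid)
    mu: float = 1.25e-8
    rho: float = 1e-8
    max_iterations: int = 25
    tolerance: float = 1e-4  # absolute log-likelihood improvement
    estimate_rho: bool = False
    min_rate: float = 1e-12  # per-generation floor for estimated hazards

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("mu and rho must be positive")
        if self.max_iterations < 1:
            raise ValueError("need at least one EM iteration")


# ---------------------------------------------------------------------------
# SMC' transition kernel for piecewise-constant rates
# ---------------------------------------------------------------------------


def _interval_times(grid: TimeGrid, lam0: float) -> tuple[np.ndarray, np.ndarray]:
    """Atomic boundaries (generations) and representative times: the
    conditional mean tMRCA within each interval under a constant-rate
    exponential prior with hazard ``lam0`` (fixed across EM iterations)."""
    b = grid.boundaries_gens
    lo, hi = b[:-1].copy(), b[1:].copy()
    t_rep = np.empty(grid.n_atomic)
    for i in range(grid.n_atomic):
        a = lo[i]
        if i == grid.n_atomic - 1:
            t_rep[i] = a + 1.0 / lam0
        else:
            c = hi[i]
            ea, ec = np.exp(-lam0 * a), np.exp(-lam0 * c)
            t_rep[i] = ((a + 1 / lam0) * ea - (c + 1 / lam0) * ec) / (ea - ec)
    return b[:-1], t_rep


def smc_prime_transition(boundaries: np.ndarray, t_rep: np.ndarray,
                         lam_atomic: np.ndarray, rho: float) -> np.ndarray:
    """Per-bp transition matrix of the SMC' process.

    ``boundaries`` are the ``n`` left boundaries of the atomic tMRCA
    intervals (generations; the last interval is open-ended), ``t_rep``
    their representative times, ``lam_atomic`` the per-generation
    coalescence rate in each interval, ``rho`` the per-bp per-generation
    recombination rate.  Row i is the distribution of the next site's
    interval given the current tMRCA is ``t_rep[i]``.
    """
    n = len(boundaries)
    lefts = boundaries
    # cumulative hazard at interval left boundaries
    widths = np.diff(lefts)
    cum = np.concatenate([[0.0], np.cumsum(lam_atomic[:-1] * widths)])

    def Lam(t: float) -> float:
        i = min(int(np.searchsorted(lefts, t, side="right")) - 1, n - 1)
        return cum[i] + lam_atomic[i] * (t - lefts[i])

    T = np.zeros((n, n))
    for i in range(n):
        s = t_rep[i]
        p_rec = -np.expm1(-2.0 * s * rho)
        K = np.zeros(n)
        Ls = Lam(s)
        # u-integration: \int_0^s exp(2 Lam(u)) du, piecewise over segments
        # clipped to [0, s]; collect per-u-segment integrals.
        u_edges = np.concatenate([lefts[lefts < s], [s]])
        u_seg = np.clip(np.searchsorted(lefts, u_edges[:-1], side="right") - 1,
                        0, n - 1)
        exp2 = np.exp(2.0 * np.array([Lam(u) for u in u_edges]))
        Ints = np.empty(len(u_edges) - 1)  # \int exp(2 Lam(u)) du per piece
        for k in range(len(u_edges) - 1):
            lam_k = lam_atomic[u_seg[k]]
            if lam_k > 0:
                Ints[k] = (exp2[k + 1] - exp2[k]) / (2.0 * lam_k)
            else:
                Ints[k] = (u_edges[k + 1] - u_edges[k]) * exp2[k]
        G = Ints.sum()
        W = np.exp(-2.0 * Ls) * G / s  # mean of exp(-2 Lam(u,s)) over u

        # (a) re-coalescence with the other branch below s, new tMRCA t < s
        for j in range(n):
            t1, t2 = lefts[j], (lefts[j + 1] if j + 1 < n else np.inf)
            t2 = min(t2, s)
            if t1 >= s or t2 <= t1:
                continue
            e1, e2 = np.exp(-2.0 * Lam(t1)), np.exp(-2.0 * Lam(t2))
            acc = 0.0
            for k in range(len(u_edges) - 1):
                ua, ub = u_edges[k], u_edges[k + 1]
                if ub <= t1:  # t-interval fully above this u-piece
                    acc += 0.5 * (e1 - e2) * Ints[k]
                elif ua >= t2:
                    continue
                else:  # u inside the t-interval: t runs from u to t2
                    # split u-piece at t1 if needed
                    va = max(ua, t1)
                    lam_k = lam_atomic[u_seg[k]]
                    if va > ua:  # lower part: t-interval above u
                        sub = ((np.exp(2 * Lam(va)) - np.exp(2 * Lam(ua)))
                               / (2 * lam_k) if lam_k > 0
                               else (va - ua) * np.exp(2 * Lam(ua)))
                        acc += 0.5 * (e1 - e2) * sub
                    vb = min(ub, t2)
                    if vb > va:
                        sub = ((np.exp(2 * Lam(vb)) - np.exp(2 * Lam(va)))
                               / (2 * lam_k) if lam_k > 0
                               else (vb - va) * np.exp(2 * Lam(va)))
                        acc += 0.5 * ((vb - va) - e2 * sub)
            K[j] += acc / s
        # (b) re-coalescence back onto the same branch: tMRCA restored
        K[i] += 0.5 * (1.0 - W)
        # (c) survival to s, then coalescence above s
        for j in range(i, n):
            t1 = max(lefts[j], s)
            t2 = lefts[j + 1] if j + 1 < n else np.inf
            if t2 <= t1:
                continue
            d1 = np.exp(-(Lam(t1) - Ls))
            d2 = np.exp(-(Lam(t2) - Ls)) if np.isfinite(t2) else 0.0
            K[j] += W * (d1 - d2)
        T[i] = p_rec * K
        T[i, i] += 1.0 - p_rec
    return T


# ---------------------------------------------------------------------------
# Observation preprocessing
# ---------------------------------------------------------------------------


def _pair_observations(records: list[MultihetsepRecord],
                       pairs: PairSelection) -> tuple[np.ndarray, np.ndarray]:
    """Distances (called sites since previous record) and per-pair
    heterozygosity indicators in [0, 1] (fractional when phasing is
    ambiguous); shapes (R,), (R, P)."""
    if not records:
        raise ValueError("empty multihetsep input")
    pairs.validate(records[0].n_haplotypes)
    d = np.array([r.called_since_last for r in records], dtype=np.int64)
    het = np.empty((len(records), len(pairs)))
    for r, rec in enumerate(records):
        phasings = rec.alleles.split(",")
        for p, (a, b) in enumerate(pairs.pairs):
            het[r, p] = float(np.mean([ph[a] != ph[b] for ph in phasings]))
    return d, het


# ---------------------------------------------------------------------------
# Forward/backward over records with eigenvalue-powered hom runs
# ---------------------------------------------------------------------------


class _HMMachinery:
    def __init__(self, T: np.ndarray, p_het: np.ndarray, prior: np.ndarray):
        self.T = T
        self.p_het = p_het
        self.p_hom = 1.0 - p_het
        self.prior = prior
        M = T * self.p_hom[None, :]  # transition then emit hom
        w, V = np.linalg.eig(M)
        self.w = w
        self.V = V
        self.Vinv = np.linalg.inv(V)

    def _emission(self, het_frac: np.ndarray) -> np.ndarray:
        # rows: pairs; columns: states
        return (het_frac[:, None] * self.p_het[None, :]
                + (1.0 - het_frac[:, None]) * self.p_hom[None, :])

    def forward(self, d: np.ndarray, het: np.ndarray,
                keep_alphas: bool = False):
        R, P = het.shape
        n = len(self.prior)
        alpha = np.tile(self.prior, (P, 1))
        loglik = np.zeros(P)
        alphas = np.empty((R, P, n)) if keep_alphas else None
        V, Vinv, w, T = self.V, self.Vinv, self.w, self.T
        for r in range(R):
            k = d[r] - 1
            if k > 0:
                a = np.real(((alpha @ V) * w[None, :] ** k) @ Vinv)
                np.maximum(a, 0.0, out=a)
            else:
                a = alpha
            a = (a @ T) * self._emission(het[r])
            norm = a.sum(axis=1)
            norm[norm <= 0] = np.finfo(float).tiny
            alpha = a / norm[:, None]
            loglik += np.log(norm)
            if keep_alphas:
                alphas[r] = alpha
        return loglik, alphas

    def backward_loglik(self, d: np.ndarray, het: np.ndarray) -> np.ndarray:
        """Total per-pair log-likelihood via the backward recursion (must
        agree with :meth:`forward` to numerical precision)."""
        R, P = het.shape
        n = len(self.prior)
        beta = np.ones((P, n))
        loglik = np.zeros(P)
        V, Vinv, w, T = self.V, self.Vinv, self.w, self.T
        for r in range(R - 1, -1, -1):
            x = (beta * self._emission(het[r])) @ T.T
            k = d[r] - 1
            if k > 0:
                x = np.real(((x @ Vinv.T) * w[None, :] ** k) @ V.T)
                np.maximum(x, 0.0, out=x)
            norm = x.sum(axis=1)
            norm[norm <= 0] = np.finfo(float).tiny
            beta = x / norm[:, None]
            loglik += np.log(norm)
        return loglik + np.log(beta @ self.prior)

    def posterior_sums(self, d: np.ndarray, het: np.ndarray):
        """Posterior state occupancies summed over records and pairs, each
        record weighted by the number of called sites it accounts for (so
        the aggregate approximates a site-uniform sample of the posterior
        local tMRCA: records alone oversample regions that segregate in
        any haplotype), plus the per-pair log-likelihoods."""
        loglik, alphas = self.forward(d, het, keep_alphas=True)
        R, P, n = alphas.shape
        beta = np.ones((P, n))
        gamma_sum = np.zeros(n)
        V, Vinv, w, T = self.V, self.Vinv, self.w, self.T
        for r in range(R - 1, -1, -1):
            g = alphas[r] * beta
            gs = g.sum(axis=1)
            gs[gs <= 0] = np.finfo(float).tiny
            gamma_sum += float(d[r]) * (g / gs[:, None]).sum(axis=0)
            # propagate beta through record r for the next (earlier) record
            x = (beta * self._emission(het[r])) @ T.T
            k = d[r] - 1
            if k > 0:
                x = np.real(((x @ Vinv.T) * w[None, :] ** k) @ V.T)
                np.maximum(x, 0.0, out=x)
            norm = x.sum(axis=1)
            norm[norm <= 0] = np.finfo(float).tiny
            beta = x / norm[:, None]
        return gamma_sum, loglik


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def _prior_marginal(boundaries: np.ndarray, lam_atomic: np.ndarray) -> np.ndarray:
    """P(tMRCA in atomic interval i) under the piecewise-constant prior."""
    widths = np.diff(boundaries)
    cum = np.concatenate([[0.0], np.cumsum(lam_atomic[:-1] * widths)])
    surv_left = np.exp(-cum)  # survival at each interval's left boundary
    surv_next = np.append(surv_left[1:], 0.0)  # S(inf) = 0 for the open tail
    return np.maximum(surv_left - surv_next, 1e-300)


def _hazard_from_marginal(grid: TimeGrid, q_atomic: np.ndarray,
                          min_rate: float) -> np.ndarray:
    """Piecewise-constant hazard per parameter segment whose prior marginal
    matches the given atomic-interval occupancy distribution."""
    seg_of = grid.segment_index_of_atomic
    n_seg = grid.n_segments
    q_seg = np.zeros(n_seg)
    np.add.at(q_seg, seg_of, q_atomic)
    q_seg = q_seg / q_seg.sum()
    surv = np.concatenate([[1.0], 1.0 - np.cumsum(q_seg)])
    surv = np.maximum(surv, 1e-300)
    dt = np.diff(grid.segment_boundaries_gens)
    lam_seg = np.empty(n_seg)
    for i in range(n_seg - 1):
        lam_seg[i] = max(-np.log(surv[i + 1] / surv[i]) / dt[i], min_rate)
    lam_seg[-1] = lam_seg[-2]  # open interval: continue the last hazard
    return lam_seg


def _atomic_rates(grid: TimeGrid, lam_seg: np.ndarray) -> np.ndarray:
    return lam_seg[grid.segment_index_of_atomic]


def estimate_rates(
    chroms: list[list[MultihetsepRecord]],
    pairs: PairSelection,
    config: HMMConfig,
) -> tuple[RateTable, list[float]]:
    """EM estimation of a single piecewise-constant coalescence rate.

    ``chroms`` is a list of per-chromosome multihetsep record lists; the
    composite likelihood multiplies over all selected pairs and
    chromosomes.  Returns a mutation-scaled single-rate table on the
    parameter segments of ``config.grid`` and the per-iteration composite
    log-likelihood trace (nondecreasing up to the stopping tolerance).

    Raises ``ValueError`` on empty input or input without informative
    (heterozygous) sites, whose likelihood would be maximized at the rate
    boundary.
    """
    grid = config.grid
    obs = [_pair_observations(records, pairs) for records in chroms
           if records]
    if not obs:
        raise ValueError("no multihetsep records supplied")
    total_called = sum(d.sum() for d, _ in obs) * len(pairs)
    total_het = sum(h.sum() for _, h in obs)
    if total_het == 0:
        raise ValueError("no heterozygous sites for any selected pair; "
                         "rates are unidentifiable")
    p_het = total_het / total_called
    lam0 = 2.0 * config.mu * (1.0 - p_het) / p_het
    boundaries, t_rep = _interval_times(grid, lam0)
    p_het_state = -np.expm1(-2.0 * config.mu * t_rep)

    lam_seg = np.full(grid.n_segments, lam0)
    rho = config.rho

    def total_loglik_and_posterior(lam_s, with_posterior, rho_val=None):
        lam_at = _atomic_rates(grid, lam_s)
        T = smc_prime_transition(boundaries, t_rep, lam_at,
                                 config.rho if rho_val is None else rho_val)
        prior = _prior_marginal(boundaries, lam_at)
        machine = _HMMachinery(T, p_het_state, prior)
        ll = 0.0
        gamma = np.zeros(grid.n_atomic)
        for d, het in obs:
            if with_posterior:
                g, l = machine.posterior_sums(d, het)
                gamma += g
            else:
                l, _ = machine.forward(d, het)
            ll += l.sum()
        return ll, gamma

    trace: list[float] = []
    current_ll, gamma = total_loglik_and_posterior(lam_seg, True, rho)
    trace.append(current_ll)
    for _ in range(config.max_iterations):
        proposal = _hazard_from_marginal(grid, gamma, config.min_rate)
        accepted = False
        for step in (1.0, 0.5, 0.25, 0.1, 0.03):
            cand = np.exp((1 - step) * np.log(lam_seg)
                          + step * np.log(proposal))
            ll, g = total_loglik_and_posterior(cand, True, rho)
            if ll >= current_ll - 1e-9:
                lam_seg, gamma = cand, g
                improved = ll - current_ll
                current_ll = ll
                accepted = True
                break
        if not accepted:
            break
        if config.estimate_rho:
            # coarse single-scalar update: hill-climb on a log factor
            for factor in (0.7, 1.4):
                ll_r, g_r = total_loglik_and_posterior(lam_seg, True,
                                                       rho * factor)
                if ll_r > current_ll:
                    rho *= factor
                    current_ll, gamma = ll_r, g_r
                    break
        trace.append(current_ll)
        if improved < config.tolerance:
            break

    seg_scaled = grid.segment_boundaries_scaled
    table = RateTable(left_boundaries=seg_scaled[:-1],
                      right_boundaries=seg_scaled[1:],
                      lambdas=lam_seg / grid.mu)
    return table, trace


# ---------------------------------------------------------------------------
# Block bootstrap
# ---------------------------------------------------------------------------


def block_bootstrap(
    chroms: list[list[MultihetsepRecord]],
    block_length_bp: float,
    n_blocks: int,
    n_reps: int,
    seed: int,
) -> list[list[list[MultihetsepRecord]]]:
    """Resample contiguous genomic blocks with replacement.

    Each replicate consists of ``n_blocks`` blocks of ``block_length_bp``
    drawn with replacement from the pool of blocks across all input
    chromosomes; every block becomes its own pseudo-chromosome so that no
    record is ever split and no artificial junctions are created.
    Deterministic given the seed.
    """
    if block_length_bp <= 0:
        raise ValueError("block length must be positive")
    import dataclasses

    pool: list[list[MultihetsepRecord]] = []
    for records in chroms:
        if not records:
            continue
        length = max(r.pos for r in records)
        n = int(np.ceil(length / block_length_bp))
        blocks: list[list[MultihetsepRecord]] = [[] for _ in range(n)]
        for rec in records:
            blocks[min(int((rec.pos - 1) // block_length_bp), n - 1)].append(rec)
        pool.extend(b for b in blocks if b)
    if not pool:
        raise ValueError("no blocks: input empty or block longer than data")
    if block_length_bp > max(max(r.pos for r in rec) for rec in chroms if rec):
        raise ValueError("block longer than the longest chromosome")
    rng = np.random.RandomState(seed)
    reps = []
    for rep in range(n_reps):
        idx = rng.randint(0, len(pool), size=n_blocks)
        rep_chroms = []
        for k, i in enumerate(idx):
            block = pool[i]
            start = block[0].pos
            recs = []
            for j, rec in enumerate(block):
                new_pos = rec.pos - start + 1
                csl = rec.called_since_last if j > 0 else min(
                    rec.called_since_last, new_pos)
                recs.append(dataclasses.replace(
                    rec, chrom=f"rep{rep}_block{k}", pos=new_pos,
                    called_since_last=csl))
            rep_chroms.append(recs)
        reps.append(rep_chroms)
    return reps
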