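"""Demographic scenario engine: exact pairwise coalescence rates and
sequence simulation.

A :class:`ScenarioSpec` describes a multi-deme demography with
piecewise-constant diploid sizes and backward-in-time events: splits
(deme merges), pulse admixture (a fraction of lineages relabeled), and
windows of continuous symmetric migration.  Two consumers share it:

* :func:`exact_coal_rates` builds the lineage-location Markov chain for a
  pair of lineages (states = unordered deme assignments plus "coalesced")
  and computes noise-free within/cross coalescence rates on a time grid by
  chaining matrix exponentials between events and stochastic relabeling
  matrices at events;
* :func:`simulate_sequences` runs the same demography through msprime and
  exports phased haplotypes to multihetsep records.

The predefined scenarios reproduce standard two-population test cases:
a clean split, a split with a post-split migration window, archaic
admixture from a deeply diverged unsampled deme (with or without a
bottleneck), and a zigzag size history for size-recovery checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.linalg import expm

from imtracer.io_msmc import MultihetsepRecord, RateTable
from imtracer.timegrid import (
    DEFAULT_GENERATION_TIME,
    DEFAULT_MU,
    TimeGrid,
)

DEFAULT_RHO = 1e-8


@dataclass(frozen=True)
class SizeChange:
    time: float  # generations, backward from present
    deme: str
    size: float


@dataclass(frozen=True)
class Split:
    """Backward in time, all lineages of ``derived`` move to ``ancestral``."""

    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class Pulse:
    """Backward in time, each lineage in ``deme`` moves to ``source`` with
    probability ``fraction`` (forward: ``deme`` received an admixture pulse
    of proportion ``fraction`` from ``source``)."""

    time: float
    deme: str
    source: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("pulse fraction must be in [0, 1]")


@dataclass(frozen=True)
class MigrationWindow:
    """Continuous symmetric migration between two demes at per-lineage
    rate ``rate`` per generation over [start, end) (backward times)."""

    start: float
    end: float
    deme_a: str
    deme_b: str
    rate: float

    def __post_init__(self) -> None:
        if self.end <= self.start or self.rate < 0:
            raise ValueError("invalid migration window")

    @property
    def total_per_direction(self) -> float:
        return self.rate * (self.end - self.start)


@dataclass(frozen=True)
class ScenarioSpec:
    """A demography plus sampling and sequence parameters.

    ``demes`` maps deme name to its diploid size at time 0; sizes further
    back are modified by :class:`SizeChange` events.  ``samples`` maps
    deme name to the number of sampled haplotypes (even numbers: phased
    diploids).  All times are in generations.
    """

    name: str
    demes: tuple[tuple[str, float], ...]
    samples: tuple[tuple[str, int], ...]
    events: tuple = ()
    migrations: tuple[MigrationWindow, ...] = ()
    mu: float = DEFAULT_MU
    rho: float = DEFAULT_RHO
    chrom_length: float = 100e6
    n_chrom: int = 22
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        names = [d for d, _ in self.demes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate deme names")
        if any(size <= 0 for _, size in self.demes):
            raise ValueError("deme sizes must be positive")
        for ev in self.events:
            for attr in ("deme", "derived", "ancestral", "source"):
                ref = getattr(ev, attr, None)
                if ref is not None and ref not in names:
                    raise ValueError(f"event references unknown deme {ref!r}")
        if list(self.events) != sorted(self.events, key=lambda e: e.time):
            raise ValueError("events must be time-ordered")

    @property
    def deme_names(self) -> list[str]:
        return [d for d, _ in self.demes]

    @property
    def sampled_demes(self) -> list[str]:
        return [d for d, n in self.samples if n > 0]

    # -- plain key-value text serialization -------------------------------

    def to_text(self) -> str:
        lines = [f"name {self.name}"]
        for d, size in self.demes:
            lines.append(f"deme {d} {size!r}")
        for d, n in self.samples:
            lines.append(f"sample {d} {n}")
        for ev in self.events:
            if isinstance(ev, SizeChange):
                lines.append(f"size_change {ev.time!r} {ev.deme} {ev.size!r}")
            elif isinstance(ev, Split):
                lines.append(f"split {ev.time!r} {ev.derived} {ev.ancestral}")
            elif isinstance(ev, Pulse):
                lines.append(
                    f"pulse {ev.time!r} {ev.deme} {ev.source} {ev.fraction!r}")
        for mw in self.migrations:
            lines.append(
                f"migration {mw.start!r} {mw.end!r} {mw.deme_a} "
                f"{mw.deme_b} {mw.rate!r}")
        lines.append(f"mu {self.mu!r}")
        lines.append(f"rho {self.rho!r}")
        lines.append(f"chrom_length {self.chrom_length!r}")
        lines.append(f"n_chrom {self.n_chrom}")
        lines.append(f"generation_time {self.generation_time!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ScenarioSpec":
        name = "scenario"
        demes, samples, events, migrations = [], [], [], []
        scalars: dict[str, float] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, *rest = line.split()
            try:
                if key == "name":
                    name = rest[0]
                elif key == "deme":
                    demes.append((rest[0], float(rest[1])))
                elif key == "sample":
                    samples.append((rest[0], int(rest[1])))
                elif key == "size_change":
                    events.append(SizeChange(float(rest[0]), rest[1],
                                             float(rest[2])))
                elif key == "split":
                    events.append(Split(float(rest[0]), rest[1], rest[2]))
                elif key == "pulse":
                    events.append(Pulse(float(rest[0]), rest[1], rest[2],
                                        float(rest[3])))
                elif key == "migration":
                    migrations.append(MigrationWindow(
                        float(rest[0]), float(rest[1]), rest[2], rest[3],
                        float(rest[4])))
                elif key in ("mu", "rho", "chrom_length", "generation_time"):
                    scalars[key] = float(rest[0])
                elif key == "n_chrom":
                    scalars[key] = int(rest[0])
                else:
                    raise ValueError(f"unknown key {key!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"scenario line {lineno}: {exc}") from None
        events.sort(key=lambda e: e.time)
        return cls(name=name, demes=tuple(demes), samples=tuple(samples),
                   events=tuple(events), migrations=tuple(migrations),
                   **scalars)

    def replace(self, **kwargs) -> "ScenarioSpec":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Exact pairwise coalescence rates via the lineage-location Markov chain
# ---------------------------------------------------------------------------


class _PairChain:
    """State space of an unordered lineage pair over demes, plus C."""

    def __init__(self, deme_names: list[str]):
        self.demes = deme_names
        self.pairs = [(i, j) for i in range(len(deme_names))
                      for j in range(i, len(deme_names))]
        self.index = {p: k for k, p in enumerate(self.pairs)}
        self.n = len(self.pairs) + 1  # + coalesced
        self.c_idx = self.n - 1

    def start_vector(self, deme_a: str, deme_b: str) -> np.ndarray:
        i, j = self.demes.index(deme_a), self.demes.index(deme_b)
        v = np.zeros(self.n)
        v[self.index[(min(i, j), max(i, j))]] = 1.0
        return v

    def generator(self, sizes: dict[str, float],
                  mig: np.ndarray) -> np.ndarray:
        """Continuous generator given current sizes and the per-lineage
        migration rate matrix ``mig`` (mig[a, c] = rate a -> c)."""
        D = len(self.demes)
        Q = np.zeros((self.n, self.n))
        for (a, b), k in self.index.items():
            for c in range(D):
                if c != a and mig[a, c] > 0:
                    dest = (min(c, b), max(c, b))
                    rate = mig[a, c] * (2.0 if a == b else 1.0)
                    Q[k, self.index[dest]] += rate
                if c != b and b != a and mig[b, c] > 0:
                    dest = (min(a, c), max(a, c))
                    Q[k, self.index[dest]] += mig[b, c]
            if a == b:
                Q[k, self.c_idx] += 1.0 / (2.0 * sizes[self.demes[a]])
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q

    def lift(self, E: np.ndarray) -> np.ndarray:
        """Lift a per-lineage stochastic matrix E (deme relabeling applied
        independently to each lineage) to the pair state space."""
        P = np.zeros((self.n, self.n))
        P[self.c_idx, self.c_idx] = 1.0
        D = len(self.demes)
        for (a, b), k in self.index.items():
            for c in range(D):
                for d in range(D):
                    dest = (min(c, d), max(c, d))
                    P[k, self.index[dest]] += E[a, c] * E[b, d]
        return P


def _event_matrix(spec: ScenarioSpec, ev) -> np.ndarray:
    names = spec.deme_names
    D = len(names)
    E = np.eye(D)
    if isinstance(ev, Split):
        i, j = names.index(ev.derived), names.index(ev.ancestral)
        E[i, i] = 0.0
        E[i, j] = 1.0
    elif isinstance(ev, Pulse):
        i, j = names.index(ev.deme), names.index(ev.source)
        E[i, i] = 1.0 - ev.fraction
        E[i, j] += ev.fraction
    return E


def _migration_matrix(spec: ScenarioSpec, t: float) -> np.ndarray:
    names = spec.deme_names
    M = np.zeros((len(names), len(names)))
    for mw in spec.migrations:
        if mw.start <= t < mw.end:
            i, j = names.index(mw.deme_a), names.index(mw.deme_b)
            M[i, j] += mw.rate
            M[j, i] += mw.rate
    return M


def exact_coal_rates(spec: ScenarioSpec, grid: TimeGrid,
                     tail_factor: float = 2.0) -> RateTable:
    """Noise-free within/cross coalescence rates of a scenario on a grid.

    Returns a mutation-scaled three-rate table on the parameter-segment
    boundaries of ``grid`` with columns (within pop 1, cross, within pop 2)
    for the first two sampled demes.  Rates are segment-averaged hazards
    ``-ln(S(t_{i+1})/S(t_i)) / dt`` — what an ideal rate estimator would
    report for a piecewise-constant model.  The open-ended final segment is
    averaged over ``tail_factor`` times the span of the last finite segment.
    """
    sampled = spec.sampled_demes
    if len(sampled) == 1:
        sampled = [sampled[0], sampled[0]]
    if len(sampled) != 2:
        raise ValueError("exact_coal_rates needs one or two sampled demes")
    chain = _PairChain(spec.deme_names)
    starts = np.stack([
        chain.start_vector(sampled[0], sampled[0]),
        chain.start_vector(sampled[0], sampled[1]),
        chain.start_vector(sampled[1], sampled[1]),
    ])

    seg_bounds = grid.segment_boundaries_gens
    last_span = seg_bounds[-1] - seg_bounds[-2]
    tail_end = seg_bounds[-2] + tail_factor * last_span
    eval_times = np.concatenate([seg_bounds[:-1], [tail_end]])
    if any(ev.time >= eval_times[-1] for ev in spec.events):
        raise ValueError("scenario events lie outside the grid support")

    times = sorted(
        set(ev.time for ev in spec.events)
        | set(b for mw in spec.migrations for b in (mw.start, mw.end))
        | set(eval_times.tolist())
    )
    sizes = dict(spec.demes)
    events_at: dict[float, list] = {}
    for ev in spec.events:
        events_at.setdefault(ev.time, []).append(ev)

    surv = np.empty((len(eval_times), 3))
    P = starts.copy()
    eval_idx = 0
    t_prev = 0.0
    for t in times:
        if t > t_prev:
            Q = chain.generator(sizes, _migration_matrix(spec, t_prev))
            P = P @ expm(Q * (t - t_prev))
        # record survival at grid boundaries (before applying instantaneous
        # relabeling at the same instant: boundaries see the pre-event state)
        if eval_idx < len(eval_times) and np.isclose(t, eval_times[eval_idx]):
            surv[eval_idx] = 1.0 - P[:, chain.c_idx]
            eval_idx += 1
        for ev in events_at.get(t, []):
            if isinstance(ev, SizeChange):
                sizes[ev.deme] = ev.size
            else:
                P = P @ chain.lift(_event_matrix(spec, ev))
        t_prev = t
    assert eval_idx == len(eval_times)

    n = grid.n_segments
    lam = np.zeros((n, 3))
    widths = np.diff(eval_times)
    for i in range(n):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(surv[i] > 0, surv[i + 1] / surv[i], 1.0)
        lam[i] = np.where(ratio > 0, -np.log(ratio) / widths[i], np.inf)
    lam = np.nan_to_num(lam, posinf=1.0)  # capped hazard where survival died
    seg_scaled = grid.segment_boundaries_scaled
    return RateTable(left_boundaries=seg_scaled[:-1],
                     right_boundaries=seg_scaled[1:],
                     lambdas=lam / grid.mu)


# ---------------------------------------------------------------------------
# Predefined scenarios
# ---------------------------------------------------------------------------


def _kya_to_gens(kya: float, generation_time: float) -> float:
    return kya * 1000.0 / generation_time


def clean_split(T_kya: float = 75.0, N: float = 20_000.0,
                generation_time: float = DEFAULT_GENERATION_TIME,
                **kwargs) -> ScenarioSpec:
    """Two constant-size populations diverging cleanly at ``T_kya``."""
    T = _kya_to_gens(T_kya, generation_time)
    return ScenarioSpec(
        name=f"clean_split_{T_kya:g}kya",
        demes=(("pop1", N), ("pop2", N), ("anc", N)),
        samples=(("pop1", 4), ("pop2", 4)),
        events=(Split(T, "pop1", "anc"), Split(T, "pop2", "anc")),
        generation_time=generation_time,
        **kwargs,
    )


def split_with_migration(T_kya: float = 75.0, mig_start_kya: float = 10.0,
                         mig_end_kya: float = 15.0,
                         total_migration: float = 0.5,
                         N: float = 20_000.0,
                         generation_time: float = DEFAULT_GENERATION_TIME,
                         **kwargs) -> ScenarioSpec:
    """Clean split plus a post-split window of symmetric migration whose
    per-direction time-integral is ``total_migration``."""
    T = _kya_to_gens(T_kya, generation_time)
    lo = _kya_to_gens(mig_start_kya, generation_time)
    hi = _kya_to_gens(mig_end_kya, generation_time)
    rate = total_migration / (hi - lo)
    return ScenarioSpec(
        name=f"split_with_migration_{T_kya:g}kya",
        demes=(("pop1", N), ("pop2", N), ("anc", N)),
        samples=(("pop1", 4), ("pop2", 4)),
        events=(Split(T, "pop1", "anc"), Split(T, "pop2", "anc")),
        migrations=(MigrationWindow(lo, hi, "pop1", "pop2", rate),),
        generation_time=generation_time,
        **kwargs,
    )


def archaic(alpha: float = 0.05, T_kya: float = 75.0,
            pulse_kya: float = 30.0, Ta_kya: float = 1000.0,
            N: float = 20_000.0, bottleneck: bool = False,
            bottleneck_factor: float = 30.0,
            bottleneck_window_kya: tuple[float, float] = (40.0, 60.0),
            generation_time: float = DEFAULT_GENERATION_TIME,
            **kwargs) -> ScenarioSpec:
    """Split at ``T_kya`` with an admixture pulse into population 1 at
    ``pulse_kya`` from an unsampled deme that diverged at ``Ta_kya``;
    optionally a bottleneck (size divided by ``bottleneck_factor``) in
    population 1 over ``bottleneck_window_kya``."""
    T = _kya_to_gens(T_kya, generation_time)
    tp = _kya_to_gens(pulse_kya, generation_time)
    Ta = _kya_to_gens(Ta_kya, generation_time)
    events: list = []
    if alpha > 0:
        events.append(Pulse(tp, "pop1", "ghost", alpha))
    if bottleneck:
        lo = _kya_to_gens(bottleneck_window_kya[0], generation_time)
        hi = _kya_to_gens(bottleneck_window_kya[1], generation_time)
        events.append(SizeChange(lo, "pop1", N / bottleneck_factor))
        events.append(SizeChange(hi, "pop1", N))
    events += [Split(T, "pop1", "anc"), Split(T, "pop2", "anc"),
               Split(Ta, "ghost", "anc")]
    events.sort(key=lambda e: e.time)
    tag = "archaic_bottleneck" if bottleneck else "archaic"
    return ScenarioSpec(
        name=f"{tag}_{100 * alpha:g}pct",
        demes=(("pop1", N), ("pop2", N), ("ghost", N), ("anc", N)),
        samples=(("pop1", 4), ("pop2", 4)),
        events=tuple(events),
        generation_time=generation_time,
        **kwargs,
    )


def zigzag(N_min: float = 3_000.0, N_max: float = 30_000.0,
           t0_gens: float = 400.0, n_flips: int = 9,
           generation_time: float = DEFAULT_GENERATION_TIME,
           **kwargs) -> ScenarioSpec:
    """Single population whose size alternates between ``N_min`` and
    ``N_max`` at exponentially increasing times (piecewise-constant
    rendering of the classic zigzag history); recombination rate defaults
    to 0.3e-8 as in the history this emulates."""
    kwargs.setdefault("rho", 0.3e-8)
    events = []
    size = N_min
    for k in range(n_flips):
        events.append(SizeChange(t0_gens * 2.0 ** k, "pop", size))
        size = N_max if size == N_min else N_min
    return ScenarioSpec(
        name="zigzag",
        demes=(("pop", N_max),),
        samples=(("pop", 8),),
        events=tuple(events),
        generation_time=generation_time,
        **kwargs,
    )


def predefined_scenarios(
        generation_time: float = DEFAULT_GENERATION_TIME) -> dict[str, ScenarioSpec]:
    """The named scenario set used throughout the simulation study."""
    g = generation_time
    out = {
        "clean_split": clean_split(75.0, generation_time=g),
        "split_with_migration": split_with_migration(75.0, generation_time=g),
        "archaic": archaic(0.05, generation_time=g),
        "archaic_bottleneck": archaic(0.05, bottleneck=True, generation_time=g),
        "zigzag": zigzag(generation_time=g),
    }
    for T in (15, 30, 50, 75, 100, 150):
        out[f"clean_split_{T}kya"] = clean_split(float(T), generation_time=g)
    for pct in (0, 1, 5, 10, 20):
        out[f"archaic_{pct}pct"] = archaic(pct / 100.0, generation_time=g)
    return out


def scenario_from_im_params(params, name: str = "fitted-im",
                            m_floor: float = 1e-12, **kwargs) -> ScenarioSpec:
    """Convert fitted two-island parameters into a ScenarioSpec.

    The resulting scenario has two demes whose sizes follow the fitted
    N1(t), N2(t) step functions and symmetric migration windows carrying
    the fitted m(t) (segments with ``m <= m_floor`` are dropped).  Running
    :func:`exact_coal_rates` on it reproduces the model's own implied
    rates, which closes the simulate-from-fit / refit consistency loop.
    The open-ended final segment's migration continues to the engine's
    evaluation horizon via a wide final window.
    """
    grid = params.grid
    bounds = grid.segment_boundaries_gens
    events = []
    for i in range(1, grid.n_segments):
        if params.N1[i] != params.N1[i - 1]:
            events.append(SizeChange(bounds[i], "pop1", params.N1[i]))
        if params.N2[i] != params.N2[i - 1]:
            events.append(SizeChange(bounds[i], "pop2", params.N2[i]))
    migrations = []
    for i in range(grid.n_segments):
        if params.m[i] > m_floor:
            hi = bounds[i + 1] if i + 1 < len(bounds) else bounds[-1]
            if i == grid.n_segments - 1:
                hi = bounds[-1] * 100.0  # open-ended tail
            migrations.append(MigrationWindow(bounds[i], hi, "pop1", "pop2",
                                              params.m[i]))
    events.sort(key=lambda e: e.time)
    return ScenarioSpec(
        name=name,
        demes=(("pop1", params.N1[0]), ("pop2", params.N2[0])),
        samples=(("pop1", 4), ("pop2", 4)),
        events=tuple(events),
        migrations=tuple(migrations),
        mu=grid.mu,
        generation_time=grid.generation_time,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Sequence simulation (msprime) and fixture corruption
# ---------------------------------------------------------------------------


def _to_msprime_demography(spec: ScenarioSpec):
    import msprime

    dem = msprime.Demography()
    for name, size in spec.demes:
        dem.add_population(name=name, initial_size=size)
    changes = []
    for ev in spec.events:
        if isinstance(ev, SizeChange):
            changes.append((ev.time, "size", ev))
        elif isinstance(ev, Split):
            changes.append((ev.time, "move", (ev.derived, ev.ancestral, 1.0)))
        elif isinstance(ev, Pulse):
            changes.append((ev.time, "move", (ev.deme, ev.source, ev.fraction)))
    for mw in spec.migrations:
        changes.append((mw.start, "mig", (mw.deme_a, mw.deme_b, mw.rate)))
        changes.append((mw.end, "mig", (mw.deme_a, mw.deme_b, 0.0)))
    changes.sort(key=lambda c: c[0])
    for time, kind, payload in changes:
        if kind == "size":
            dem.add_population_parameters_change(
                time=time, population=payload.deme, initial_size=payload.size)
        elif kind == "move":
            src, dst, frac = payload
            dem.add_mass_migration(time=time, source=src, dest=dst,
                                   proportion=frac)
        else:
            a, b, rate = payload
            dem.add_migration_rate_change(time=time, rate=rate, source=a, dest=b)
            dem.add_migration_rate_change(time=time, rate=rate, source=b, dest=a)
    dem.sort_events()
    return dem


def simulate_sequences(
    spec: ScenarioSpec,
    seed: int,
    n_chrom: int | None = None,
    chrom_length: float | None = None,
) -> list[list[MultihetsepRecord]]:
    """Coalescent-with-recombination simulation of the scenario.

    Returns one list of multihetsep records per chromosome (chromosomes
    named ``chr1`` ...), with fully known phase and every site treated as
    called.  Byte-identical output for a fixed seed.
    """
    import msprime

    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    n_chrom = spec.n_chrom if n_chrom is None else n_chrom
    length = spec.chrom_length if chrom_length is None else chrom_length
    dem = _to_msprime_demography(spec)
    samples = {d: n // 2 for d, n in spec.samples if n > 0}
    rng = np.random.RandomState(seed)
    chroms: list[list[MultihetsepRecord]] = []
    for c in range(n_chrom):
        s_anc, s_mut = int(rng.randint(1, 2 ** 31 - 1)), int(rng.randint(1, 2 ** 31 - 1))
        ts = msprime.sim_ancestry(
            samples=samples, demography=dem, sequence_length=length,
            recombination_rate=spec.rho, ploidy=2, random_seed=s_anc)
        ts = msprime.sim_mutations(ts, rate=spec.mu, random_seed=s_mut,
                                   model=msprime.BinaryMutationModel())
        records = []
        last_pos = 0
        for var in ts.variants():
            pos = int(var.site.position) + 1
            if pos <= last_pos:
                continue
            genotypes = var.genotypes
            if genotypes.max() > 1 or genotypes.min() < 0 or genotypes.max() == 0:
                continue
            alleles = "".join(str(g) for g in genotypes)
            records.append(MultihetsepRecord(
                chrom=f"chr{c + 1}", pos=pos,
                called_since_last=pos - last_pos, alleles=alleles))
            last_pos = pos
        chroms.append(records)
    return chroms


def write_multihetsep_files(chroms: list[list[MultihetsepRecord]],
                            out_dir: str | Path, prefix: str = "sim") -> list[Path]:
    from imtracer.io_msmc import write_multihetsep

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, records in enumerate(chroms):
        path = out_dir / f"{prefix}.chr{i + 1}.multihetsep.txt"
        write_multihetsep(records, path)
        paths.append(path)
    return paths


def inject_switch_errors(
    records: list[MultihetsepRecord],
    rate_per_bp: float,
    seed: int,
    sequence_length: float | None = None,
) -> list[MultihetsepRecord]:
    """Corrupt phase by swapping haplotype labels within each individual
    from each sampled switch point onward.

    Switch points form a Poisson process of intensity ``rate_per_bp`` per
    individual along the chromosome; two consecutive switches restore the
    original phase in between.  ``rate_per_bp = 0`` returns the records
    unchanged.
    """
    if rate_per_bp < 0:
        raise ValueError("switch error rate must be nonnegative")
    if not records or rate_per_bp == 0:
        return list(records)
    length = sequence_length or max(r.pos for r in records)
    n_hap = records[0].n_haplotypes
    if n_hap % 2:
        raise ValueError("switch errors require an even haplotype count")
    rng = np.random.RandomState(seed)
    switch_points = []
    for _ in range(n_hap // 2):
        k = rng.poisson(rate_per_bp * length)
        switch_points.append(np.sort(rng.uniform(1, length + 1, size=k)))
    out = []
    for rec in records:
        phasings = []
        for p in rec.alleles.split(","):
            h = list(p)
            for ind in range(n_hap // 2):
                flips = int(np.searchsorted(switch_points[ind], rec.pos,
                                            side="right"))
                if flips % 2:
                    a, b = 2 * ind, 2 * ind + 1
                    h[a], h[b] = h[b], h[a]
            phasings.append("".join(h))
        out.append(dataclasses.replace(rec, alleles=",".join(phasings)))
    return out
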