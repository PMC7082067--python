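"""Discretized time axis shared by rate estimation and IM fitting.

Times come in two unit systems:

* *mutation-scaled* units, the native scale of MSMC-family rate tables,
  where a time ``t`` in generations is reported as ``t * mu`` with ``mu``
  the per-bp per-generation mutation rate;
* *generations*, used for all model computations.

The axis is a sequence of atomic interval boundaries grouped into
parameter segments by an MSMC-style pattern string such as
``1*2+25*1+1*2+1*3`` (28 parameter segments over 32 atomic intervals).
Boundary placement follows the PSMC-family convention of exponential
quantiles of the pairwise-coalescence prior: atomic boundary ``i`` of
``n`` sits at ``-ln(1 - i/n)`` in coalescent time units (units of
``2*N_ref`` generations), optionally compressed by the number of
haplotype pairs analysed jointly.  The final interval is open-ended.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

DEFAULT_PATTERN = "1*2+25*1+1*2+1*3"
DEFAULT_MU = 1.25e-8
DEFAULT_N_REF = 20_000.0
#: Default generation time in years used only for reporting axes in years.
DEFAULT_GENERATION_TIME = 29.0

_PATTERN_TOKEN = re.compile(r"^(\d+)\*(\d+)$")


@dataclass(frozen=True)
class TimePattern:
    """Grouping of atomic time intervals into parameter segments.

    ``groups`` is an ordered list of ``(segment_count, intervals_per_segment)``
    pairs, exactly the semantics of the ``--pattern`` flag of the MSMC-family
    tools.
    """

    groups: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("time pattern must contain at least one group")
        for count, width in self.groups:
            if count <= 0 or width <= 0:
                raise ValueError(
                    f"time pattern entries must be positive, got {count}*{width}"
                )
        if self.n_atomic < 2:
            raise ValueError("time pattern must span at least 2 atomic intervals")

    @property
    def n_segments(self) -> int:
        return sum(count for count, _ in self.groups)

    @property
    def n_atomic(self) -> int:
        return sum(count * width for count, width in self.groups)

    def segment_of_atomic(self) -> np.ndarray:
        """Parameter-segment index for every atomic interval."""
        idx = []
        seg = 0
        for count, width in self.groups:
            for _ in range(count):
                idx.extend([seg] * width)
                seg += 1
        return np.asarray(idx, dtype=int)

    def __str__(self) -> str:
        return "+".join(f"{c}*{w}" for c, w in self.groups)


def parse_time_pattern(pattern_text: str) -> TimePattern:
    """Parse an MSMC-style segment-pattern string like ``1*2+25*1+1*2+1*3``.

    Raises ``ValueError`` naming the offending token on malformed input.
    """
    if not isinstance(pattern_text, str) or not pattern_text.strip():
        raise ValueError("empty time pattern")
    groups = []
    for token in pattern_text.strip().split("+"):
        match = _PATTERN_TOKEN.match(token.strip())
        if match is None:
            raise ValueError(f"malformed time-pattern token: {token!r}")
        count, width = int(match.group(1)), int(match.group(2))
        if count == 0 or width == 0:
            raise ValueError(f"zero entry in time-pattern token: {token!r}")
        groups.append((count, width))
    return TimePattern(tuple(groups))


@dataclass(frozen=True)
class TimeGrid:
    """Discretized time axis in mutation-scaled units.

    ``boundaries_scaled`` holds the ``n_atomic + 1`` atomic boundaries
    starting at 0; the last atomic interval is open-ended (its stored right
    boundary is the last *finite* boundary, i.e. ``boundaries_scaled[-1]``
    is finite and the final segment extends beyond it to infinity).
    """

    pattern: TimePattern
    boundaries_scaled: np.ndarray
    mu: float
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries_scaled, dtype=float)
        object.__setattr__(self, "boundaries_scaled", b)
        if b[0] != 0.0:
            raise ValueError("first grid boundary must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("grid boundaries must be strictly increasing")
        if len(b) != self.pattern.n_atomic + 1:
            raise ValueError(
                f"expected {self.pattern.n_atomic + 1} boundaries, got {len(b)}"
            )

    @property
    def n_atomic(self) -> int:
        return self.pattern.n_atomic

    @property
    def n_segments(self) -> int:
        return self.pattern.n_segments

    @cached_property
    def segment_index_of_atomic(self) -> np.ndarray:
        return self.pattern.segment_of_atomic()

    @cached_property
    def segment_boundaries_scaled(self) -> np.ndarray:
        """The ``n_segments + 1`` parameter-segment boundaries (scaled units)."""
        seg_of = self.segment_index_of_atomic
        starts = [0]
        for a in range(1, self.n_atomic):
            if seg_of[a] != seg_of[a - 1]:
                starts.append(a)
        idx = np.array(starts + [self.n_atomic])
        return self.boundaries_scaled[idx]

    @cached_property
    def segment_boundaries_gens(self) -> np.ndarray:
        return scale_to_generations(self.segment_boundaries_scaled, self.mu)

    @cached_property
    def boundaries_gens(self) -> np.ndarray:
        return scale_to_generations(self.boundaries_scaled, self.mu)

    def segment_of_time_gens(self, t: float) -> int:
        """Parameter segment containing time ``t`` (generations)."""
        b = self.segment_boundaries_gens
        if t < 0:
            raise ValueError("time must be nonnegative")
        return min(int(np.searchsorted(b, t, side="right")) - 1, self.n_segments - 1)

    def years(self, t_gens: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(t_gens) * self.generation_time


def make_time_grid(
    pattern: TimePattern | str = DEFAULT_PATTERN,
    n_haplotype_pairs: int = 1,
    mu: float = DEFAULT_MU,
    n_ref: float = DEFAULT_N_REF,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> TimeGrid:
    """Build a time grid with exponential-quantile boundary placement.

    Atomic boundary ``i`` of ``n`` sits at ``-ln(1 - i/n)`` coalescent time
    units; one coalescent unit is ``2 * n_ref`` generations (the mean
    pairwise tMRCA for a diploid population of size ``n_ref``), divided by
    ``n_haplotype_pairs``.  Boundaries are then expressed in mutation-scaled
    units by multiplying with ``mu``.  The grid is reproducible bit-for-bit
    from its arguments.
    """
    if isinstance(pattern, str):
        pattern = parse_time_pattern(pattern)
    if mu <= 0:
        raise ValueError("mu must be positive")
    if n_haplotype_pairs < 1:
        raise ValueError("n_haplotype_pairs must be >= 1")
    n = pattern.n_atomic
    i = np.arange(n)
    quantiles = -np.log1p(-i / n)  # last boundary of the open interval omitted
    bounds_gens = np.append(quantiles, -np.log(1.0 / (2 * n)) )  # finite cap for
    # the left edge of the open-ended final interval is -ln(1 - (n-1)/n); the
    # appended value only records a finite "last boundary" used for penalty
    # spans and plotting, placed at the 1/(2n) tail quantile.
    bounds_gens = bounds_gens * (2.0 * n_ref / n_haplotype_pairs)
    return TimeGrid(
        pattern=pattern,
        boundaries_scaled=bounds_gens * mu,
        mu=mu,
        generation_time=generation_time,
    )


def scale_to_generations(t_scaled, mu: float):
    """Convert mutation-scaled time to generations (divide by ``mu``)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return np.asarray(t_scaled, dtype=float) / mu if np.ndim(t_scaled) else float(t_scaled) / mu


def generations_to_scaled(t_gens, mu: float):
    """Inverse of :func:`scale_to_generations`."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return np.asarray(t_gens, dtype=float) * mu if np.ndim(t_gens) else float(t_gens) * mu
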