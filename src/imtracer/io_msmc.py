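"""Readers and writers for MSMC2 rate-table dialects and multihetsep files.

Two tab-separated table dialects are supported:

* the single-rate "final" table with header
  ``time_index  left_time_boundary  right_time_boundary  lambda``;
* the combined three-rate table with columns
  ``lambda_00  lambda_01  lambda_11`` (within population 1, cross,
  within population 2).

A multihetsep file lists segregating sites, one per line, as
``chrom  pos  called_sites_since_last  alleles`` with no header;
``alleles`` is a string of one character per haplotype, with
comma-separated alternatives when the phasing of a site is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_FLOAT_FMT = "%.14g"  # byte-stable, locale-independent significant digits


@dataclass(frozen=True)
class RateTable:
    """Piecewise-constant coalescence rates on contiguous time segments.

    Times and rates are in mutation-scaled units (a time ``t`` in
    generations appears as ``t*mu``; the rate per generation is
    ``lambda * mu``).  ``lambdas`` has shape ``(n_segments, 1)`` or
    ``(n_segments, 3)``; in the three-column case the order is
    (within-1, cross, within-2).  The last segment is open-ended; its
    stored right boundary is a finite plotting cap.
    """

    left_boundaries: np.ndarray
    right_boundaries: np.ndarray
    lambdas: np.ndarray

    def __post_init__(self) -> None:
        left = np.asarray(self.left_boundaries, dtype=float)
        right = np.asarray(self.right_boundaries, dtype=float)
        lam = np.atleast_2d(np.asarray(self.lambdas, dtype=float))
        if lam.shape[0] == 1 and len(left) > 1:
            lam = lam.T
        object.__setattr__(self, "left_boundaries", left)
        object.__setattr__(self, "right_boundaries", right)
        object.__setattr__(self, "lambdas", lam)
        if not (len(left) == len(right) == lam.shape[0]):
            raise ValueError("rate table columns have inconsistent lengths")
        if lam.shape[1] not in (1, 3):
            raise ValueError("rate table must have 1 or 3 lambda columns")
        if left[0] != 0.0:
            raise ValueError("first left boundary must be 0")
        if not np.allclose(left[1:], right[:-1], rtol=0, atol=1e-12):
            raise ValueError("non-contiguous time boundaries in rate table")
        if np.any(right <= left):
            raise ValueError("segment right boundaries must exceed left boundaries")
        if np.any(lam < 0):
            raise ValueError("negative coalescence rate in rate table")

    @property
    def n_segments(self) -> int:
        return len(self.left_boundaries)

    @property
    def n_lambda(self) -> int:
        return self.lambdas.shape[1]

    def boundaries(self) -> np.ndarray:
        """All ``n_segments + 1`` boundaries including the final plotting cap."""
        return np.append(self.left_boundaries, self.right_boundaries[-1])

    def rates_per_generation(self, mu: float) -> np.ndarray:
        return self.lambdas * mu

    def boundaries_gens(self, mu: float) -> np.ndarray:
        return self.boundaries() / mu


def read_rate_table(path: str | Path) -> RateTable:
    """Read a single- or three-rate MSMC2-style table.

    Raises ``ValueError`` with a line number on malformed rows.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty rate table")
    header = lines[0].split("\t")
    n_lambda = len(header) - 3
    if n_lambda not in (1, 3):
        raise ValueError(f"{path}: expected 1 or 3 lambda columns, got {n_lambda}")
    left, right, lams = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3 + n_lambda:
            raise ValueError(f"{path}:{lineno}: expected {3 + n_lambda} fields")
        try:
            idx = int(fields[0])
            lo, hi = float(fields[1]), float(fields[2])
            row = [float(x) for x in fields[3:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if idx != len(left):
            raise ValueError(f"{path}:{lineno}: time_index not consecutive")
        left.append(lo)
        right.append(hi)
        lams.append(row)
    try:
        return RateTable(np.array(left), np.array(right), np.array(lams))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_rate_table(table: RateTable, path: str | Path) -> None:
    path = Path(path)
    if table.n_lambda == 1:
        header = "time_index\tleft_time_boundary\tright_time_boundary\tlambda"
    else:
        header = (
            "time_index\tleft_time_boundary\tright_time_boundary"
            "\tlambda_00\tlambda_01\tlambda_11"
        )
    rows = [header]
    for i in range(table.n_segments):
        fields = [str(i),
                  _FLOAT_FMT % table.left_boundaries[i],
                  _FLOAT_FMT % table.right_boundaries[i]]
        fields += [_FLOAT_FMT % x for x in table.lambdas[i]]
        rows.append("\t".join(fields))
    path.write_text("\n".join(rows) + "\n")


def _piecewise_constant_eval(table: RateTable, t: np.ndarray) -> np.ndarray:
    """Evaluate a single-rate table at times ``t`` (piecewise-constant,
    clamping to the first/last segment outside the finite support)."""
    bounds = table.boundaries()
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0,
                  table.n_segments - 1)
    return table.lambdas[idx, 0]


def combine_cross_coal(
    within1: RateTable, across: RateTable, within2: RateTable
) -> RateTable:
    """Merge three single-rate tables into one three-rate table.

    The result lives on the grid of the ``across`` run; within-population
    rates are transferred by piecewise-constant evaluation at the midpoints
    of the target segments (exact when the grids nest).
    """
    for name, tab in (("within1", within1), ("across", across), ("within2", within2)):
        if tab.n_lambda != 1:
            raise ValueError(f"{name} table must have a single lambda column")
    mid = 0.5 * (across.left_boundaries + across.right_boundaries)
    lam = np.column_stack([
        _piecewise_constant_eval(within1, mid),
        across.lambdas[:, 0],
        _piecewise_constant_eval(within2, mid),
    ])
    return RateTable(across.left_boundaries.copy(),
                     across.right_boundaries.copy(), lam)


@dataclass(frozen=True)
class MultihetsepRecord:
    """One segregating site: position, called sites since the previous
    segregating site (inclusive of this one), and the phased allele string
    (comma-separated alternatives if the phasing is ambiguous)."""

    chrom: str
    pos: int
    called_since_last: int
    alleles: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based and positive")
        if self.called_since_last < 1:
            raise ValueError("called_since_last must be positive")
        phasings = self.alleles.split(",")
        n = len(phasings[0])
        if n == 0 or any(len(p) != n for p in phasings):
            raise ValueError(f"inconsistent allele string {self.alleles!r}")

    @property
    def n_haplotypes(self) -> int:
        return len(self.alleles.split(",")[0])


def read_multihetsep(path: str | Path) -> list[MultihetsepRecord]:
    path = Path(path)
    records: list[MultihetsepRecord] = []
    last_pos: dict[str, int] = {}
    n_hap = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 fields")
        try:
            rec = MultihetsepRecord(fields[0], int(fields[1]), int(fields[2]),
                                    fields[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        if rec.chrom in last_pos and rec.pos <= last_pos[rec.chrom]:
            raise ValueError(f"{path}:{lineno}: positions not strictly increasing")
        if n_hap is None:
            n_hap = rec.n_haplotypes
        elif rec.n_haplotypes != n_hap:
            raise ValueError(f"{path}:{lineno}: inconsistent haplotype count")
        last_pos[rec.chrom] = rec.pos
        records.append(rec)
    return records


def write_multihetsep(records: Iterable[MultihetsepRecord], path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"{r.chrom}\t{r.pos}\t{r.called_since_last}\t{r.alleles}" for r in records
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
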