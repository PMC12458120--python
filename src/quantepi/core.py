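"""Core genomic containers shared by every analysis stage.

All coordinates are 0-based, half-open ``[start, end)`` — the native
convention of BED and bedGraph — so an interval's width is ``end - start``
and adjacent intervals share no base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "QuantTrack",
    "BetaMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input violated a container invariant (ordering, range, overlap)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self!r}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint base (floor division)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class QuantTrack:
    """A stepwise-constant, non-negative signal over genomic intervals.

    This is the in-memory form of a quantitative ChIP efficiency surface:
    sorted, non-overlapping intervals each carrying one value. Bases not
    covered by any interval carry signal 0 (absence means no signal, not
    missing data). Per-chromosome data are stored as parallel numpy arrays
    for fast interval arithmetic.

    Parameters
    ----------
    data
        Mapping ``chrom -> (starts, ends, values)`` of equal-length arrays,
        sorted by start, non-overlapping, values >= 0.
    chrom_lengths
        Optional chromosome length map; needed only by consumers that must
        reason about chromosome bounds (e.g. profile matrices).
    """

    def __init__(
        self,
        data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        chrom_lengths: dict[str, int] | None = None,
    ) -> None:
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValidationError(f"{chrom}: ragged track arrays")
            if len(starts):
                if np.any(starts < 0):
                    raise ValidationError(f"{chrom}: negative coordinate")
                if np.any(ends <= starts):
                    raise ValidationError(f"{chrom}: empty or inverted interval")
                if np.any(starts[1:] < starts[:-1]):
                    raise ValidationError(f"{chrom}: intervals not sorted by start")
                if np.any(starts[1:] < ends[:-1]):
                    raise ValidationError(f"{chrom}: overlapping intervals")
                if np.any(values < 0):
                    raise ValidationError(f"{chrom}: negative signal value")
            self._data[chrom] = (starts, ends, values)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, int, int, float]],
        chrom_lengths: dict[str, int] | None = None,
    ) -> "QuantTrack":
        """Build a track from ``(chrom, start, end, value)`` tuples.

        Records are sorted on load; overlapping intervals are rejected.
        """
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        data = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            data[chrom] = (starts, ends, values)
        return cls(data, chrom_lengths=chrom_lengths)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) for one chromosome; empty arrays if absent."""
        if chrom not in self._data:
            empty = np.array([], dtype=np.int64)
            return empty, empty, np.array([], dtype=np.float64)
        return self._data[chrom]

    def intervals(self) -> list[tuple[str, int, int, float]]:
        """All intervals as ``(chrom, start, end, value)`` in sorted order."""
        out = []
        for chrom in sorted(self._data):
            starts, ends, values = self._data[chrom]
            out.extend(
                (chrom, int(s), int(e), float(v))
                for s, e, v in zip(starts, ends, values)
            )
        return out

    def n_intervals(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    def area(self, chrom: str, start: float, end: float) -> float:
        """Integral of the signal over ``[start, end)`` in signal*bp.

        Accepts fractional bounds (used by scaled-body profile bins);
        uncovered bases contribute 0.
        """
        if end <= start:
            return 0.0
        starts, ends, values = self.arrays(chrom)
        if not len(starts):
            return 0.0
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        overlap = np.clip(e - s, 0.0, None)
        return float(np.dot(overlap, values[lo:hi]))

    def mean(self, chrom: str, start: float, end: float) -> float:
        """Base-pair-weighted mean signal over ``[start, end)``."""
        if end <= start:
            return 0.0
        return self.area(chrom, start, end) / (end - start)

    def scale(self, factor: float) -> "QuantTrack":
        """Return a copy with every value multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValidationError("scale factor must be non-negative")
        data = {
            chrom: (s.copy(), e.copy(), v * factor)
            for chrom, (s, e, v) in self._data.items()
        }
        return QuantTrack(data, chrom_lengths=self.chrom_lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuantTrack):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        for chrom in self._data:
            a, b = self._data[chrom], other._data[chrom]
            if not all(np.array_equal(x, y) for x, y in zip(a, b)):
                return False
        return True


@dataclass
class BetaMatrix:
    """Methylation beta values (fractions in [0, 1]) at ordered CpG positions.

    ``probes`` holds probe_id / chrom / pos (one base per probe); ``beta``
    holds one column per sample, row-aligned with ``probes``. Probes are
    sorted by (chrom, pos) with no duplicate positions.
    """

    probes: pd.DataFrame
    beta: pd.DataFrame
    sample_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "pos"}
        if not required.issubset(self.probes.columns):
            raise ValidationError(f"probe table needs columns {sorted(required)}")
        if len(self.probes) != len(self.beta):
            raise ValidationError("probe and beta tables have different lengths")
        vals = self.beta.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValidationError("beta values must lie in [0, 1]")
        key = self.probes[["chrom", "pos"]]
        if key.duplicated().any():
            raise ValidationError("duplicate probe positions")
        ordered = self.probes.sort_values(["chrom", "pos"], kind="mergesort")
        if not ordered.index.equals(self.probes.index):
            self.beta = self.beta.loc[ordered.index].reset_index(drop=True)
            self.probes = ordered.reset_index(drop=True)
        for group, cols in self.sample_groups.items():
            missing = [c for c in cols if c not in self.beta.columns]
            if missing:
                raise ValidationError(f"group {group!r}: unknown samples {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def group_mean(self, samples: list[str]) -> np.ndarray:
        if not samples:
            raise ValidationError("empty sample group")
        return self.beta[samples].to_numpy(dtype=float).mean(axis=1)
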