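"""Per-base read coverage from bedGraph tracks.

bedGraph uses 0-based half-open intervals, matching the package's internal
coordinate convention. Positions not covered by any record have depth 0.
"""

from __future__ import annotations

from bisect import bisect_right
from pathlib import Path
from typing import Iterable, Mapping


class CoverageTrack:
    """Sparse per-chromosome depth, queryable by position or interval."""

    def __init__(self, intervals: Mapping[str, list[tuple[int, int, float]]] | None = None):
        # per chrom: parallel sorted lists of (start, end, value)
        self._chroms: dict[str, tuple[list[int], list[int], list[float]]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self._set_chrom(chrom, ivs)

    def _set_chrom(self, chrom: str, ivs: Iterable[tuple[int, int, float]]) -> None:
        ivs = sorted(ivs)
        starts, ends, values = [], [], []
        for s, e, v in ivs:
            if e <= s:
                raise ValueError(f"{chrom}: empty coverage interval {s}-{e}")
            if ends and s < ends[-1]:
                raise ValueError(f"{chrom}: overlapping coverage intervals at {s}")
            starts.append(s)
            ends.append(e)
            values.append(float(v))
        self._chroms[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
                chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                per_chrom.setdefault(chrom, []).append((s, e, v))
        return cls(per_chrom)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def chrom_max_end(self, chrom: str) -> int:
        if chrom not in self._chroms:
            return 0
        ends = self._chroms[chrom][1]
        return ends[-1] if ends else 0

    def depth(self, chrom: str, pos: int) -> float:
        """Depth at a single base."""
        if chrom not in self._chroms:
            return 0.0
        starts, ends, values = self._chroms[chrom]
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return values[i]
        return 0.0

    def min_depth(self, chrom: str, start: int, end: int) -> float:
        """Minimum depth over [start, end); any uncovered base counts as 0."""
        if end <= start:
            raise ValueError("empty interval")
        if chrom not in self._chroms:
            return 0.0
        starts, ends, values = self._chroms[chrom]
        i = max(bisect_right(starts, start) - 1, 0)
        cursor = start
        lo = float("inf")
        while cursor < end and i < len(starts):
            s, e, v = starts[i], ends[i], values[i]
            if e <= cursor:
                i += 1
                continue
            if s > cursor:
                return 0.0  # gap
            lo = min(lo, v)
            cursor = e
            i += 1
        if cursor < end:
            return 0.0
        return lo

    def is_fully_covered(self, chrom: str, start: int, end: int, min_depth: float = 1.0) -> bool:
        """True iff every base of [start, end) has depth >= min_depth."""
        return self.min_depth(chrom, start, end) >= min_depth

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Mean depth over [start, end), uncovered bases contributing 0."""
        if end <= start:
            raise ValueError("empty interval")
        if chrom not in self._chroms:
            return 0.0
        starts, ends, values = self._chroms[chrom]
        total = 0.0
        i = max(bisect_right(starts, start) - 1, 0)
        for s, e, v in zip(starts[i:], ends[i:], values[i:]):
            if s >= end:
                break
            ov = min(e, end) - max(s, start)
            if ov > 0:
                total += ov * v
        return total / (end - start)


def write_bedgraph(track_rows: Iterable[tuple[str, int, int, float]], path: str | Path) -> None:
    rows = sorted(track_rows)
    with open(path, "w") as fh:
        for chrom, s, e, v in rows:
            v_str = f"{v:g}"
            fh.write(f"{chrom}\t{s}\t{e}\t{v_str}\n")
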