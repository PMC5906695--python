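"""Genomic interval algebra on 0-based half-open coordinates.

All interval sets are normalized on construction: per-chromosome arrays are
sorted and overlapping/adjacent-after-merge records are collapsed, so
``total_bp`` is always the exact number of distinct bases covered.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Sort and merge an (n, 2) array of [start, end) intervals."""
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s <= cur_e:  # overlap or adjacency merges
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


class IntervalSet:
    """An immutable set of genomic intervals, merged and sorted per chromosome."""

    def __init__(self, records: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            if start < 0:
                raise ValueError(f"negative coordinate {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        self._ivals: dict[str, np.ndarray] = {
            c: _normalize(np.asarray(v, dtype=np.int64)) for c, v in sorted(by_chrom.items())
        }

    @classmethod
    def _from_arrays(cls, ivals: Mapping[str, np.ndarray]) -> "IntervalSet":
        obj = cls.__new__(cls)
        obj._ivals = {c: a for c, a in sorted(ivals.items()) if a.size}
        return obj

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        recs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                recs.append((f[0], int(f[1]), int(f[2])))
        return cls(recs)

    # -- basic accessors ---------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return list(self._ivals)

    def arrays(self, chrom: str) -> np.ndarray:
        return self._ivals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for c, arr in self._ivals.items():
            for s, e in arr:
                yield c, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(a) for a in self._ivals.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chromosomes != other.chromosomes:
            return False
        return all(np.array_equal(self._ivals[c], other._ivals[c]) for c in self._ivals)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_bp} bp)"

    @property
    def total_bp(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._ivals.values()))

    def is_empty(self) -> bool:
        return not self._ivals

    # -- set algebra -------------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        chroms = set(self._ivals) | set(other._ivals)
        out = {}
        for c in chroms:
            merged = np.concatenate([self.arrays(c), other.arrays(c)])
            out[c] = _normalize(merged)
        return IntervalSet._from_arrays(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for c in self._ivals:
            a, b = self.arrays(c), other.arrays(c)
            if not b.size:
                continue
            pieces = []
            j = 0
            for s, e in a:
                # advance to first b interval that can overlap
                while j < len(b) and b[j, 1] <= s:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    pieces.append((max(s, b[k, 0]), min(e, b[k, 1])))
                    k += 1
            if pieces:
                out[c] = np.asarray(pieces, dtype=np.int64)
        return IntervalSet._from_arrays(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for c in self._ivals:
            a, b = self.arrays(c), other.arrays(c)
            if not b.size:
                out[c] = a.copy()
                continue
            pieces = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    bs, be = b[k]
                    if bs > cur:
                        pieces.append((cur, min(bs, e)))
                    cur = max(cur, be)
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    pieces.append((cur, e))
            if pieces:
                out[c] = np.asarray(pieces, dtype=np.int64)
        return IntervalSet._from_arrays(out)

    # -- point / interval queries -------------------------------------------
    def contains(self, chrom: str, pos: int) -> bool:
        arr = self.arrays(chrom)
        if not arr.size:
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return bool(i >= 0 and pos < arr[i, 1])

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an array of positions."""
        arr = self.arrays(chrom)
        positions = np.asarray(positions)
        if not arr.size:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(positions.shape, dtype=bool)
        res[ok] = positions[ok] < arr[idx[ok], 1]
        return res

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        arr = self.arrays(chrom)
        if not arr.size:
            return False
        i = int(np.searchsorted(arr[:, 0], end, side="left"))
        return bool(i > 0 and arr[i - 1, 1] > start)

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Exact number of bases of [start, end) covered by this set."""
        arr = self.arrays(chrom)
        if not arr.size:
            return 0
        s = np.clip(arr[:, 0], start, end)
        e = np.clip(arr[:, 1], start, end)
        return int(np.maximum(e - s, 0).sum())

    # -- export --------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = [(c, int(s), int(e)) for c, s, e in self]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e in self:
                fh.write(f"{c}\t{s}\t{e}\n")


def genome_intervals(lengths: Mapping[str, int]) -> IntervalSet:
    """Full-chromosome interval set from a name -> length map."""
    return IntervalSet((c, 0, int(n)) for c, n in lengths.items() if n > 0)
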