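"""cfDNA fragment sets: containers, interval arithmetic, and BED/SAM I/O.

A :class:`FragmentSet` holds one sample's fragments as 0-based half-open
intervals grouped by chromosome. Coverage queries use sorted endpoint
arrays with prefix sums, so the total overlap of all fragments with a
window costs O(log n) instead of a per-base scan:

    sum_i |frag_i ∩ [a, b)|  =  ∫_a^b (#{s_i <= x} − #{e_i <= x}) dx

and each integral is a closed form over the sorted starts/ends.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam

from .annotation import normalize_chrom_name

logger = logging.getLogger(__name__)


class FragmentSet:
    """One sample's cfDNA fragments as half-open genomic intervals."""

    def __init__(self, intervals: Mapping[str, np.ndarray], stats: dict | None = None):
        self._intervals: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError(f"{chrom}: fragment with end <= start")
            if arr.size:
                self._intervals[chrom] = arr
        self._index_cache: dict[str, dict] = {}
        self.stats = stats or {}

    # ---- basic accessors -------------------------------------------------

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._intervals)

    @property
    def n_fragments(self) -> int:
        return sum(a.shape[0] for a in self._intervals.values())

    def count(self, chrom: str) -> int:
        a = self._intervals.get(chrom)
        return 0 if a is None else a.shape[0]

    def intervals(self, chrom: str) -> np.ndarray:
        return self._intervals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def lengths(self, chrom: str | None = None) -> np.ndarray:
        if chrom is not None:
            a = self.intervals(chrom)
            return a[:, 1] - a[:, 0]
        if not self._intervals:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([a[:, 1] - a[:, 0] for a in self._intervals.values()])

    def midpoints(self, chrom: str) -> np.ndarray:
        a = self.intervals(chrom)
        return (a[:, 0] + a[:, 1]) // 2

    # ---- coverage queries ------------------------------------------------

    def _index(self, chrom: str) -> dict:
        idx = self._index_cache.get(chrom)
        if idx is None:
            a = self.intervals(chrom)
            starts = np.sort(a[:, 0])
            ends = np.sort(a[:, 1])
            order = np.argsort(a[:, 0], kind="stable") if a.size else np.empty(0, np.int64)
            idx = {
                "starts": starts,
                "ends": ends,
                "cs_starts": np.concatenate(([0], np.cumsum(starts))),
                "cs_ends": np.concatenate(([0], np.cumsum(ends))),
                "ends_by_start": a[order, 1] if a.size else np.empty(0, np.int64),
                "max_len": int((a[:, 1] - a[:, 0]).max()) if a.size else 0,
            }
            self._index_cache[chrom] = idx
        return idx

    def overlap_sums(self, chrom: str, starts, ends) -> np.ndarray:
        """Total overlapped bp (summed over fragments) per query window."""
        a = np.asarray(starts, dtype=np.int64)
        b = np.asarray(ends, dtype=np.int64)
        if np.any(b < a):
            raise ValueError("query windows must have end >= start")
        if self.count(chrom) == 0:
            return np.zeros(a.shape, dtype=np.int64)
        idx = self._index(chrom)

        def integral(points: np.ndarray, csum: np.ndarray) -> np.ndarray:
            # ∫_a^b #{p_i <= x} dx  for each (a, b)
            k1 = np.searchsorted(points, a, side="right")
            k2 = np.searchsorted(points, b, side="left")
            inner = csum[k2] - csum[k1]
            return k1 * (b - a) + k2 * b - k1 * b - inner

        return integral(idx["starts"], idx["cs_starts"]) - integral(idx["ends"], idx["cs_ends"])

    def window_coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over ``[start, end)`` as a length end-start array."""
        span = end - start
        cov = np.zeros(span + 1, dtype=np.float64)
        if self.count(chrom):
            idx = self._index(chrom)
            starts = idx["starts"]
            # only fragments with start in [start - max_len, end) can overlap
            lo = np.searchsorted(starts, start - idx["max_len"], side="left")
            hi = np.searchsorted(starts, end, side="left")
            s = np.clip(starts[lo:hi] - start, 0, span)
            e = np.clip(idx["ends_by_start"][lo:hi] - start, 0, span)
            keep = e > s
            np.add.at(cov, s[keep], 1.0)
            np.add.at(cov, e[keep], -1.0)
        return np.cumsum(cov)[:span]

    def midpoint_counts(self, chrom: str, starts, ends) -> np.ndarray:
        """Number of fragment midpoints per query window."""
        mids = np.sort(self.midpoints(chrom))
        a = np.asarray(starts, dtype=np.int64)
        b = np.asarray(ends, dtype=np.int64)
        return np.searchsorted(mids, b, side="left") - np.searchsorted(mids, a, side="left")

    # ---- construction helpers --------------------------------------------

    @classmethod
    def from_arrays(cls, chroms, starts, ends, stats=None) -> "FragmentSet":
        chroms = np.asarray(chroms)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out: dict[str, np.ndarray] = {}
        for c in dict.fromkeys(chroms.tolist()):  # preserve first-seen order
            m = chroms == c
            out[str(c)] = np.column_stack((starts[m], ends[m]))
        return cls(out, stats=stats)

    def deduplicated(self) -> "FragmentSet":
        """Remove exact-coordinate duplicate fragments."""
        return FragmentSet(
            {c: np.unique(a, axis=0) for c, a in self._intervals.items()},
            stats=dict(self.stats),
        )


def read_fragments(
    path: str | Path,
    format: str | None = None,
    assembly=None,
    dedup: bool = False,
    normalize_chrom: str | None = None,
) -> FragmentSet:
    """Read a fragment BED3 or a paired-end SAM/BAM into a FragmentSet.

    For alignment input only proper pairs are converted, one fragment per
    pair spanning leftmost start to rightmost end (the template). Records
    with end <= start are rejected and counted; records on chromosomes not
    in *assembly* (when given) are skipped and counted.
    """
    path = Path(path)
    if format is None:
        format = "SAM" if path.suffix.lower() in (".sam", ".bam", ".cram") else "BED"
    known = set(assembly.chrom_names) if assembly is not None else None
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    n_rejected = n_skipped = n_lines = 0

    if format == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                n_lines += 1
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 3:
                    raise ValueError(f"line {lineno}: fragment BED needs >= 3 columns")
                try:
                    chrom, s, e = fields[0], int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: malformed BED record") from exc
                if normalize_chrom:
                    chrom = normalize_chrom_name(chrom, normalize_chrom)
                if known is not None and chrom not in known:
                    n_skipped += 1
                    continue
                if e <= s:
                    n_rejected += 1
                    continue
                chroms.append(chrom)
                starts.append(s)
                ends.append(e)
    elif format == "SAM":
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or not read.is_proper_pair:
                    continue
                # count each template once, from the leftmost mate
                if read.template_length <= 0:
                    continue
                n_lines += 1
                chrom = read.reference_name
                if normalize_chrom:
                    chrom = normalize_chrom_name(chrom, normalize_chrom)
                if known is not None and chrom not in known:
                    n_skipped += 1
                    continue
                s = read.reference_start
                e = s + read.template_length
                if e <= s:
                    n_rejected += 1
                    continue
                chroms.append(chrom)
                starts.append(s)
                ends.append(e)
    else:
        raise ValueError(f"unknown fragment format {format!r}")

    stats = {"n_read": len(starts), "n_rejected": n_rejected, "n_skipped": n_skipped, "n_records": n_lines}
    logger.info("read_fragments(%s): %d fragments, %d rejected, %d skipped", path.name, *list(stats.values())[:3])
    fs = FragmentSet.from_arrays(np.array(chroms, dtype=object), starts, ends, stats=stats)
    return fs.deduplicated() if dedup else fs


def write_fragments(fragments: FragmentSet, path: str | Path) -> None:
    """Write canonical fragment BED3 (chromosomes in stored order)."""
    with open(path, "w") as fh:
        for chrom in fragments.chroms:
            a = fragments.intervals(chrom)
            for s, e in a:
                fh.write(f"{chrom}\t{s}\t{e}\n")
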