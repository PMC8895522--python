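"""Shared helpers: interval arithmetic, BH adjustment, seed derivation, logging.

Conventions used throughout the package:

* positions are 1-based in summary-statistic TSV files and converted to
  0-based half-open intervals internally (BED/BEDPE files are 0-based
  half-open on disk, as the formats require);
* all TSV files are tab-separated with a header row and ``.`` for missing;
* every source of randomness is an :class:`numpy.random.Generator` built
  from a single integer seed, with named child streams derived via
  :func:`child_seed` so individual generators can be re-run independently.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("loop2target")

MISSING = "."


class GenomicInterval(NamedTuple):
    """A 0-based half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or touching half-open intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # touching intervals merge for coverage
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_coverage(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered after merging."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def point_in_any(chrom: str, pos0: int, merged: Sequence[GenomicInterval]) -> bool:
    """Membership of a 0-based point in a merged, sorted interval list."""
    for iv in merged:
        if iv.chrom != chrom:
            continue
        if iv.start <= pos0 < iv.end:
            return True
    return False


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def child_seed(master: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from a single master integer.

    The child is a CRC32 mix of the stream name with the master seed so that
    each generator draws from its own reproducible stream and can be rerun
    in isolation.
    """
    h = zlib.crc32(name.encode("utf-8"))
    return int((int(master) * 1_000_003 + h) % (2**31 - 1))


def rng_for(master: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, name))


class JsonLineFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:  # noqa: D102
        payload = {
            "level": record.levelname,
            "logger": record.name,
            "msg": record.getMessage(),
        }
        return json.dumps(payload)


def setup_logging(json_lines: bool = False, level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        handler.setFormatter(JsonLineFormatter())
    else:
        handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    root = logging.getLogger("loop2target")
    root.handlers[:] = [handler]
    root.setLevel(level)
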