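"""Fragment-size distributions and in-silico size selection.

Implements the per-sample length histogram over a fixed bp window, the
short-fragment summary statistic P20_150 (proportion of fragments between
20 and 150 bp, both bounds inclusive), per-length log2 ratios against a
reference distribution, the per-length median distribution across samples,
and length-window fragment selection (including the strict >1,000 bp
"long DNA" preset).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .fragments import Fragments, as_fragments

#: Lower bound (inclusive) of the strict "long DNA" selection: length > 1,000 bp.
LONG_FRAGMENT_MIN = 1001


@dataclasses.dataclass
class SizeDistribution:
    """Histogram of fragment lengths over ``low..high`` bp (inclusive).

    Lengths outside the window land in the underflow/overflow buckets, which
    are excluded from ``density`` but retained so that long fragments stay
    countable.  ``total`` counts in-window fragments; ``total_all`` counts
    every fragment seen.
    """

    sample_id: str
    low: int
    high: int
    counts: np.ndarray
    underflow: int = 0
    overflow: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.high - self.low + 1:
            raise ValueError("counts length does not match the size window")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.low, self.high + 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def total_all(self) -> int:
        return self.total + self.underflow + self.overflow

    @property
    def density(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"length": self.lengths, "count": self.counts, "density": self.density})


def size_distribution(fragments, low: int = 20, high: int = 2000, sample_id: str | None = None) -> SizeDistribution:
    frags = as_fragments(fragments)
    if low < 1:
        raise ValueError("lower bound must be >= 1")
    if low > high:
        raise ValueError("lower bound exceeds upper bound")
    lens = frags.length
    in_range = (lens >= low) & (lens <= high)
    counts = np.bincount(lens[in_range] - low, minlength=high - low + 1)
    return SizeDistribution(
        sample_id=sample_id if sample_id is not None else frags.sample_id,
        low=low,
        high=high,
        counts=counts,
        underflow=int((lens < low).sum()),
        overflow=int((lens > high).sum()),
    )


def modal_length(dist: SizeDistribution) -> int:
    """Smallest length achieving the maximum density (ties break low)."""
    if dist.total == 0:
        raise ValueError("empty size distribution has no mode")
    return int(dist.low + np.argmax(dist.counts))


def p20_150(dist: SizeDistribution, denominator: str = "all") -> float:
    """Proportion of fragments between 20 and 150 bp, bounds inclusive.

    ``denominator`` is "all" (every passing fragment, including those outside
    the histogram window; the default) or "in_range".
    """
    if dist.total == 0:
        raise ValueError("empty size distribution")
    lo = max(20, dist.low)
    hi = min(150, dist.high)
    short = int(dist.counts[lo - dist.low : hi - dist.low + 1].sum()) if lo <= hi else 0
    denom = dist.total_all if denominator == "all" else dist.total
    return short / denom


def log2_ratio_to_reference(dist: SizeDistribution, ref: SizeDistribution, pseudocount: float = 1e-6) -> np.ndarray:
    """Per-length log2((density + eps) / (ref_density + eps))."""
    if (dist.low, dist.high) != (ref.low, ref.high):
        raise ValueError("size distributions cover different length ranges")
    if ref.total == 0:
        raise ValueError("reference distribution is empty")
    return np.log2((dist.density + pseudocount) / (ref.density + pseudocount))


def median_distribution(dists: list[SizeDistribution], sample_id: str = "median") -> SizeDistribution:
    """Per-length median of densities across samples, renormalised to sum 1.

    Returned as a pseudo-count histogram scaled to the mean total so density
    is well defined; only its ``density`` is meaningful downstream.
    """
    if not dists:
        raise ValueError("median of an empty list of distributions")
    ranges = {(d.low, d.high) for d in dists}
    if len(ranges) != 1:
        raise ValueError("size distributions cover different length ranges")
    med = np.median(np.stack([d.density for d in dists]), axis=0)
    total = med.sum()
    if total == 0:
        raise ValueError("median density is identically zero")
    scale = 1_000_000_000
    counts = np.rint(med / total * scale).astype(np.int64)
    return SizeDistribution(sample_id, dists[0].low, dists[0].high, counts)


def size_select(fragments, min_bp: int = 1, max_bp: int | None = None) -> Fragments:
    """Fragments with ``min_bp <= length <= max_bp`` (max unbounded if None)."""
    frags = as_fragments(fragments)
    if max_bp is not None and min_bp > max_bp:
        raise ValueError("min_bp exceeds max_bp")
    mask = frags.length >= min_bp
    if max_bp is not None:
        mask &= frags.length <= max_bp
    return frags.subset(mask)


def select_long(fragments) -> Fragments:
    """The strict long-DNA preset: fragments with length > 1,000 bp."""
    return size_select(fragments, min_bp=LONG_FRAGMENT_MIN)
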