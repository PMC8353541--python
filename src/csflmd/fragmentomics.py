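"""Fragment-length statistics for cell-free DNA origin determination.

cfDNA fragment sizes reflect nucleosomal protection: ~166 bp of DNA wraps a
single nucleosome, so plasma cfDNA piles up in a mono-nucleosomal peak near
166 bp while CSF cfDNA retains a larger di-nucleosomal fraction near twice
that. The peak ratio — fragments of 140-200 bp over fragments of 300-360 bp,
reported on the log2 scale — is therefore higher for plasma than for CSF and
flags blood contamination of a CSF sample (e.g. a traumatic lumbar puncture).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

PEAK1_WINDOW = (140, 200)  # mono-nucleosomal, inclusive on both ends
PEAK2_WINDOW = (300, 360)  # di-nucleosomal, inclusive on both ends
DEFAULT_CONTAMINATION_THRESHOLD = 2.8  # midpoint of typical CSF (2.16) and plasma (3.51) medians

__all__ = [
    "FragmentLengthProfile",
    "peak_counts",
    "log2_peak_ratio",
    "flag_contamination",
    "profile_from_lengths",
    "profile_from_histogram",
]


@dataclass
class FragmentLengthProfile:
    """Fragment-length histogram with nucleosomal peak-window counts."""

    histogram: Mapping[int, int]
    n_total: int
    peak1_count: int
    peak2_count: int
    log2_peak_ratio: float  # NaN when undefined

    @property
    def ratio_defined(self) -> bool:
        return self.peak1_count > 0 and self.peak2_count > 0

    def __post_init__(self) -> None:
        if self.peak1_count < 0 or self.peak2_count < 0:
            raise ValueError("peak counts must be non-negative")
        if self.peak1_count + self.peak2_count > self.n_total:
            raise ValueError("peak windows cannot contain more fragments than the total")


def peak_counts(lengths: Iterable[int]) -> tuple[int, int, int]:
    """Tally fragments in the mono- (140-200 bp) and di-nucleosomal (300-360 bp)
    windows; both windows are closed intervals. Returns (peak1, peak2, n_total)."""
    arr = np.asarray(list(lengths) if not isinstance(lengths, np.ndarray) else lengths)
    if arr.size == 0:
        raise ValueError("no fragment lengths supplied")
    if (arr < 1).any():
        raise ValueError("fragment lengths must be >= 1 bp")
    p1 = int(((arr >= PEAK1_WINDOW[0]) & (arr <= PEAK1_WINDOW[1])).sum())
    p2 = int(((arr >= PEAK2_WINDOW[0]) & (arr <= PEAK2_WINDOW[1])).sum())
    return p1, p2, int(arr.size)


def log2_peak_ratio(peak1_count: int, peak2_count: int) -> float:
    """log2 of the mono/di-nucleosomal peak-count ratio; NaN when either count
    is zero (flagged undefined rather than raising, so one degenerate sample
    does not abort a batch)."""
    if peak1_count < 0 or peak2_count < 0:
        raise ValueError("peak counts must be non-negative")
    if peak1_count == 0 or peak2_count == 0:
        return math.nan
    return math.log2(peak1_count / peak2_count)


def profile_from_lengths(lengths: Iterable[int]) -> FragmentLengthProfile:
    arr = np.asarray(list(lengths) if not isinstance(lengths, np.ndarray) else lengths, dtype=int)
    p1, p2, n = peak_counts(arr)
    vals, counts = np.unique(arr, return_counts=True)
    hist = {int(v): int(c) for v, c in zip(vals, counts)}
    return FragmentLengthProfile(hist, n, p1, p2, log2_peak_ratio(p1, p2))


def profile_from_histogram(histogram: Mapping[int, int]) -> FragmentLengthProfile:
    """Build a profile from a length -> count histogram (e.g. a two-column TSV)."""
    if not histogram:
        raise ValueError("empty histogram")
    p1 = p2 = n = 0
    for length, count in histogram.items():
        if length < 1 or count < 0:
            raise ValueError("histogram must have lengths >= 1 and counts >= 0")
        n += count
        if PEAK1_WINDOW[0] <= length <= PEAK1_WINDOW[1]:
            p1 += count
        elif PEAK2_WINDOW[0] <= length <= PEAK2_WINDOW[1]:
            p2 += count
    if n == 0:
        raise ValueError("histogram has zero total count")
    return FragmentLengthProfile(dict(histogram), n, p1, p2, log2_peak_ratio(p1, p2))


def flag_contamination(
    profile: FragmentLengthProfile, threshold: float = DEFAULT_CONTAMINATION_THRESHOLD
) -> str:
    """Classify a sample as 'csf_like' or 'plasma_contaminated' by its log2
    peak ratio; 'undefined' when a peak window is empty."""
    if not profile.ratio_defined:
        return "undefined"
    return "plasma_contaminated" if profile.log2_peak_ratio > threshold else "csf_like"
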