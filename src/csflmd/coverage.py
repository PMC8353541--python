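"""Bias-corrected, panel-normalized binned coverage.

Turns a fragment table (or raw bin counts) into log2 coverage ratios per 1 Mb
autosomal bin: fragments are assigned to the bin containing their midpoint
after a mapping-quality filter, counts are corrected for GC content and
mappability, normalized against a panel of reference (diploid) samples, and
median-recentered so a copy-neutral genome sits at log2 ratio 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import AUTOSOMES, GenomeBins

DEFAULT_MIN_MAPQ = 20
DEFAULT_MAPPABILITY_THRESHOLD = 0.9
DEFAULT_LOG2_CAP = (-3.0, 2.0)

__all__ = [
    "BinnedCoverage",
    "bin_fragments",
    "correct_gc_mappability",
    "normalize_to_panel",
    "panel_from_samples",
    "coverage_from_counts",
]


@dataclass
class BinnedCoverage:
    """Per-bin read counts and corrected log2 ratios.

    ``mask`` marks bins that survived all filters (usable track, mappability
    threshold, positive panel median); log2_ratio is NaN off-mask.
    """

    bins: GenomeBins
    raw_count: np.ndarray
    corrected: np.ndarray
    log2_ratio: np.ndarray
    mask: np.ndarray

    def masked_log2(self) -> np.ndarray:
        return self.log2_ratio[self.mask]

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.to_frame()
        df["raw_count"] = self.raw_count
        df["corrected"] = self.corrected
        df["log2_ratio"] = self.log2_ratio
        df["mask"] = self.mask
        return df


def _as_fragment_frame(fragments) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        df = fragments.copy()
        df.columns = [str(c).lower() for c in df.columns]
        missing = {"chrom", "start", "end", "mapq"} - set(df.columns)
        if missing:
            raise ValueError(f"fragment table missing columns: {sorted(missing)}")
        return df
    rows = list(fragments)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq"])


def bin_fragments(
    fragments,
    bins: GenomeBins,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[np.ndarray, dict[str, int]]:
    """Count fragments per bin by midpoint assignment.

    A fragment lands in the bin containing its midpoint (fragments may
    straddle a bin boundary; the midpoint rule is the convention of
    read-count CNA callers). Fragments with MAPQ below ``min_mapq`` or on a
    non-autosomal chromosome are discarded; the returned dict reports how many
    were dropped for each reason. Coordinates are 0-based half-open; a record
    with end <= start raises an error naming its line.
    """
    df = _as_fragment_frame(fragments)
    counts = np.zeros(len(bins), dtype=np.int64)
    discarded = {"low_mapq": 0, "non_autosome": 0}
    if len(df) == 0:
        return counts, discarded

    start = df["start"].to_numpy(dtype=np.int64)
    end = df["end"].to_numpy(dtype=np.int64)
    bad = np.nonzero(end <= start)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"malformed fragment at line {i + 1}: end <= start ({end[i]} <= {start[i]})")

    chrom = df["chrom"].astype(str).str.replace("^chr", "", regex=True)
    autosomal = chrom.isin(AUTOSOMES).to_numpy()
    discarded["non_autosome"] = int((~autosomal).sum())
    mapq_ok = df["mapq"].to_numpy() >= min_mapq
    discarded["low_mapq"] = int((autosomal & ~mapq_ok).sum())
    keep = autosomal & mapq_ok

    mid = (start + end) // 2
    chrom_arr = chrom.to_numpy()
    for c, sl in bins.chrom_slices():
        sel = keep & (chrom_arr == c)
        if not sel.any():
            continue
        edges = np.append(bins.start[sl], bins.end[sl.stop - 1])
        idx = np.searchsorted(edges, mid[sel], side="right") - 1
        in_range = (idx >= 0) & (idx < sl.stop - sl.start)
        counts[sl.start:sl.stop] += np.bincount(idx[in_range], minlength=sl.stop - sl.start)
    return counts, discarded


def correct_gc_mappability(
    raw_counts: np.ndarray,
    bins: GenomeBins,
    mappability_threshold: float = DEFAULT_MAPPABILITY_THRESHOLD,
    n_gc_bins: int = 10,
    min_usable_bins: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove GC and mappability bias from raw bin counts.

    Counts are first scaled by mappability and bin width, then divided by a
    smooth GC trend estimated as the median count within GC deciles,
    linearly interpolated between decile centers. The output is
    median-centered so a copy-neutral bin sits at 1. Returns
    ``(corrected, mask)``; masked-out bins (low mappability, unusable) are NaN.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.shape != (len(bins),):
        raise ValueError("raw_counts length does not match bins")
    if np.nansum(raw) == 0:
        raise ValueError("all bin counts are zero")
    mask = bins.usable & (bins.mappability >= mappability_threshold)
    if mask.sum() < min_usable_bins:
        raise ValueError(
            f"insufficient data for bias fit: {int(mask.sum())} usable bins < {min_usable_bins}"
        )

    width_scale = bins.width / bins.bin_size
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = raw / (bins.mappability * width_scale)

    # GC trend: median rate within GC quantile bins, then a smooth quadratic
    # through the binned medians (the bias curve is unimodal; a straight
    # interpolation undercorrects the sparse GC extremes).
    gc_in = bins.gc[mask]
    rate_in = rate[mask]
    edges = np.unique(np.quantile(gc_in, np.linspace(0, 1, n_gc_bins + 1)))
    which = np.clip(np.searchsorted(edges, gc_in, side="right") - 1, 0, max(len(edges) - 2, 0))
    centers, medians = [], []
    for k in range(max(len(edges) - 1, 1)):
        sel = which == k
        if sel.sum() >= 3:
            centers.append(float(np.median(gc_in[sel])))
            medians.append(float(np.median(rate_in[sel])))
    if len(centers) >= 4:
        coef = np.polyfit(centers, medians, deg=2)
        trend = np.polyval(coef, bins.gc)
        trend = np.maximum(trend, 0.05 * float(np.median(rate_in)))
    elif len(centers) >= 2:
        trend = np.interp(bins.gc, centers, medians)
    else:
        trend = np.full(len(bins), float(np.median(rate_in)))

    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = rate / trend
    mask = mask & np.isfinite(corrected) & (trend > 0)
    med = float(np.median(corrected[mask]))
    if med <= 0:
        raise ValueError("median corrected coverage is non-positive")
    corrected = corrected / med
    corrected[~mask] = np.nan
    return corrected, mask


def normalize_to_panel(
    corrected: np.ndarray,
    panel_median: np.ndarray,
    mask: np.ndarray,
    cap: tuple[float, float] = DEFAULT_LOG2_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """log2 ratio of corrected coverage to the panel-of-normals bin medians.

    Bins with a non-positive or missing panel median are masked out. Ratios
    are re-centered so the genome-wide median log2 ratio is 0 and capped to
    ``cap`` (deep deletions and high amplifications saturate).
    """
    corrected = np.asarray(corrected, dtype=float)
    panel = np.asarray(panel_median, dtype=float)
    if corrected.shape != panel.shape:
        raise ValueError(
            f"dimension mismatch: {corrected.shape[0]} bins vs {panel.shape[0]} panel medians"
        )
    mask = np.asarray(mask, dtype=bool) & np.isfinite(panel) & (panel > 0) & np.isfinite(corrected)
    log2r = np.full(corrected.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r[mask] = np.log2(corrected[mask] / panel[mask])
    mask = mask & np.isfinite(log2r)
    log2r[mask] -= np.median(log2r[mask])
    log2r[mask] = np.clip(log2r[mask], cap[0], cap[1])
    log2r[~mask] = np.nan
    return log2r, mask


def panel_from_samples(corrected_list: Sequence[np.ndarray]) -> np.ndarray:
    """Per-bin median corrected coverage over a panel of reference samples."""
    if not corrected_list:
        raise ValueError("empty panel")
    stack = np.vstack([np.asarray(c, dtype=float) for c in corrected_list])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(stack, axis=0)


def coverage_from_counts(
    raw_counts: np.ndarray,
    bins: GenomeBins,
    panel_median: np.ndarray | None = None,
    mappability_threshold: float = DEFAULT_MAPPABILITY_THRESHOLD,
    cap: tuple[float, float] = DEFAULT_LOG2_CAP,
) -> BinnedCoverage:
    """Full correction chain: raw counts -> corrected ratios -> panel log2 ratios.

    Without a panel, the corrected ratios themselves (median 1 by
    construction) stand in for the panel, i.e. log2 of the median-centered
    corrected coverage.
    """
    corrected, mask = correct_gc_mappability(
        raw_counts, bins, mappability_threshold=mappability_threshold
    )
    panel = np.ones(len(bins)) if panel_median is None else panel_median
    log2r, mask = normalize_to_panel(corrected, panel, mask, cap=cap)
    return BinnedCoverage(
        bins=bins,
        raw_count=np.asarray(raw_counts, dtype=np.int64),
        corrected=corrected,
        log2_ratio=log2r,
        mask=mask,
    )
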