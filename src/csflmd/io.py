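"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are 0-based half-open on disk except WIG, which is
1-based per the format definition.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .diagnostics import SampleRecord
from .simulate import GenomeBins

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "patient_id",
    "group",
    "route",
    "cytology",
    "cfdna_call",
    "cancer_fraction",
    "concentration",
    "rbc_count",
]


def write_fragments_tsv(path, fragments: pd.DataFrame) -> None:
    """BED3+MAPQ fragment table: chrom, start, end, mapq; no header."""
    fragments[["chrom", "start", "end", "mapq"]].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "mapq"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bedgraph(path, bins: GenomeBins, values: np.ndarray) -> None:
    pd.DataFrame(
        {"chrom": bins.chrom, "start": bins.start, "end": bins.end, "value": values}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_wig(path, bins: GenomeBins, values: np.ndarray) -> None:
    """Fixed-step WIG (1-based starts), one block per chromosome."""
    with open(path, "w") as fh:
        for chrom, sl in bins.chrom_slices():
            fh.write(
                f"fixedStep chrom={chrom} start={int(bins.start[sl.start]) + 1} "
                f"step={bins.bin_size} span={bins.bin_size}\n"
            )
            for v in values[sl]:
                fh.write(f"{v}\n")


def read_wig(path) -> pd.DataFrame:
    """Read a fixed-step WIG into (chrom, start, value) with 0-based starts."""
    rows = []
    chrom, pos, step = None, 0, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1
                step = int(fields["step"])
            else:
                rows.append((chrom, pos, float(line)))
                pos += step
    return pd.DataFrame(rows, columns=["chrom", "start", "value"])


def write_bins_tsv(path, bins: GenomeBins) -> None:
    bins.to_frame().to_csv(path, sep="\t", index=False)


def read_bins_tsv(path, bin_size: int | None = None) -> GenomeBins:
    df = pd.read_csv(path, sep="\t")
    if bin_size is None:
        bin_size = int((df["end"] - df["start"]).max())
    return GenomeBins(
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        gc=df["gc"].to_numpy(dtype=float),
        mappability=df["mappability"].to_numpy(dtype=float),
        usable=df["usable"].to_numpy(dtype=bool),
        bin_size=bin_size,
    )


def write_coverage_tsv(path, cov) -> None:
    cov.to_frame().to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path):
    """Read a coverage table written by ``write_coverage_tsv`` back into a
    BinnedCoverage."""
    from .coverage import BinnedCoverage

    df = pd.read_csv(path, sep="\t")
    bins = GenomeBins(
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        gc=df["gc"].to_numpy(dtype=float),
        mappability=df["mappability"].to_numpy(dtype=float),
        usable=df["usable"].to_numpy(dtype=bool),
        bin_size=int((df["end"] - df["start"]).max()),
    )
    return BinnedCoverage(
        bins=bins,
        raw_count=df["raw_count"].to_numpy(dtype=np.int64),
        corrected=df["corrected"].to_numpy(dtype=float),
        log2_ratio=df["log2_ratio"].to_numpy(dtype=float),
        mask=df["mask"].to_numpy(dtype=bool),
    )


def write_panel_tsv(path, bins: GenomeBins, median: np.ndarray) -> None:
    pd.DataFrame(
        {"chrom": bins.chrom, "start": bins.start, "end": bins.end, "median": median}
    ).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_seg(path, sample_id: str, segments: pd.DataFrame) -> None:
    """SEG format: sample, chrom, start, end, num marks, segment mean."""
    out = pd.DataFrame(
        {
            "ID": sample_id,
            "chrom": segments["chrom"],
            "loc.start": segments["start"],
            "loc.end": segments["end"],
            "num.mark": segments["num_bins"],
            "seg.mean": segments["seg_mean"].round(6),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_sample_sheet(path, records: Iterable[SampleRecord]) -> None:
    rows = [{c: getattr(r, c) for c in SAMPLE_SHEET_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in SAMPLE_SHEET_COLUMNS:
            if c in df.columns:
                v = row[c]
                kwargs[c] = None if pd.isna(v) else v
        for c in ("sample_id", "patient_id", "group", "route", "cytology", "cfdna_call"):
            if kwargs.get(c) is not None:
                kwargs[c] = str(kwargs[c])
        records.append(SampleRecord(**kwargs))
    return records


def fragment_lengths_to_histogram_tsv(path, lengths: np.ndarray) -> None:
    vals, counts = np.unique(np.asarray(lengths, dtype=int), return_counts=True)
    pd.DataFrame({"length": vals, "count": counts}).to_csv(path, sep="\t", index=False)


def read_histogram_tsv(path) -> dict[int, int]:
    df = pd.read_csv(path, sep="\t")
    return {int(r["length"]): int(r["count"]) for _, r in df.iterrows()}
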