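"""Synthetic ULP-WGS cohort generator.

Emulates the data a CSF cfDNA leptomeningeal-disease analysis consumes,
without any sequencing: 1 Mb binned read counts over autosomes 1-22 at
ultra-low-pass depth (~0.1X) with GC/mappability bias and segmental copy-number
alterations mixed in at a controllable tumor fraction; bimodal nucleosomal
fragment-length distributions that differ between CSF and plasma; and cohorts
of samples (LMD / PT / PTACSF) with cytology results drawn at a stated
sensitivity, cfDNA concentrations, and red-blood-cell counts.

Bin counts are negative-binomial: ULP-WGS coverage is overdispersed relative
to Poisson, and the dispersion parameter recovers the Poisson limit at 0.
Every stochastic operation is reproducible given its seed; cohort generation
derives per-sample sub-seeds from a master stream (see ``simulate_cohort``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .diagnostics import SampleRecord

AUTOSOMES = tuple(str(i) for i in range(1, 23))
DEFAULT_BIN_SIZE = 1_000_000
MONO_NUCLEOSOME_BP = 166  # DNA wrapped around a single nucleosome
DI_NUCLEOSOME_BP = 2 * MONO_NUCLEOSOME_BP

# Mono-nucleosome mixture weights calibrated so that the log2 peak ratio
# (140-200 bp count over 300-360 bp count) of simulated samples matches
# typical CSF (~2.16) and plasma (~3.51) medians, accounting for the mass of
# each Gaussian component captured by its peak window.
CSF_MONO_WEIGHT = 0.808
PLASMA_MONO_WEIGHT = 0.915
MONO_SD = 10.0
DI_SD = 16.0

__all__ = [
    "GenomeBins",
    "CnaSegmentSpec",
    "SimSampleConfig",
    "CohortConfig",
    "SimulatedSample",
    "make_genome_bins",
    "uniform_genome",
    "gc_bias",
    "expected_bin_means",
    "simulate_binned_counts",
    "simulate_fragment_lengths",
    "expected_peak1_share",
    "random_cna_profile",
    "simulate_cohort",
]


def normalize_chrom(label: object) -> str:
    """Canonical autosome label ('1'..'22'); 'chr' prefixes are stripped.
    Anything else (X, Y, MT, ...) is rejected."""
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s not in AUTOSOMES:
        raise ValueError(f"non-autosomal chromosome label {label!r}: only 1-22 are supported")
    return s


@dataclass
class GenomeBins:
    """Fixed-width genomic bins over autosomes with GC/mappability tracks.

    Coordinates are 0-based half-open; bins tile each chromosome completely,
    every bin is bin_size wide except possibly the last per chromosome.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    mappability: np.ndarray
    usable: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def width(self) -> np.ndarray:
        return self.end - self.start

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "gc": self.gc,
                "mappability": self.mappability,
                "usable": self.usable,
            }
        )

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous index slice per chromosome, in stored order."""
        out = []
        i = 0
        while i < len(self):
            c = self.chrom[i]
            j = i
            while j < len(self) and self.chrom[j] == c:
                j += 1
            out.append((str(c), slice(i, j)))
            i = j
        return out


@dataclass(frozen=True)
class CnaSegmentSpec:
    """One somatic copy-number segment of the simulated tumor genome."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not (0 <= self.copy_number <= 5):
            raise ValueError(f"copy_number must be in [0, 5], got {self.copy_number}")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


@dataclass
class SimSampleConfig:
    """Parameters for one simulated sample's coverage and fragment lengths."""

    tumor_fraction: float = 0.0
    mean_depth: float = 0.1
    cna_profile: Sequence[CnaSegmentSpec] = field(default_factory=list)
    origin: str = "CSF"
    plasma_contamination: float = 0.0
    nb_dispersion: float = 0.01
    gc_bias_strength: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must be in [0, 1]")
        if not (0.0 <= self.plasma_contamination <= 1.0):
            raise ValueError("plasma_contamination must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.origin not in ("CSF", "plasma"):
            raise ValueError("origin must be 'CSF' or 'plasma'")


@dataclass
class CohortConfig:
    """Study-design parameters for a simulated cohort.

    Defaults mirror the diagnostic-study composition this generator emulates:
    43 LMD samples, 5 parenchymal-tumor (PT) samples, 3 samples from patients
    whose parenchymal tumor abuts a CSF space (PTACSF); cytology sensitivity
    0.72 for LMD samples. Tumor fractions of LMD and PTACSF samples are
    logit-normal, calibrated to a median near 59% with IQR ~44-85%.
    """

    n_lmd_samples: int = 43
    n_pt_samples: int = 5
    n_ptacsf_samples: int = 3
    cytology_sensitivity: float = 0.72
    tf_logit_loc: float = 0.36
    tf_logit_scale: float = 1.48
    lumbar_fraction: float = 0.7
    mean_depth: float = 0.1
    nb_dispersion: float = 0.01
    n_fragments: int = 50_000
    frac_genome_altered: float = 0.25
    contamination_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lmd_samples, self.n_pt_samples, self.n_ptacsf_samples) < 0:
            raise ValueError("sample counts must be non-negative")
        if not (0.0 <= self.cytology_sensitivity <= 1.0):
            raise ValueError("cytology_sensitivity must be in [0, 1]")


@dataclass
class SimulatedSample:
    """One simulated sample: its clinical record plus attached raw data."""

    record: SampleRecord
    true_tumor_fraction: float
    cna_profile: list[CnaSegmentSpec]
    raw_counts: np.ndarray
    fragment_lengths: np.ndarray
    plasma_contamination: float = 0.0


def uniform_genome(n_chroms: int = 22, chrom_length: int = 100_000_000) -> dict[str, int]:
    """A simple synthetic genome: ``n_chroms`` equal-length autosomes."""
    if not (1 <= n_chroms <= 22):
        raise ValueError("n_chroms must be in [1, 22]")
    return {str(i): chrom_length for i in range(1, n_chroms + 1)}


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if len(x) < 2 or window <= 1:
        return x
    w = min(window, len(x))
    kernel = np.ones(w) / w
    pad = np.pad(x, (w, w), mode="reflect")
    return np.convolve(pad, kernel, mode="same")[w:-w]


def make_genome_bins(
    chrom_lengths: Mapping[object, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    mappability_threshold: float = 0.9,
    seed: int = 0,
) -> GenomeBins:
    """Tile autosomes into fixed-width bins with synthetic GC and mappability.

    GC per bin is a smooth, spatially autocorrelated track in [0.3, 0.6]
    (moving-average-filtered noise, as real isochore structure is locally
    correlated); mappability lies in [0.7, 1.0] with most bins near 1. A bin
    is usable when its mappability reaches ``mappability_threshold``.
    """
    if not chrom_lengths:
        raise ValueError("chrom_lengths is empty")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    items = []
    for label, length in chrom_lengths.items():
        c = normalize_chrom(label)
        if length <= 0:
            raise ValueError(f"chromosome {label!r} has non-positive length")
        items.append((c, int(length)))
    items.sort(key=lambda t: int(t[0]))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    chroms, starts, ends, gcs, maps = [], [], [], [], []
    for c, length in items:
        edges = list(range(0, length, bin_size)) + [length]
        n = len(edges) - 1
        chroms.extend([c] * n)
        starts.extend(edges[:-1])
        ends.extend(edges[1:])
        # smooth GC in [0.3, 0.6]
        raw = _smooth(rng.standard_normal(n), window=10)
        s = np.clip(raw / (3.0 * max(raw.std(), 1e-9)), -1.0, 1.0) if n > 1 else np.zeros(n)
        gcs.extend(0.45 + 0.15 * s)
        # mappability in [0.7, 1.0], most bins high
        u = np.clip(_smooth(rng.uniform(0, 1, n), window=5), 0.0, 1.0)
        maps.extend(1.0 - 0.3 * u**4)

    gc = np.clip(np.asarray(gcs), 0.3, 0.6)
    mp = np.clip(np.asarray(maps), 0.7, 1.0)
    return GenomeBins(
        chrom=np.asarray(chroms, dtype=object),
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        gc=gc,
        mappability=mp,
        usable=mp >= mappability_threshold,
        bin_size=bin_size,
    )


def gc_bias(gc: np.ndarray, strength: float = 8.0) -> np.ndarray:
    """Smooth unimodal multiplicative GC bias: quadratic with peak efficiency
    at GC = 0.45, floored at 0.05. strength = 0 disables the bias."""
    return np.maximum(1.0 - strength * (np.asarray(gc) - 0.45) ** 2, 0.05)


def _copy_number_per_bin(bins: GenomeBins, profile: Sequence[CnaSegmentSpec]) -> np.ndarray:
    cn = np.full(len(bins), 2.0)
    for seg in profile:
        if not (0 <= seg.copy_number <= 5):
            raise ValueError("segment copy_number outside [0, 5]")
        mid = (bins.start + bins.end) // 2
        sel = (bins.chrom == seg.chrom) & (mid >= seg.start) & (mid < seg.end)
        cn[sel] = seg.copy_number
    return cn


def expected_bin_means(bins: GenomeBins, cfg: SimSampleConfig) -> np.ndarray:
    """Expected read count per bin under the tumor/normal mixture:
    depth_scale * gc_bias * mappability * (tf*c + (1-tf)*2)/2."""
    tf = cfg.tumor_fraction
    cn = _copy_number_per_bin(bins, cfg.cna_profile)
    mixture = (tf * cn + (1.0 - tf) * 2.0) / 2.0
    depth_scale = cfg.mean_depth * bins.width / MONO_NUCLEOSOME_BP
    return depth_scale * gc_bias(bins.gc, cfg.gc_bias_strength) * bins.mappability * mixture


def simulate_binned_counts(bins: GenomeBins, cfg: SimSampleConfig) -> np.ndarray:
    """Draw negative-binomial bin counts around the mixture means.

    Variance is mu * (1 + dispersion * mu); dispersion -> 0 recovers Poisson.
    Deterministic given cfg.seed.
    """
    mu = expected_bin_means(bins, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    if cfg.nb_dispersion <= 0:
        return rng.poisson(mu).astype(np.int64)
    size = 1.0 / cfg.nb_dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(np.int64)


def _mono_weight(cfg: SimSampleConfig) -> float:
    if cfg.origin == "plasma":
        return PLASMA_MONO_WEIGHT
    p = cfg.plasma_contamination
    return (1.0 - p) * CSF_MONO_WEIGHT + p * PLASMA_MONO_WEIGHT


def simulate_fragment_lengths(cfg: SimSampleConfig, n_fragments: int) -> np.ndarray:
    """Draw integer fragment lengths from the two-component nucleosomal mixture.

    Discretized Gaussians centered at 166 bp (mono-nucleosome) and 332 bp
    (di-nucleosome). Plasma puts more weight on the mono-nucleosomal peak than
    CSF; a CSF sample with plasma_contamination p draws from the
    (1-p)*CSF + p*plasma mixture. Deterministic given cfg.seed.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    w = _mono_weight(cfg)
    is_mono = rng.random(n_fragments) < w
    lengths = np.where(
        is_mono,
        rng.normal(MONO_NUCLEOSOME_BP, MONO_SD, n_fragments),
        rng.normal(DI_NUCLEOSOME_BP, DI_SD, n_fragments),
    )
    return np.maximum(np.rint(lengths).astype(np.int64), 1)


def expected_peak1_share(
    plasma_contamination: float,
    csf_mono_weight: float = CSF_MONO_WEIGHT,
    plasma_mono_weight: float = PLASMA_MONO_WEIGHT,
) -> float:
    """Expected fraction of fragments landing in the 140-200 bp window, as a
    function of the plasma contamination fraction of a CSF sample. Strictly
    increasing in the contamination fraction whenever plasma weighs the
    mono-nucleosomal peak more heavily than CSF."""
    p = plasma_contamination
    w = (1.0 - p) * csf_mono_weight + p * plasma_mono_weight
    capture_mono = norm.cdf(200.5, MONO_NUCLEOSOME_BP, MONO_SD) - norm.cdf(
        139.5, MONO_NUCLEOSOME_BP, MONO_SD
    )
    capture_di_in_p1 = norm.cdf(200.5, DI_NUCLEOSOME_BP, DI_SD) - norm.cdf(
        139.5, DI_NUCLEOSOME_BP, DI_SD
    )
    return float(w * capture_mono + (1.0 - w) * capture_di_in_p1)


def random_cna_profile(
    bins: GenomeBins,
    rng: np.random.Generator,
    frac_genome_altered: float = 0.25,
    seg_bins: tuple[int, int] = (20, 80),
    copies: Sequence[int] = (1, 3, 4),
) -> list[CnaSegmentSpec]:
    """Draw non-overlapping segmental alterations covering roughly the target
    fraction of the genome, with segment lengths between seg_bins bins."""
    if not (0.0 <= frac_genome_altered < 1.0):
        raise ValueError("frac_genome_altered must be in [0, 1)")
    n = len(bins)
    altered = np.zeros(n, dtype=bool)
    target = frac_genome_altered * n
    slices = bins.chrom_slices()
    segments: list[CnaSegmentSpec] = []
    for _ in range(1000):
        if altered.sum() >= target:
            break
        chrom, sl = slices[rng.integers(len(slices))]
        lo, hi = sl.start, sl.stop
        max_len = min(seg_bins[1], hi - lo)
        if max_len < 1:
            continue
        length = int(rng.integers(min(seg_bins[0], max_len), max_len + 1))
        start_bin = int(rng.integers(lo, hi - length + 1))
        idx = slice(start_bin, start_bin + length)
        if altered[idx].any():
            continue
        altered[idx] = True
        cn = int(rng.choice(np.asarray(copies)))
        segments.append(
            CnaSegmentSpec(chrom, int(bins.start[idx.start]), int(bins.end[idx.stop - 1]), cn)
        )
    return segments


def _logit_normal_tf(rng: np.random.Generator, loc: float, scale: float) -> float:
    z = rng.normal(loc, scale)
    return float(1.0 / (1.0 + math.exp(-z)))


# cfDNA concentration (ng/uL) log-normal parameters per group, calibrated to
# typical medians/IQRs: LMD ~0.804 (0.201-1.29), PTACSF ~0.0725 (0.0362-1.14),
# PT ~0.0234 (0.0192-0.0312).
_CONC_PARAMS = {
    "LMD": (math.log(0.804), 1.38),
    "PTACSF": (math.log(0.0725), 2.56),
    "PT": (math.log(0.0234), 0.36),
}


def simulate_cohort(cohort: CohortConfig, bins: GenomeBins) -> list[SimulatedSample]:
    """Generate a cohort of simulated samples with attached raw data.

    LMD and PTACSF samples receive a tumor fraction from the configured
    logit-normal distribution (tumor DNA reaches the CSF in both; only the
    group label differs); PT samples have tumor fraction 0. Cytology is
    positive with probability ``cytology_sensitivity`` for LMD samples and
    negative for PT/PTACSF. Per-sample sub-seeds are drawn as 31-bit integers
    from a master generator seeded by ``cohort.seed``, so each sample's data
    depend only on the cohort seed and its index.
    """
    master = np.random.default_rng(np.random.SeedSequence([int(cohort.seed), 99]))
    groups = (
        ["LMD"] * cohort.n_lmd_samples
        + ["PT"] * cohort.n_pt_samples
        + ["PTACSF"] * cohort.n_ptacsf_samples
    )
    samples: list[SimulatedSample] = []
    for i, group in enumerate(groups):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(np.random.SeedSequence([sub_seed, 2]))
        if group == "PT":
            tf = 0.0
            profile: list[CnaSegmentSpec] = []
        else:
            tf = _logit_normal_tf(rng, cohort.tf_logit_loc, cohort.tf_logit_scale)
            profile = random_cna_profile(bins, rng, cohort.frac_genome_altered)
        contaminated = group != "PT" and rng.random() < cohort.contamination_rate
        contamination = float(rng.uniform(0.3, 0.7)) if contaminated else 0.0
        cfg = SimSampleConfig(
            tumor_fraction=tf,
            mean_depth=cohort.mean_depth,
            cna_profile=profile,
            origin="CSF",
            plasma_contamination=contamination,
            nb_dispersion=cohort.nb_dispersion,
            seed=sub_seed,
        )
        counts = simulate_binned_counts(bins, cfg)
        lengths = simulate_fragment_lengths(cfg, cohort.n_fragments)
        if group == "LMD":
            cytology = "positive" if rng.random() < cohort.cytology_sensitivity else "negative"
        else:
            cytology = "negative"
        mu, sigma = _CONC_PARAMS[group]
        concentration = float(np.exp(rng.normal(mu, sigma)))
        rbc = float(np.exp(rng.normal(math.log(2000.0), 0.5))) if contaminated else float(
            np.exp(rng.normal(math.log(5.0), 1.0))
        )
        record = SampleRecord(
            sample_id=f"SIM-{i:03d}",
            patient_id=f"P{i:03d}",
            group=group,
            route="lumbar" if rng.random() < cohort.lumbar_fraction else "shunt",
            cytology=cytology,
            concentration=concentration,
            rbc_count=rbc,
        )
        samples.append(
            SimulatedSample(
                record=record,
                true_tumor_fraction=tf,
                cna_profile=profile,
                raw_counts=counts,
                fragment_lengths=lengths,
                plasma_contamination=contamination,
            )
        )
    return samples
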