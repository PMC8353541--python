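"""Tumor-fraction inference from binned log2 coverage ratios.

An "ichorCNA-style" copy-number hidden Markov model over a tumor/normal
mixture: the sample is modeled as a fraction ``tf`` of tumor DNA with integer
copy number c in {0..5} per segment mixed with (1 - tf) diploid normal DNA,
so a bin with tumor copy number c has expected log2 ratio
log2((tf*c + (1-tf)*2) / 2). Emissions are Gaussian around these tied means;
transitions are homogeneous with a high self-transition probability (segments
are long relative to 1 Mb bins); chromosomes are independent chains. The
tumor fraction is estimated by profile likelihood over a grid, the copy-number
path by Viterbi decoding, and a sample is called positive for leptomeningeal
disease when a meaningfully nonzero tumor fraction beats the diploid model by
a likelihood margin.

This is a deliberate simplification of full ichorCNA: no subclonal states and
tumor ploidy fixed at 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import BinnedCoverage

COPY_STATES = np.arange(6)
# State preference for exact likelihood ties: diploid first, then lower copies
# (a conservative, null-leaning decode).
_STATE_PREFERENCE = np.array([2, 0, 1, 3, 4, 5])

DEFAULT_TF_GRID = tuple([0.0, 0.03, 0.05] + [round(0.10 + 0.05 * k, 2) for k in range(18)])
DEFAULT_TF_MIN = 0.03
DEFAULT_DELTA_LOGLIK = 2.0

__all__ = [
    "HmmParams",
    "TumorFractionEstimate",
    "expected_log2_ratio",
    "hmm_loglik",
    "viterbi_path",
    "viterbi_segments",
    "estimate_tumor_fraction",
    "classify_lmd",
    "DEFAULT_TF_GRID",
]


@dataclass
class HmmParams:
    """Parameters of the 6-state copy-number HMM."""

    tf: float
    sigma: float
    p_stay: float = 0.999
    pi: np.ndarray | None = None  # uniform when None
    floor_log2: float = -3.0
    copy_states: np.ndarray = field(default_factory=lambda: COPY_STATES.copy())

    def __post_init__(self) -> None:
        if not (0.0 <= self.tf <= 1.0):
            raise ValueError("tf must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 < self.p_stay < 1.0):
            raise ValueError("p_stay must be in (0, 1)")
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)
            if self.pi.shape != (len(self.copy_states),) or not math.isclose(
                float(self.pi.sum()), 1.0, rel_tol=1e-9
            ):
                raise ValueError("pi must be a distribution over the copy states")

    @property
    def n_states(self) -> int:
        return len(self.copy_states)

    def log_pi(self) -> np.ndarray:
        if self.pi is None:
            return np.full(self.n_states, -math.log(self.n_states))
        with np.errstate(divide="ignore"):
            return np.log(self.pi)

    def state_means(self) -> np.ndarray:
        return expected_log2_ratio(self.copy_states, self.tf, self.floor_log2)


def expected_log2_ratio(copy_number, tf: float, floor_log2: float = -3.0):
    """Expected log2 coverage ratio of a bin with tumor copy number c at
    tumor fraction tf: log2((tf*c + (1-tf)*2)/2), floored at ``floor_log2``
    (a homozygous deletion at tf=1 would otherwise be -inf)."""
    c = np.asarray(copy_number, dtype=float)
    if ((c < 0) | (c > 5)).any():
        raise ValueError("copy_number must be in [0, 5]")
    if not (0.0 <= tf <= 1.0):
        raise ValueError("tf must be in [0, 1]")
    mix = (tf * c + (1.0 - tf) * 2.0) / 2.0
    with np.errstate(divide="ignore"):
        out = np.maximum(np.log2(mix), floor_log2)
    return float(out) if np.isscalar(copy_number) else out


def _emission_logpdf(x: np.ndarray, means: np.ndarray, sigma: float) -> np.ndarray:
    const = -0.5 * math.log(2.0 * math.pi) - math.log(sigma)
    z = (x[:, None] - means[None, :]) / sigma
    return const - 0.5 * z * z


def _forward_chain(emis: np.ndarray, log_pi: np.ndarray, p_stay: float) -> float:
    """Exact forward log-likelihood of one chain.

    The transition matrix has p_stay on the diagonal and q = (1-p_stay)/(K-1)
    elsewhere, so the incoming mass at state j is q*sum(alpha) + (p-q)*alpha_j,
    evaluated in shifted log space for stability.
    """
    n, k = emis.shape
    q = (1.0 - p_stay) / (k - 1)
    alpha = log_pi + emis[0]
    for t in range(1, n):
        m = alpha.max()
        a = np.exp(alpha - m)
        alpha = emis[t] + m + np.log(q * a.sum() + (p_stay - q) * a)
    m = alpha.max()
    return float(m + math.log(np.exp(alpha - m).sum()))


def _viterbi_chain(emis: np.ndarray, log_pi: np.ndarray, p_stay: float) -> np.ndarray:
    """Most probable state path of one chain, ties broken toward copy 2 then
    lower copies."""
    n, k = emis.shape
    log_p = math.log(p_stay)
    log_q = math.log((1.0 - p_stay) / (k - 1))
    pref = _STATE_PREFERENCE[_STATE_PREFERENCE < k]
    delta = log_pi + emis[0]
    back = np.zeros((n, k), dtype=np.int8)
    for t in range(1, n):
        scores = delta[:, None] + np.full((k, k), log_q)
        np.fill_diagonal(scores, delta + log_p)
        best = scores.max(axis=0)
        eligible = scores == best[None, :]
        first = np.argmax(eligible[pref, :], axis=0)
        back[t] = pref[first]
        delta = best + emis[t]
    path = np.empty(n, dtype=np.int64)
    best = delta.max()
    path[-1] = pref[np.argmax(delta[pref] == best)]
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _chains(x: np.ndarray, chrom: np.ndarray | None) -> list[np.ndarray]:
    """Split bin indices into per-chromosome chains (order preserved)."""
    if chrom is None:
        return [np.arange(len(x))]
    chrom = np.asarray(chrom)
    out, i = [], 0
    while i < len(chrom):
        j = i
        while j < len(chrom) and chrom[j] == chrom[i]:
            j += 1
        out.append(np.arange(i, j))
        i = j
    return out


def _prepare(x, mask):
    x = np.asarray(x, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        return x, mask
    return x, np.isfinite(x)


def hmm_loglik(
    log2_ratios, params: HmmParams, chrom=None, mask=None
) -> float:
    """Exact forward log-likelihood, summed over per-chromosome chains.

    Masked-out bins are skipped without breaking chain adjacency: one
    transition step applies across a masked gap regardless of its width.
    """
    x, m = _prepare(log2_ratios, mask)
    if chrom is not None:
        chrom = np.asarray(chrom)[m]
    x = x[m]
    if x.size == 0:
        raise ValueError("all bins are masked out")
    means = params.state_means()
    log_pi = params.log_pi()
    total = 0.0
    for idx in _chains(x, chrom):
        emis = _emission_logpdf(x[idx], means, params.sigma)
        total += _forward_chain(emis, log_pi, params.p_stay)
    return total


def viterbi_path(log2_ratios, params: HmmParams, chrom=None, mask=None) -> np.ndarray:
    """Most probable copy-number path over the masked-in bins (per-chromosome
    chains decoded independently). Returns copy numbers, one per masked bin."""
    x, m = _prepare(log2_ratios, mask)
    if chrom is not None:
        chrom = np.asarray(chrom)[m]
    x = x[m]
    if x.size == 0:
        raise ValueError("all bins are masked out")
    means = params.state_means()
    log_pi = params.log_pi()
    states = np.empty(len(x), dtype=np.int64)
    for idx in _chains(x, chrom):
        emis = _emission_logpdf(x[idx], means, params.sigma)
        states[idx] = _viterbi_chain(emis, log_pi, params.p_stay)
    return params.copy_states[states]


def viterbi_segments(
    log2_ratios, params: HmmParams, bins=None, mask=None
) -> pd.DataFrame:
    """Viterbi decode and merge adjacent equal-copy bins into segments.

    With ``bins`` (a GenomeBins) the segments carry genomic coordinates;
    otherwise bin indices are used. Columns: chrom, start, end, copy_number,
    num_bins, seg_mean.
    """
    if bins is not None:
        chrom_all = bins.chrom
        start_all, end_all = bins.start, bins.end
    else:
        n = len(np.asarray(log2_ratios))
        chrom_all = np.array(["*"] * n, dtype=object)
        start_all = np.arange(n)
        end_all = np.arange(1, n + 1)
    x, m = _prepare(log2_ratios, mask)
    idx_in = np.nonzero(m)[0]
    copies = viterbi_path(x, params, chrom=chrom_all, mask=m)
    xv = x[m]

    rows = []
    i = 0
    while i < len(idx_in):
        j = i
        c = copies[i]
        ch = chrom_all[idx_in[i]]
        while j < len(idx_in) and copies[j] == c and chrom_all[idx_in[j]] == ch:
            j += 1
        rows.append(
            {
                "chrom": ch,
                "start": int(start_all[idx_in[i]]),
                "end": int(end_all[idx_in[j - 1]]),
                "copy_number": int(c),
                "num_bins": j - i,
                "seg_mean": float(np.mean(xv[i:j])),
            }
        )
        i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_number", "num_bins", "seg_mean"])


@dataclass
class TumorFractionEstimate:
    """Result of tumor-fraction inference on one sample."""

    tf_hat: float
    loglik: float
    loglik_diploid: float
    sigma: float
    segments: pd.DataFrame
    fga: float  # fraction of (masked-in) genome with copy number != 2
    lmd_call: str
    n_bins_used: int
    grid_loglik: dict[float, float] = field(default_factory=dict)

    @property
    def delta_loglik(self) -> float:
        return self.loglik - self.loglik_diploid


def _profile_sigma(
    x: np.ndarray, chrom, tf: float, p_stay: float, floor_log2: float, n_iter: int = 2
) -> float:
    """Robust residual-scale profile of the emission sigma at fixed tf:
    start from the MAD scale, then iterate Viterbi decode -> RMS residual."""
    sigma = max(1.4826 * float(np.median(np.abs(x - np.median(x)))), 0.05)
    for _ in range(n_iter):
        params = HmmParams(tf=tf, sigma=sigma, p_stay=p_stay, floor_log2=floor_log2)
        copies = viterbi_path(x, params, chrom=chrom)
        mu = expected_log2_ratio(copies, tf, floor_log2)
        sigma = max(float(np.sqrt(np.mean((x - mu) ** 2))), 0.03)
    return sigma


def estimate_tumor_fraction(
    coverage: BinnedCoverage,
    grid: Sequence[float] = DEFAULT_TF_GRID,
    refine: bool = False,
    p_stay: float = 0.999,
    floor_log2: float = -3.0,
    tf_min: float = DEFAULT_TF_MIN,
    delta_loglik: float = DEFAULT_DELTA_LOGLIK,
) -> TumorFractionEstimate:
    """Profile-likelihood tumor-fraction estimate over a grid.

    For each candidate tf the emission sigma is profiled (iterated Viterbi
    residual scale) and the exact forward log-likelihood computed; tf_hat is
    the grid argmax with ties broken toward smaller tf (a conservative null
    preference). With ``refine`` the optimum is polished by golden-section
    search between its grid neighbours. The grid must contain 0 so the
    diploid log-likelihood is always available for the positivity margin.
    """
    grid = sorted(set(float(t) for t in grid))
    if not grid or grid[0] != 0.0:
        raise ValueError("tf grid must be nonempty and include 0")
    mask = coverage.mask
    n_used = int(mask.sum())
    if n_used < 10:
        raise ValueError(f"only {n_used} masked-in bins; need at least 10")
    if n_used < 100:
        warnings.warn(f"only {n_used} masked-in bins; estimate may be unstable")
    x = coverage.log2_ratio[mask]
    chrom = coverage.bins.chrom[mask]

    def loglik_at(tf: float) -> tuple[float, float]:
        sigma = _profile_sigma(x, chrom, tf, p_stay, floor_log2)
        params = HmmParams(tf=tf, sigma=sigma, p_stay=p_stay, floor_log2=floor_log2)
        return hmm_loglik(x, params, chrom=chrom), sigma

    grid_ll: dict[float, float] = {}
    sigmas: dict[float, float] = {}
    best_tf = 0.0
    for tf in grid:
        ll, sig = loglik_at(tf)
        grid_ll[tf] = ll
        sigmas[tf] = sig
        if ll > grid_ll[best_tf]:
            best_tf = tf

    tf_hat, ll_hat, sigma_hat = best_tf, grid_ll[best_tf], sigmas[best_tf]
    if refine and tf_hat > 0.0:
        i = grid.index(tf_hat)
        lo = grid[i - 1] if i > 0 else 0.0
        hi = grid[i + 1] if i + 1 < len(grid) else min(1.0, tf_hat + 0.05)
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c_pt = b - invphi * (b - a)
        d_pt = a + invphi * (b - a)
        fc, _ = loglik_at(c_pt)
        fd, _ = loglik_at(d_pt)
        for _ in range(25):
            if fc > fd:
                b, d_pt, fd = d_pt, c_pt, fc
                c_pt = b - invphi * (b - a)
                fc, _ = loglik_at(c_pt)
            else:
                a, c_pt, fc = c_pt, d_pt, fd
                d_pt = a + invphi * (b - a)
                fd, _ = loglik_at(d_pt)
        tf_star = c_pt if fc > fd else d_pt
        ll_star, sigma_star = loglik_at(tf_star)
        if ll_star > ll_hat:
            tf_hat, ll_hat, sigma_hat = tf_star, ll_star, sigma_star

    params_hat = HmmParams(tf=tf_hat, sigma=sigma_hat, p_stay=p_stay, floor_log2=floor_log2)
    segments = viterbi_segments(coverage.log2_ratio, params_hat, bins=coverage.bins, mask=mask)
    fga = (
        float(segments.loc[segments.copy_number != 2, "num_bins"].sum() / n_used)
        if len(segments)
        else 0.0
    )
    est = TumorFractionEstimate(
        tf_hat=tf_hat,
        loglik=ll_hat,
        loglik_diploid=grid_ll[0.0],
        sigma=sigma_hat,
        segments=segments,
        fga=fga,
        lmd_call="negative",
        n_bins_used=n_used,
        grid_loglik=grid_ll,
    )
    est.lmd_call = classify_lmd(est, tf_min=tf_min, delta_loglik=delta_loglik)
    return est


def classify_lmd(
    est: TumorFractionEstimate,
    tf_min: float = DEFAULT_TF_MIN,
    delta_loglik: float = DEFAULT_DELTA_LOGLIK,
) -> str:
    """Binary LMD call: positive when the inferred tumor fraction is
    meaningfully nonzero (>= tf_min) AND the aneuploid model beats the diploid
    model by at least ``delta_loglik`` log-likelihood units."""
    positive = est.tf_hat >= tf_min and (est.loglik - est.loglik_diploid) >= delta_loglik
    return "positive" if positive else "negative"
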