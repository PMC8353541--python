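"""Paired diagnostic-test evaluation for CSF cfDNA vs cytology.

Samples carry a group label that defines disease truth: ``LMD`` samples come
from patients with cytologically confirmed leptomeningeal disease (truth
positive); ``PT`` samples come from patients with parenchymal tumors not
abutting a CSF space (truth negative); ``PTACSF`` samples come from patients
whose parenchymal tumor abuts the CSF and sheds DNA into it, which confounds
the cfDNA call — they are excluded from accuracy evaluation by default.

The statistics here are the standard paired-design toolkit: per-test confusion
tables against truth, a 2x2 concordance table between the two tests, exact
binomial (Clopper-Pearson) confidence intervals for each proportion metric,
the exact McNemar test on the discordant cells, Fisher's exact test for
association of sampling route with outcome, and Wilcoxon rank-sum comparisons
of log2-transformed cancer fraction and cfDNA concentration between groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("LMD", "PT", "PTACSF")
ROUTES = ("lumbar", "shunt")

__all__ = [
    "SampleRecord",
    "Confusion",
    "PairedDiagnosticTable",
    "MetricEstimate",
    "DiagnosticMetrics",
    "build_tables",
    "diagnostic_metrics",
    "clopper_pearson",
    "mcnemar_exact",
    "mcnemar_asymptotic",
    "fisher_exact",
    "route_association",
    "group_summaries",
]


@dataclass
class SampleRecord:
    """One CSF (or plasma) sample with its clinical labels and cfDNA outcomes.

    ``cytology`` and ``cfdna_call`` are 'positive'/'negative'; cytology
    readings other than "positive for malignant cells" (atypical, suspicious)
    are mapped to 'negative' upstream of this container.
    """

    sample_id: str
    patient_id: str
    group: str
    route: str = "lumbar"
    cytology: str | None = None
    cfdna_call: str | None = None
    cancer_fraction: float | None = None
    concentration: float | None = None
    rbc_count: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.route not in ROUTES:
            raise ValueError(
                f"sample {self.sample_id!r}: route must be one of {ROUTES}, got {self.route!r}"
            )
        if self.concentration is not None and self.concentration < 0:
            raise ValueError(f"sample {self.sample_id!r}: concentration must be >= 0")

    @property
    def truth_positive(self) -> bool:
        """Disease truth: LMD samples positive, PT and PTACSF negative."""
        return self.group == "LMD"


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PairedDiagnosticTable:
    """2x2 concordance between two tests on the same samples.

    a: both positive; b: test1 positive / test2 negative;
    c: test1 negative / test2 positive; d: both negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("concordance cells must be non-negative")
        if self.n == 0:
            raise ValueError("concordance table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class MetricEstimate:
    point: float
    lo: float
    hi: float
    defined: bool = True

    def display(self, ndigits: int = 2) -> str:
        if not self.defined:
            return "NA"
        p = _round_half_up(self.point, ndigits)
        lo = _round_half_up(self.lo, ndigits)
        hi = _round_half_up(self.hi, ndigits)
        return f"{p:.{ndigits}f} ({lo:.{ndigits}f}-{hi:.{ndigits}f})"


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    accuracy: MetricEstimate

    def as_dict(self) -> dict[str, MetricEstimate]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def _round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, e.g. 0.625 -> 0.63 at 2 digits.

    Display values in clinical tables conventionally round half up; Python's
    builtin round() uses banker's rounding and would print 0.62.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _require(record: SampleRecord, fields: Sequence[str]) -> None:
    for f in fields:
        if getattr(record, f) is None:
            raise ValueError(f"sample {record.sample_id!r}: missing required field {f!r}")


def build_tables(
    records: Iterable[SampleRecord], exclude_ptacsf: bool = True
) -> tuple[dict[str, Confusion], PairedDiagnosticTable]:
    """Tabulate each test against disease truth and the two tests against each other.

    Returns ``({"cfdna": Confusion, "cytology": Confusion}, paired)`` where the
    paired table's test1 is cfDNA and test2 is cytology. With ``exclude_ptacsf``
    (the default, mirroring the study design) PTACSF samples are dropped before
    tabulation because tumor DNA from a parenchymal tumor abutting the CSF
    makes the cfDNA assay positive without leptomeningeal disease.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    if exclude_ptacsf:
        records = [r for r in records if r.group != "PTACSF"]
        if not records:
            raise ValueError("empty cohort after PTACSF exclusion")

    conf = {}
    for test in ("cfdna_call", "cytology"):
        tp = fp = fn = tn = 0
        for r in records:
            _require(r, ["cytology", "cfdna_call"])
            pos = getattr(r, test) == "positive"
            if r.truth_positive:
                tp += pos
                fn += not pos
            else:
                fp += pos
                tn += not pos
        conf["cfdna" if test == "cfdna_call" else "cytology"] = Confusion(tp, fp, fn, tn)

    a = sum(1 for r in records if r.cfdna_call == "positive" and r.cytology == "positive")
    b = sum(1 for r in records if r.cfdna_call == "positive" and r.cytology == "negative")
    c = sum(1 for r in records if r.cfdna_call == "negative" and r.cytology == "positive")
    d = sum(1 for r in records if r.cfdna_call == "negative" and r.cytology == "negative")
    return conf, PairedDiagnosticTable(a, b, c, d)


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for x successes in n trials.

    The bounds are beta-distribution quantiles; the lower bound is exactly 0
    when x == 0 and the upper exactly 1 when x == n. For x == n the lower
    bound has the closed form (alpha/2)**(1/n).
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= x <= n):
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def _proportion(x: int, n: int, alpha: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(math.nan, math.nan, math.nan, defined=False)
    lo, hi = clopper_pearson(x, n, alpha)
    return MetricEstimate(x / n, lo, hi)


def diagnostic_metrics(confusion: Confusion, alpha: float = 0.05) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact 95% CIs.

    A metric whose denominator is zero is returned flagged undefined rather
    than raising, so a degenerate cohort still yields the other metrics.
    """
    tp, fp, fn, tn = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    return DiagnosticMetrics(
        sensitivity=_proportion(tp, tp + fn, alpha),
        specificity=_proportion(tn, tn + fp, alpha),
        ppv=_proportion(tp, tp + fp, alpha),
        npv=_proportion(tn, tn + fn, alpha),
        accuracy=_proportion(tp + tn, confusion.n, alpha),
    )


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar test on the discordant counts of a paired table.

    Under the null the b discordant outcomes of one kind among b + c total are
    Binomial(b + c, 1/2); the two-sided p doubles the upper tail at max(b, c)
    and is capped at 1. With no discordant pairs p = 1 by convention.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    k = max(b, c)
    p = 2.0 * float(stats.binom.sf(k - 1, n, 0.5))
    return min(1.0, p)


def mcnemar_asymptotic(b: int, c: int, continuity: bool = True) -> float:
    """Chi-square McNemar test (continuity-corrected by default), for comparison."""
    n = b + c
    if n == 0:
        return 1.0
    num = (abs(b - c) - 1) ** 2 if continuity else (b - c) ** 2
    return float(stats.chi2.sf(num / n, df=1))


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of hypergeometric
    probabilities no larger than the observed table's)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    if t.sum() == 0:
        raise ValueError("table is empty")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def route_association(records: Iterable[SampleRecord], test: str = "cfdna_call") -> float:
    """Fisher exact p for association between sampling route and a test outcome."""
    records = list(records)
    table = [
        [
            sum(1 for r in records if r.route == route and getattr(r, test) == result)
            for result in ("positive", "negative")
        ]
        for route in ROUTES
    ]
    return fisher_exact(table)


def group_summaries(
    records: Iterable[SampleRecord],
    fields: Sequence[str] = ("cancer_fraction", "concentration"),
    bonferroni: bool = True,
) -> dict[str, object]:
    """Per-group median/IQR for the requested fields plus pairwise Wilcoxon
    rank-sum p-values on log2-transformed values.

    Quantiles use linear interpolation. Values of exactly zero map to -inf
    under log2; the rank-sum statistic is unaffected because ranks are
    preserved. Pairwise p-values are Bonferroni-corrected across the group
    pairs present unless ``bonferroni=False``. Absent groups are omitted with
    a warning.
    """
    records = list(records)
    out: dict[str, object] = {"summaries": {}, "pairwise": {}}
    for f in fields:
        by_group: dict[str, np.ndarray] = {}
        for g in GROUPS:
            vals = np.array(
                [getattr(r, f) for r in records if r.group == g and getattr(r, f) is not None],
                dtype=float,
            )
            if vals.size == 0:
                warnings.warn(f"group {g} absent or has no {f}; omitted from summaries")
                continue
            by_group[g] = vals
        summ = {}
        for g, vals in by_group.items():
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            summ[g] = {"n": int(vals.size), "median": float(med), "q1": float(q1), "q3": float(q3)}
        out["summaries"][f] = summ

        pairs = list(combinations(sorted(by_group), 2))
        m = len(pairs)
        pw = {}
        for g1, g2 in pairs:
            with np.errstate(divide="ignore"):
                x = np.log2(by_group[g1])
                y = np.log2(by_group[g2])
            if np.array_equal(np.sort(x), np.sort(y)):
                p = 1.0  # identical samples: no evidence of a shift
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1])
            if bonferroni:
                p = min(1.0, p * m)
            pw[f"{g1}_vs_{g2}"] = p
        out["pairwise"][f] = pw
    return out
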