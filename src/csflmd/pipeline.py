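"""End-to-end orchestration: simulate -> coverage -> tumor fraction ->
fragmentomics -> diagnostics, producing a study-style cohort report.

A run is fully determined by its configuration (including the seed): the
report text and JSON are byte-identical across repeated runs. Timings and
per-sample progress go to a separate log file so the report stays
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as cio
from .coverage import coverage_from_counts, correct_gc_mappability, panel_from_samples
from .diagnostics import (
    SampleRecord,
    _round_half_up,
    build_tables,
    diagnostic_metrics,
    group_summaries,
    mcnemar_asymptotic,
    mcnemar_exact,
    route_association,
)
from .fragmentomics import flag_contamination, profile_from_lengths
from .simulate import (
    CohortConfig,
    SimSampleConfig,
    make_genome_bins,
    simulate_binned_counts,
    simulate_cohort,
    uniform_genome,
)
from .tumor_fraction import DEFAULT_TF_GRID, estimate_tumor_fraction

__all__ = ["RunConfig", "run_pipeline", "render_report", "format_p", "format_percent"]


@dataclass
class RunConfig:
    """All pipeline parameters in one place; defaults are the study-anchored
    values where one exists (1 Mb bins, MAPQ 20, copy states 0-5, peak windows
    140-200/300-360 bp)."""

    # genome / binning
    n_chroms: int = 22
    chrom_length: int = 100_000_000
    bin_size: int = 1_000_000
    min_mapq: int = 20
    mappability_threshold: float = 0.9
    # cohort simulation
    simulate_first: bool = True
    n_lmd_samples: int = 43
    n_pt_samples: int = 5
    n_ptacsf_samples: int = 3
    cytology_sensitivity: float = 0.72
    mean_depth: float = 0.1
    nb_dispersion: float = 0.01
    n_fragments: int = 50_000
    frac_genome_altered: float = 0.25
    contamination_rate: float = 0.0
    lumbar_fraction: float = 0.7
    n_panel: int = 20
    # tumor-fraction model
    p_stay: float = 0.999
    tf_min: float = 0.03
    delta_loglik: float = 2.0
    refine: bool = False
    # fragmentomics
    contamination_threshold: float = 2.8
    # evaluation
    alpha: float = 0.05
    exclude_ptacsf: bool = True
    # inputs for non-simulated runs
    sample_sheet: str | None = None
    input_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_lmd_samples=self.n_lmd_samples,
            n_pt_samples=self.n_pt_samples,
            n_ptacsf_samples=self.n_ptacsf_samples,
            cytology_sensitivity=self.cytology_sensitivity,
            mean_depth=self.mean_depth,
            nb_dispersion=self.nb_dispersion,
            n_fragments=self.n_fragments,
            frac_genome_altered=self.frac_genome_altered,
            contamination_rate=self.contamination_rate,
            lumbar_fraction=self.lumbar_fraction,
            seed=self.seed,
        )


def format_p(p: float) -> str:
    """Clinical-journal p-value style: '.01', '<.001', '>.99'."""
    if math.isnan(p):
        return "NA"
    if p < 0.001:
        return "<.001"
    if p > 0.995:
        return ">.99"
    r = _round_half_up(p, 2)
    if r < 0.005:
        return "<.01"
    return f"{r:.2f}".lstrip("0")


def format_percent(x: float) -> str:
    """Prose-style whole percent: 0.625 -> '63%'."""
    return f"{_round_half_up(100.0 * x, 0):.0f}%"


def _simulate_panel(bins, cfg: RunConfig) -> np.ndarray:
    """Panel of normals: per-bin median corrected coverage over simulated
    diploid replicates (a synthetic stand-in for reference standards)."""
    master = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 12345]))
    corrected_list = []
    for _ in range(cfg.n_panel):
        sub = int(master.integers(0, 2**31 - 1))
        sim = SimSampleConfig(
            tumor_fraction=0.0,
            mean_depth=cfg.mean_depth,
            nb_dispersion=cfg.nb_dispersion,
            seed=sub,
        )
        counts = simulate_binned_counts(bins, sim)
        corrected, _ = correct_gc_mappability(
            counts, bins, mappability_threshold=cfg.mappability_threshold
        )
        corrected_list.append(corrected)
    return panel_from_samples(corrected_list)


def _analyze_sample(counts, lengths, bins, panel, cfg: RunConfig) -> dict:
    cov = coverage_from_counts(
        counts, bins, panel_median=panel, mappability_threshold=cfg.mappability_threshold
    )
    est = estimate_tumor_fraction(
        cov,
        grid=DEFAULT_TF_GRID,
        refine=cfg.refine,
        p_stay=cfg.p_stay,
        tf_min=cfg.tf_min,
        delta_loglik=cfg.delta_loglik,
    )
    out = {
        "tf_hat": est.tf_hat,
        "lmd_call": est.lmd_call,
        "delta_loglik": est.delta_loglik,
        "fga": est.fga,
        "n_bins_used": est.n_bins_used,
        "segments": est.segments,
    }
    if lengths is not None and len(lengths) > 0:
        profile = profile_from_lengths(lengths)
        out["log2_peak_ratio"] = profile.log2_peak_ratio
        out["contamination_flag"] = flag_contamination(profile, cfg.contamination_threshold)
    else:
        out["log2_peak_ratio"] = math.nan
        out["contamination_flag"] = "undefined"
    return out


def _load_real_inputs(cfg: RunConfig, bins):
    records = cio.read_sample_sheet(cfg.sample_sheet)
    input_dir = Path(cfg.input_dir or ".")
    samples = []
    for rec in records:
        wig = input_dir / f"{rec.sample_id}.wig"
        counts = cio.read_wig(wig)["value"].to_numpy()
        hist_path = input_dir / f"{rec.sample_id}.lengths.tsv"
        lengths = None
        if hist_path.exists():
            hist = cio.read_histogram_tsv(hist_path)
            lengths = np.repeat(
                np.fromiter(hist.keys(), dtype=int), np.fromiter(hist.values(), dtype=int)
            )
        samples.append((rec, counts.astype(np.int64), lengths, None))
    return samples


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full pipeline and write per-sample outputs plus a cohort report.

    Returns the results dict that ``render_report`` consumes. A sample whose
    analysis fails is logged and excluded with its reason rather than aborting
    the cohort.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_dir = out / "segments"
    seg_dir.mkdir(exist_ok=True)
    log_lines = []
    t0 = time.time()

    bins = make_genome_bins(
        uniform_genome(config.n_chroms, config.chrom_length),
        bin_size=config.bin_size,
        mappability_threshold=config.mappability_threshold,
        seed=config.seed,
    )
    panel = _simulate_panel(bins, config)
    log_lines.append(f"[{time.time() - t0:.1f}s] genome: {len(bins)} bins; panel of {config.n_panel}")

    if config.simulate_first:
        cohort = simulate_cohort(config.cohort_config(), bins)
        samples = [
            (s.record, s.raw_counts, s.fragment_lengths, s.true_tumor_fraction) for s in cohort
        ]
    else:
        if not config.sample_sheet:
            raise ValueError("simulate_first is off and no sample_sheet given")
        samples = _load_real_inputs(config, bins)

    per_sample = []
    records: list[SampleRecord] = []
    failures = []
    for rec, counts, lengths, true_tf in samples:
        try:
            res = _analyze_sample(counts, lengths, bins, panel, config)
        except Exception as exc:  # isolate the failing sample
            failures.append({"sample_id": rec.sample_id, "reason": str(exc)})
            log_lines.append(f"[{time.time() - t0:.1f}s] {rec.sample_id}: FAILED ({exc})")
            continue
        rec.cfdna_call = res["lmd_call"]
        rec.cancer_fraction = res["tf_hat"]
        records.append(rec)
        cio.write_seg(seg_dir / f"{rec.sample_id}.seg", rec.sample_id, res.pop("segments"))
        row = {"sample_id": rec.sample_id, "group": rec.group, "route": rec.route,
               "cytology": rec.cytology, **res}
        if true_tf is not None:
            row["true_tumor_fraction"] = true_tf
        per_sample.append(row)
        log_lines.append(
            f"[{time.time() - t0:.1f}s] {rec.sample_id}: tf={res['tf_hat']:.3f} "
            f"call={res['lmd_call']} bins={res['n_bins_used']}"
        )

    if not records:
        raise ValueError("no sample analyzed successfully")

    conf, paired = build_tables(records, exclude_ptacsf=config.exclude_ptacsf)
    metrics = {test: diagnostic_metrics(c, alpha=config.alpha) for test, c in conf.items()}
    evaluation = {
        "confusion": {t: dataclasses.asdict(c) for t, c in conf.items()},
        "paired_table": dataclasses.asdict(paired),
        "metrics": {
            t: {k: dataclasses.asdict(v) for k, v in m.as_dict().items()}
            for t, m in metrics.items()
        },
        "mcnemar_exact_p": mcnemar_exact(paired.b, paired.c),
        "mcnemar_asymptotic_p": mcnemar_asymptotic(paired.b, paired.c),
        "fisher_route_cfdna_p": route_association(records, "cfdna_call"),
        "fisher_route_cytology_p": route_association(records, "cytology"),
        "group_summaries": group_summaries(records),
    }

    results = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_bins": len(bins),
        "samples": per_sample,
        "failures": failures,
        "evaluation": evaluation,
    }

    config.to_yaml(out / "config.yaml")
    cio.write_sample_sheet(out / "sample_sheet.tsv", records)
    cio.write_panel_tsv(out / "panel.tsv", bins, panel)
    text, js = render_report(results)
    (out / "report.txt").write_text(text)
    (out / "report.json").write_text(js)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def render_report(results: dict) -> tuple[str, str]:
    """Render the cohort results as a human-readable text report and a
    machine-readable JSON string (both deterministic given the results)."""
    ev = results["evaluation"]
    lines = []
    lines.append("CSF cfDNA leptomeningeal disease detection - cohort report")
    lines.append(f"csflmd version {results['version']}")
    lines.append("")
    conf = ev["confusion"]
    lines.append(
        f"Cohort: {len(results['samples'])} samples analyzed "
        f"({len(results['failures'])} failed)"
    )
    paired = ev["paired_table"]
    lines.append(
        "Paired outcomes (cfDNA vs cytology): "
        f"both+ {paired['a']}, cfDNA-only+ {paired['b']}, "
        f"cytology-only+ {paired['c']}, both- {paired['d']}"
    )
    lines.append("")
    lines.append("Diagnostic metrics (95% CI)")
    lines.append(f"{'Metric':28s}{'CSF cfDNA':22s}{'Cytology':22s}")
    names = {
        "sensitivity": "Sensitivity",
        "specificity": "Specificity",
        "ppv": "Positive predictive value",
        "npv": "Negative predictive value",
        "accuracy": "Accuracy",
    }
    for key, label in names.items():
        row = f"{label:28s}"
        for test in ("cfdna", "cytology"):
            m = ev["metrics"][test][key]
            if m.get("defined", True) and not math.isnan(m["point"]):
                cell = (
                    f"{_round_half_up(m['point'], 2):.2f} "
                    f"({_round_half_up(m['lo'], 2):.2f}-{_round_half_up(m['hi'], 2):.2f})"
                )
            else:
                cell = "NA"
            row += f"{cell:22s}"
        lines.append(row.rstrip())
    lines.append("")
    sens_cf = ev["metrics"]["cfdna"]["sensitivity"]["point"]
    sens_cy = ev["metrics"]["cytology"]["sensitivity"]["point"]
    lines.append(
        f"cfDNA sensitivity {format_percent(sens_cf)} vs cytology {format_percent(sens_cy)}; "
        f"McNemar exact P = {format_p(ev['mcnemar_exact_p'])}"
    )
    lines.append(
        f"Sampling route association: cfDNA P = {format_p(ev['fisher_route_cfdna_p'])}, "
        f"cytology P = {format_p(ev['fisher_route_cytology_p'])} (Fisher exact)"
    )
    lines.append("")
    gs = ev["group_summaries"]
    for fieldname, summ in gs["summaries"].items():
        lines.append(f"{fieldname} by group (median [IQR]):")
        for g in sorted(summ):
            s = summ[g]
            lines.append(
                f"  {g:8s} n={s['n']:3d}  {s['median']:.4g} [{s['q1']:.4g}-{s['q3']:.4g}]"
            )
        for pair, p in sorted(gs["pairwise"][fieldname].items()):
            lines.append(f"  Wilcoxon {pair}: P = {format_p(p)} (Bonferroni-corrected)")
        lines.append("")
    lines.append("Per-sample results")
    lines.append(
        f"{'sample':10s}{'group':8s}{'cytology':10s}{'cfDNA':10s}"
        f"{'tf_hat':8s}{'peak_ratio':11s}{'flag':20s}"
    )
    for s in results["samples"]:
        pr = s["log2_peak_ratio"]
        pr_s = f"{pr:.2f}" if not math.isnan(pr) else "NA"
        lines.append(
            f"{s['sample_id']:10s}{s['group']:8s}{s['cytology']:10s}{s['lmd_call']:10s}"
            f"{s['tf_hat']:<8.3f}{pr_s:11s}{s['contamination_flag']:20s}".rstrip()
        )
    for f in results["failures"]:
        lines.append(f"{f['sample_id']:10s}EXCLUDED: {f['reason']}")
    text = "\n".join(lines) + "\n"
    js = json.dumps(results, indent=2, sort_keys=True, default=_json_default) + "\n"
    return text, js
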