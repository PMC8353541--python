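# csflmd

Detection of leptomeningeal disease (LMD) from cerebrospinal-fluid (CSF)
cell-free DNA (cfDNA), for researchers evaluating liquid-biopsy diagnostics
against CSF cytology.

LMD — spread of cancer to the membranes surrounding the brain and spinal
cord — is conventionally diagnosed by finding malignant cells in CSF, a test
with notoriously poor sensitivity. Tumor cells shed DNA into the CSF, and
that DNA carries somatic copy-number alterations that are visible in
ultra-low-pass whole-genome sequencing (ULP-WGS, ~0.1× depth). This package
implements the complete analysis chain for that idea:

- **Coverage**: fragments are counted into 1 Mb bins over autosomes 1–22
  (midpoint assignment, MAPQ ≥ 20), corrected for GC content and mappability,
  and normalized against a panel of diploid reference samples to per-bin
  log₂ coverage ratios.
- **Tumor fraction**: a 6-state copy-number hidden Markov model over a
  tumor/normal mixture. A bin with tumor copy number c ∈ {0,…,5} at tumor
  fraction *tf* has expected log₂ ratio

      μ(c, tf) = log₂( (tf·c + (1 − tf)·2) / 2 ),

  with Gaussian emissions N(μ(c, tf), σ²) and homogeneous transitions
  (self-transition 0.999; chromosomes are independent chains). *tf* is
  estimated by profile likelihood over a grid with σ profiled at each grid
  point; the copy-number path comes from Viterbi decoding. A sample is
  called **LMD-positive** when tf̂ ≥ 0.03 and the aneuploid model beats the
  diploid model by ≥ 2 log-likelihood units. This is an "ichorCNA-style"
  model: no subclonal states, ploidy fixed at 2.
- **Fragmentomics**: cfDNA fragment sizes reflect nucleosomal protection
  (~166 bp per nucleosome). The log₂ peak ratio — fragments of 140–200 bp
  over fragments of 300–360 bp — is higher in plasma (~3.5) than CSF (~2.2)
  and flags blood contamination of a CSF sample.
- **Diagnostics**: paired evaluation of cfDNA vs cytology against the group
  truth (LMD positive; parenchymal-tumor controls negative): sensitivity,
  specificity, predictive values and accuracy with exact Clopper–Pearson
  95% CIs, the exact McNemar test on discordant pairs, Fisher exact tests
  for sampling-route association, and Wilcoxon rank-sum group comparisons
  of log₂ cancer fraction and cfDNA concentration.
- **Synthetic cohorts**: a first-class generator producing binned ULP-WGS
  coverage with segmental aneuploidy at a controllable tumor fraction,
  bimodal nucleosomal fragment lengths (CSF vs plasma), and cohorts with
  cytology drawn at a stated sensitivity — so the whole pipeline is testable
  without sequencing data.

Samples from patients whose parenchymal tumor abuts a CSF space (PTACSF)
shed tumor DNA into CSF without leptomeningeal disease; they are excluded
from accuracy evaluation by default, mirroring the study design this
package models.

## Worked example

`examples/04_diagnostics_table.py` builds the cohort from published paired
outcome counts (43 LMD samples: 30 positive on both tests, 10 cfDNA-only,
1 cytology-only, 2 negative on both; 5 parenchymal-tumor samples negative on
both) and prints:

```
paired table: both+ 30, cfDNA-only+ 10, cytology-only+ 1, both- 7 (n=48)

Metric                      CSF cfDNA           Cytology
sensitivity                 0.93 (0.81-0.99)    0.72 (0.56-0.85)
specificity                 1.00 (0.48-1.00)    1.00 (0.48-1.00)
ppv                         1.00 (0.91-1.00)    1.00 (0.89-1.00)
npv                         0.63 (0.24-0.91)    0.29 (0.10-0.56)
accuracy                    0.94 (0.83-0.99)    0.75 (0.60-0.86)

cfDNA detects LMD in 93% of positive samples vs 72% by cytology; exact
McNemar P = .01 (the two tests disagree asymmetrically: 10 vs 1 discordant samples)
```

cfDNA misses 3 of 43 LMD samples but cytology misses 12; the discordance is
lopsided enough (10 vs 1) that the exact McNemar test rejects equal
sensitivity. `examples/02_tumor_fraction.py` shows the estimator on one
simulated sample (true tf 0.60, ~25% of the genome altered, 0.1× depth):

```
estimated tumor fraction: 0.55 (true 0.60)
log-likelihood gain over the diploid model: 1000.5 (>= 2 required for a positive call)
fraction of genome altered: 0.25 (true ~0.25)
LMD call: positive
```

The other examples cover cohort simulation, the fragment-length peak ratio
(CSF ≈ 2.16, plasma ≈ 3.54, a 50% contaminated sample in between), and the
full pipeline with its report.

## Command line

A thin CLI wraps the library for shell use:

```bash
csflmd simulate --seed 1 --out-dir sim/          # cohort + WIG counts + sample sheet
csflmd coverage --fragments f.tsv --bins bins.tsv --out cov.tsv
csflmd tf --coverage cov.tsv --out tf.json --seg sample.seg
csflmd fragment --histogram lengths.tsv --out frag.json
csflmd evaluate --sample-sheet sheet.tsv --out eval.json
csflmd run-all --seed 1 --out-dir run/           # everything, ending in a report
```

`run-all` is deterministic given its seed: two runs produce byte-identical
reports.

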