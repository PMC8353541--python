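"""Simulate a study-style CSF cfDNA cohort.

Generates 1 Mb binned ULP-WGS coverage over 22 autosomes plus nucleosomal
fragment lengths for a cohort of 43 LMD / 5 PT / 3 PTACSF samples, and prints
the cohort composition and a few per-sample ground truths.
"""

import numpy as np

from csflmd import CohortConfig, make_genome_bins, simulate_cohort, uniform_genome

bins = make_genome_bins(uniform_genome(22, 100_000_000), seed=0)
print(f"genome: {len(bins)} bins of 1 Mb over 22 autosomes")

cohort = simulate_cohort(CohortConfig(seed=0), bins)
groups = [s.record.group for s in cohort]
print(f"cohort: {len(cohort)} samples "
      f"({groups.count('LMD')} LMD, {groups.count('PT')} PT, {groups.count('PTACSF')} PTACSF)")

tf_lmd = [s.true_tumor_fraction for s in cohort if s.record.group == "LMD"]
print(f"true tumor fraction in LMD samples: median {np.median(tf_lmd):.2f} "
      f"(the fraction of CSF cfDNA derived from tumor cells)")

cyto_pos = sum(s.record.cytology == "positive" for s in cohort if s.record.group == "LMD")
print(f"cytology positive in {cyto_pos}/{len(tf_lmd)} LMD samples "
      f"(drawn at the configured 72% sensitivity)")

s = cohort[0]
print(f"\nfirst sample {s.record.sample_id}: tf={s.true_tumor_fraction:.2f}, "
      f"{len(s.cna_profile)} CNA segments, "
      f"mean bin count {s.raw_counts.mean():.0f} (targeting 0.1X depth)")
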