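"""Fragment-length peak ratio: CSF vs plasma, and a contaminated sample.

Plasma cfDNA is dominated by mono-nucleosomal fragments (~166 bp); CSF cfDNA
retains more di-nucleosomal fragments (~332 bp). The log2 ratio of fragment
counts in the 140-200 bp window over the 300-360 bp window is therefore
higher in plasma, and flags blood contamination of a CSF sample.
"""

from csflmd import SimSampleConfig, flag_contamination, profile_from_lengths
from csflmd.simulate import simulate_fragment_lengths

for label, cfg in [
    ("pure CSF", SimSampleConfig(origin="CSF", seed=1)),
    ("pure plasma", SimSampleConfig(origin="plasma", seed=1)),
    ("CSF + 50% plasma", SimSampleConfig(origin="CSF", plasma_contamination=0.5, seed=1)),
]:
    lengths = simulate_fragment_lengths(cfg, 50_000)
    prof = profile_from_lengths(lengths)
    flag = flag_contamination(prof)  # threshold 2.8 = midpoint of group medians
    print(f"{label:18s} peak1={prof.peak1_count:6d} peak2={prof.peak2_count:6d} "
          f"log2 peak ratio = {prof.log2_peak_ratio:.2f} -> {flag}")

print("\ntypical medians: ~2.16 in CSF, ~3.51 in plasma; a CSF sample above the "
      "2.8 threshold is flagged as plasma-contaminated (e.g. traumatic tap).")
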