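"""Call punctate pioneer-factor peaks against the input control.

Tags are extended to the 150 bp insert size; candidate regions come from
bins whose pooled chip+control coverage is Poisson-surprising, and each
candidate is tested with a binomial chip-vs-input test at BH FDR 0.05.
"""

from ladpipe import SimConfig, simulate_experiment, call_peaks, deduplicate, downsample
from ladpipe.core import intersect_any
from ladpipe.peaks import peaks_to_intervals

truth, libraries = simulate_experiment(SimConfig(seed=42))
control = deduplicate(libraries["input"])
tf_A = deduplicate(libraries["tf_A"])
tf_B = deduplicate(libraries["tf_B"])

# equal-depth comparison: downsample both conditions to the smaller library
target = min(tf_A.total_tags, tf_B.total_tags)
tf_A, tf_B = downsample(tf_A, target, seed=1), downsample(tf_B, target, seed=2)

peaks_A = call_peaks(tf_A, control)
peaks_B = call_peaks(tf_B, control)
print(f"peaks: {len(peaks_A)} in young, {len(peaks_B)} in old "
      f"(truth: {len(truth.tf_sites_A)} and {len(truth.tf_sites_B)} sites; "
      "weak sites at this depth stay below the FDR cut)")

hits = intersect_any(peaks_to_intervals(peaks_B), truth.tf_sites_B)
print(f"{int(hits.sum())}/{len(peaks_B)} old-condition peaks coincide with a true site")
best = max(peaks_B, key=lambda p: p.enrichment)
print(f"strongest peak: {best.chrom}:{best.start}-{best.end} "
      f"summit {best.summit}, {best.enrichment:.1f}x over expectation, q={best.q:.1e}")
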