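"""Test whether gained TF sites concentrate inside young-condition LADs.

Each site is compared against a random genomic region of the same size on
the same chromosome; the resulting 2x2 table (sites vs background, in vs
out of LADs) is tested with a two-sided Fisher exact test.
"""

from ladpipe import SimConfig, simulate_experiment, overlap_enrichment, merge_intervals

config = SimConfig(seed=42)
truth, _ = simulate_experiment(config)

result = overlap_enrichment(
    truth.tf_gained,
    merge_intervals(truth.lads_A),
    config.layout,
    seed=7,
)
print(f"{result.k_observed}/{result.n_sites} gained TF sites overlap a young LAD")
print(f"{result.k_background}/{result.n_background} random same-size regions do")
print(f"odds ratio {result.odds_ratio:.1f}, Fisher p = {result.fisher_p:.2e}")
print("A p-value this small says the co-location of new pioneer-factor "
      "binding with (former) lamina domains is far beyond chance.")
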