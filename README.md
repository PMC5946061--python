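# ladpipe

Differential lamina-associated-domain (LAD) and pioneer-factor
co-occupancy analysis for two-condition ChIP-seq.

## The problem

The nuclear lamina tethers broad, gene-poor heterochromatic domains —
lamina-associated domains — at the nuclear periphery. When the lamina
deteriorates (aging, laminopathies), some of these domains detach, and
pioneer transcription factors such as Foxa2, which can engage compacted
chromatin, gain binding precisely where lamina contact is lost. Testing
that model computationally requires a chain of analyses that no single
tool provides end to end:

1. **Broad-domain calling.** LADs appear in lamin B1 ChIP-seq as
   megabase-scale enrichment plateaus, not sharp peaks. `ladpipe` calls
   them SICER-style: the genome is tiled into *w* = 10 kb windows; a
   window with tag count ≥ *l₀* is *eligible*, where *l₀* is the smallest
   count with P(X ≥ *l₀*) < *p₀* under X ~ Poisson(λ_bg) and
   λ_bg = (total tags · w)/(effective genome size); eligible windows at
   most *g* = 3 ineligible windows apart are joined into islands; each
   island is then tested against the input library with a Poisson
   upper-tail test on the library-size-scaled control expectation and
   filtered at Benjamini–Hochberg FDR 0.05.
2. **Punctate peak calling** for the transcription factor, against the
   same input: candidate regions from Poisson-surprising bins of
   fragment-extended coverage, each tested with a binomial chip-vs-input
   test, BH FDR 0.05.
3. **Shared/exclusive classification** of two conditions' region sets
   (the Venn numbers), overlap meaning ≥ 1 shared bp.
4. **Overlap enrichment** of binding sites in a domain set against a
   background of random genomic regions of the same size on the same
   chromosome, tested with a two-sided Fisher exact test on the 2×2
   table [[k_obs, n−k_obs], [k_bg, n−k_bg]].
5. **Local coverage statistics**: site-centred profile matrices
   (CPM-normalized), and the fraction of sites whose summed lamin
   coverage in a 10 kb window is strictly higher in one condition.
6. **Nearest-gene assignment** (single closest TSS, up to 10,000 kb),
   TSS-distance binning (0–5, 5–50, 50–500, >500 kb), and direct-target
   calling by expression fold change (> +2 / < −2, signed linear).

Because real libraries run to tens of millions of reads, the package
ships a first-class **synthetic-data generator** that reproduces the
statistical structure of the design at desk scale (40 Mb genome, 2×10⁵
reads/library) with full ground truth: shared and condition-exclusive
LADs, nested H3K9me3 domains, TF sites gained where lamina contact is
lost, a flat input, and an expression table coupled to TF gain. Every
stage of the pipeline is validated against that truth and against
independent brute-force oracles.

## Worked example

```python
from ladpipe import (SimConfig, simulate_experiment, deduplicate,
                     call_domains, overlap_enrichment, merge_intervals,
                     binned_coverage, windowed_sum_comparison)
from ladpipe.domains import islands_to_intervals

config = SimConfig(seed=42)
truth, libs = simulate_experiment(config)

islands = call_domains(deduplicate(libs["lamin_A"]), deduplicate(libs["input"]))
called = islands_to_intervals(islands)

enr = overlap_enrichment(truth.tf_gained, merge_intervals(truth.lads_A),
                         config.layout, seed=7)
cov_y = binned_coverage(deduplicate(libs["lamin_A"]), 100, normalize=True)
cov_o = binned_coverage(deduplicate(libs["lamin_B"]), 100, normalize=True)
_, frac = windowed_sum_comparison(truth.tf_gained, cov_y, cov_o, window=10_000)
```

On the default conditions this prints (see `examples/` for the full
scripts):

```
true LADs: 12 covering 7.20 Mb
called islands: 12 covering 7.22 Mb
base-level recall   0.997
base-level precision 0.994
100/100 gained TF sites overlap a young LAD
15/100 random same-size regions do
odds ratio 1108.7, Fisher p = 5.29e-41
lamin sum higher in young at 92% of gained sites
```

Reading the numbers: the island caller recovers the planted LADs almost
base-exactly; every TF site gained in the "old" condition falls inside a
"young" LAD versus ~15% expected by chance (Fisher p ≈ 10⁻⁴¹); and at
~92–95% of those sites the young condition carries strictly more lamin
signal in the surrounding 10 kb — the local-lamina-loss signature, whose
generator expectation is 95% (90% of sites in wholly lost domains, the
rest tying at random).

Each capability has a short narrative script under `examples/`, and the
same operations are exposed as CLI verbs:

```bash
ladpipe simulate --seed 4 --outdir fix
ladpipe call-domains --chip fix/tags/lamin_A.bed --control fix/tags/input.bed \
    --chrom-sizes fix/chrom.sizes --outdir out
ladpipe enrich --sites fix/truth/tf_gained.bed --domains fix/truth/lads_A.bed \
    --chrom-sizes fix/chrom.sizes --seed 2
ladpipe run --config pipeline.yaml
```

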