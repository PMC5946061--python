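# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention). Adjacency is not
overlap: [0,100) and [100,200) share no base. Chromosome names match by
exact string comparison — no "chr" aliasing — because silent aliasing
corrupts toy genomes far more often than it rescues real ones. All
readers/writers speak plain-text BED3/BED6, chrom.sizes, bedGraph and
TSV; BAM/CRAM, FASTA and liftover are out of scope (the package consumes
tag records, assuming alignment, quality filtering and alignment-level
deduplication happened upstream).

## Tag preprocessing

A tag's counting anchor is its 5′ position (start on +, end−1 on −).
Deduplication keeps the first tag per (chrom, start, strand) —
the coordinate-level analogue of alignment duplicate removal — and is
idempotent. Downsampling is a uniform sample without replacement,
bit-reproducible per seed, preserving input order; the pipeline uses it
to equalize depth within each compared pair of libraries before calling,
so cross-condition peak counts are comparable. Fragment extension grows
each tag from its 5′ end to the library insert size (default 150 bp,
configurable per library; only the TF library's insert is
well-determined, so a single consistent default is applied to all).
Binned coverage counts each tag once in the bin containing its 5′
position; CPM normalization multiplies by 10⁶/total. Replicate
correlation is the Pearson r of per-region summed coverage over a
caller-supplied region list (regions < 50 bp dropped); the region
universe is deliberately an input, not a default, because there is no
canonical choice — r is undefined (an error) for < 2 regions or
zero-variance sums.

## Island (broad-domain) calling

Window size 10 kb, gap 3 — the gap counted in **windows** (30 kb),
matching SICER/Epic parameter semantics. The eligibility threshold l₀ is
the smallest count with P(X ≥ l₀ | Poisson(λ_bg)) < p₀, with
λ_bg = N·w / (G·f_eff); p₀ defaults to SICER's documented 0.2 and
f_eff (effective genome fraction) to 0.8. Islands are maximal runs of
eligible windows bridged across ≤ gap ineligible windows, never spanning
a chromosome; the island interval runs from the first to the last
eligible window. Significance is control-based: expected chip count =
island control count (floored at a 1-tag pseudocount so empty-control
islands cannot yield p = 0) × the chip/control library-size ratio;
p = Poisson upper tail; BH over all candidate islands; keep q < 0.05.
The per-island score is Σ −ln pmf(count; λ_bg) over eligible windows
(clipped at 0), reported for ranking only. Chromosome-end partial
windows keep their true width with λ unadjusted — a sub-permille effect
at both toy and genome scale. The random-background E-value mode of
SICER is not implemented: an input library is assumed, as it is the
better null whenever it exists.

## Peak calling

A deliberately simple candidate-then-compare caller, not a re-creation
of any specific tool: (1) extend tags to the insert size; (2) fragment
pileup in 50 bp bins; (3) candidate bins where the **pooled**
chip+control count clears the genome-wide Poisson tail at 10⁻⁴;
(4) merge candidates within 100 bp, drop regions < 100 bp; (5) binomial
test of chip vs control fragment counts per region with θ =
N_chip/(N_chip+N_control); (6) BH, keep q < 0.05 and require observed >
expected. Candidate selection uses the pooled count on purpose:
selecting on chip alone conditions the subsequent binomial test on
chip-high regions and inflates it (measured 17/100 null chip/control
pairs yielding a called peak); the binomial test conditions on the
pooled total, so selecting on that total leaves it exact (0/100 after
the change). Pooled selection costs some sensitivity at marginal sites —
at the default synthetic depth roughly a third of planted weak sites
stay below the FDR cut — which is the right trade for a calibrated
caller; called peaks are near-universally true sites. The post-hoc
coverage filter (≥ 400 covered bases per region, i.e. 400/75 ≈ 5.3
reads at 75 bp reads) is available for harmonizing site lists across
libraries of different origin.

## Co-occupancy statistics

Venn classification counts, for each merged set, the regions overlapping
(≥ 1 bp) any region of the other set. The A-side and B-side counts can
legitimately differ (one broad domain can span several peaks); both are
reported, the A-side count labelled as the Venn center and the
difference recorded as `center_discrepancy` rather than silently
collapsed.

The enrichment background replaces each site with a region of identical
length placed uniformly at random on the same chromosome (rejecting
placements crossing the chromosome end or an optional exclusion set).
It deliberately preserves only chromosome and length — no G/C or gap
structure — matching the plain "random regions of the same size"
construction. One draw is the default; averaging over n_draws (rounded)
is supported for variance reduction. The 2×2 table is tested with a
two-sided Fisher exact test (`scipy.stats.fisher_exact`, verified in the
test suite against exact-integer hypergeometric enumeration to < 10⁻¹⁰
on every table with n ≤ 60); the odds ratio uses a 0.5 continuity
substitution when a cell is zero. This is intentionally *not* a full
permutation test à la GAT/regioneR; the Fisher-on-one-draw design is the
analysis this package reproduces, and its null calibration is verified
(≤ 5% + 2 SE rejections over 200 null runs).

## Coverage statistics

"A W-base region surrounding a site" is read as **total width** W
centred on the site midpoint: the 10 kb lamin window spans ±5 kb, the
5 kb H3K9me3 window ±2.5 kb. Both are single config values, so the
per-side reading is a one-line change. Profile matrices store coverage
*density* (per base) on a site-centred grid, so a row sum × bin width
equals the site's windowed coverage sum exactly (conservation is a
tested invariant); sites near chromosome ends are zero-padded. Rows
follow input site order, with an optional sort by descending row sum for
heatmap export. In the fraction-higher statistic, ties count as
**not-higher** — the conservative choice, and the one that makes the
statistic reproducible on synthetic data.

## Gene assignment

Single-closest-gene: site midpoint to nearest TSS on the same
chromosome, strand-ignored, unassigned beyond 10,000 kb; ties break
lexicographically by gene id so results are order-independent.
TSS-distance bins are half-open, lower-inclusive ([0,5), [5,50),
[50,500), ≥500 kb). Fold changes are signed linear (+2 = twofold up,
−2 = twofold down) with a log2 switch (thresholds become ±1); bound
genes missing from the expression table are excluded and logged, and a
gene bound by several sites counts once. The full basal-plus-extension
regulatory-domain model of GREAT-style tools, ontology enrichment and
pathway analysis are out of scope.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition
(young/old-like) experiment, not its sequence content: a 2 × 20 Mb
genome; 8 shared + 4 young-only + 4 old-only LADs of 200 kb–1 Mb placed
non-overlapping with ≥ 50 kb separation (more than gap × window, so
distinct truth domains cannot be bridged into one island by
construction); an H3K9me3 domain nested in the central 50% of every LAD;
100 TF sites gained in the old condition — 90% inside the wholly lost
(young-only) LADs, flagged `lost_lamina`, the rest inside shared LADs as
a lamina-retained control class — plus 50 shared TF sites outside LADs;
2×10⁵ reads per library (Poisson-jittered), 75 bp reads, 150 bp
fragments. Domain libraries sample tag positions from a homogeneous
Poisson background with a 3× multiplicative rate inside the relevant
truth domains; TF libraries lay the equivalent extra read mass down as
fragments jittered around site centers (σ = fragment/2) so extended
coverage piles where a binding event would; the input is flat. Genes
(200 TSSs, uniform) nearest a gained site are upregulated (fold change
drawn from U(2.5, 6)) with probability 0.8; 5% of background genes are
strongly downregulated; everything else stays sub-threshold.

Two design points deserve a note. First, the lamina-retained gained
sites carry **no** local erosion of old-condition lamin signal by
default (knobs `local_erosion_fold`/`local_erosion_span` exist, default
off). With erosion, every gained site becomes locally lamina-lost and
the generator loses its internal contrast between lamina-lost and
lamina-retained sites — the contrast both the fraction-higher statistic
and its validation rely on. Without it, the analytic expectation of the
fraction-higher-in-young statistic is f + (1−f)/2 = 0.95 for f = 0.9
(lost sites are higher essentially always; retained sites strictly
higher half the time under the tie rule), exposed as
`TruthSet.expected_fraction_higher_young`. Second, the genome is scaled
to 40 Mb so the full pipeline runs in seconds; enrichment folds, not
absolute depths, carry the signal, so the calling statistics behave as
they would at genome scale with proportionally deeper libraries.

What passing on this generator does **not** show: robustness to G/C and
mappability bias, to fragment-size variation, to copy-number structure,
or to the heavy duplicate load of real libraries — none of which exist
in the simulation. It shows that the inference chain is correct and
calibrated when its distributional assumptions hold.

## Numerical choices

Poisson/binomial tails via `scipy.stats` survival functions (checked
against direct term summation to 10⁻¹⁰ over the relevant parameter
ranges); BH via `scipy.stats.false_discovery_control`; Pearson via
`scipy.stats.pearsonr`. Eligibility and candidate thresholds are found
by incrementing the smallest count whose tail clears the cutoff, so they
are exact integers, not continuous approximations. Merged interval
output is sorted by (layout order, start); all samplers take explicit
integer seeds through `numpy.random.default_rng` /
`SeedSequence.spawn`, and the pipeline derives fixed per-stage offsets
from its single seed, making every output byte-reproducible. Degenerate
inputs fail loudly: empty control for calling, unmerged inputs to Venn
and enrichment, zero sites for coverage statistics, zero variance for
correlation.

## Problem sizes used in validation

The test suite and the acceptance script run the generator at its
default conditions (40 Mb, 2×10⁵ reads/library) for recovery checks,
200 seeded runs for the Fisher null calibration, 100 seeded null
chip/control pairs (2 Mb, 2×10⁴ reads) for the peak-caller false-positive
check, 1,000 random eligibility vectors (≤ 1,000 windows) for island
assembly, and every 2×2 table with n ≤ 60 for the Fisher oracle. These
sizes make the whole suite complete in about a minute while keeping
every statistical check adequately powered.
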