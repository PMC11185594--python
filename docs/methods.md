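# Methods

## Mutation rates and screen saturation

A plating of N cells yielding k colonies gives a phenotypic mutation rate
r = k/N with standard deviation √k/N, treating the colony count as Poisson.
At k = 0 the reported sd is 0; the `ci` option adds an exact (Garwood)
Poisson 95% interval instead, whose upper bound at zero colonies is
3.689/N. The scale of everything downstream is set by two published
spontaneous baselines from the same canavanine assay design: a phenotypic
rate r₀ = 1.52×10⁻⁷ per cell plated, and the per-base-pair rate
m₀ = 6.44×10⁻¹⁰ per division inferred from it. The induced per-bp rate is
μ = F·m₀ with F = r/r₀ the fold induction; mutations per genome are
λ = μ·G with the haploid genome length G defaulting to 1.2×10⁷ bp (a config
constant, chosen as the conventional budding-yeast genome size); and the
per-site screen coverage μ × cells screened is the expected number of
independent mutants in the whole screen carrying a mutation at any given
genomic site. When per-strain cell counts are available the coverage is
computed per strain and averaged; with a single pooled count the pooled
product is reported. Strain and species comparisons use paired t-tests on
concentration-matched rate series and 2×2 chi-square tests on (colonies,
non-colony cells) at a single concentration; the chi-square runs without
Yates continuity correction by default (a flag enables it).

## Dose–response phenotyping

Each strain's colony size at stressor concentration c is divided by its own
no-stress (0 mM) size and capped at 1.0. The cap is forced by the assay's
ceiling: a fully resistant strain scores 1 everywhere, so the trapezoid-rule
AUC over the 0–0.8 mM copper series is exactly 0.8 mM, the maximum the
assay can report. Missing concentrations simply drop out of the trapezoid
grid; nothing is interpolated. A strain with no colony at 0 mM is
unscorable and flagged rather than silently scored.

Effect size is ΔAUC = AUC − mean(ancestral AUCs), with ancestor replicate
AUCs pooled across plates of the same ancestor strain. A mutant is a
physiological escapee — a colony recovered on selection without a heritable
resistance mutation — unless its AUC exceeds the ancestral mean by more
than three sample standard deviations (n−1 estimator); the boundary itself
counts as an escapee. The timepoint entering the AUC is configurable
(72 h by default, matching a final copper imaging day).

Edge effects on permissive plates are removed by layer normalization:
positions are grouped by their distance to the nearest plate edge (a 32×48
plate has 16 layers), and each size is rescaled by plate median / layer
median. Medians are used for robustness to the outliers QC removes; the
transform preserves the plate median and is idempotent on noise-free data.
Pleiotropic cost is growth relative to the ancestor in six permissive media
(MM/CM/YP × dextrose/glycerol) after layer correction; per condition a
one-sample t against 1 and a between-species Kruskal–Wallis are Bonferroni
corrected by the explicit family size (6). The joint effect–cost analysis
reports a per-species Spearman rho and the species × resistance interaction
p-value from a two-factor linear model.

## Genotype filtering

The six hard filters run sequentially in their listed order, each on the
survivors of the previous one, and each removal is attributed to the first
triggering filter. "Unique genotype calls" counts distinct called genotypes
and excludes missing calls, whose handling belongs to the per-lineage
missingness filter. The ancestor-disagreement filter is evaluated on called
genotypes only, so an otherwise-missing panel cannot trigger it. The
missingness filter (> 10% of an ancestor's derivatives without a call)
removes the site only for that lineage; such a site stays in the filtered
table with its lineage exclusions recorded, and does not count as retained.
The indel clause of the final filter is read allele-wise: a site is removed
when more than one distinct indel allele is each carried by two or more
strains. The genotype-quality clause removes the whole site if any strain's
GQ is below 10 (site-level reading); a per-strain masking alternative is
available behind a flag. Haploid calls are encoded homozygous; het calls at
haploid sites are retained as evidence precisely because they are the
mapping artifacts filters 2–4 target. Structural variants are filtered to
precise, high-quality singletons, keeping het singletons only for
duplications (a real duplication in a haploid maps heterozygous).
Derived calls are genotypes differing from the lineage ancestor's call;
disruptive effects are nonsynonymous, frameshift, nonsense, in-frame indel
and stop-lost.

## Karyotyping

Depth is averaged per chromosome over 1 kb windows (terminal sub-1 kb
windows weighted equally — simpler than length weighting and negligible at
this window size), excluding configured intervals such as the chromosome
XII rDNA cluster whose copy number varies independently of karyotype.
Ratios r_c are depths over the least-covered chromosome's depth; copy
numbers are round(base·r_c) with half-up tie-breaking, under base 1 and
base 2. Diploidization is flagged when more than one chromosome both fits
integers better under base 2 (|2r − round(2r)| < |r − round(r)|) and is
aneuploid there (round(2r) ≠ 2) — an algorithmic stand-in for what is
otherwise a manual-inspection call. Locus copy number is
round(interval depth / same-chromosome background) × chromosome copies.
Step boundaries are found by comparing k-window means (k = 5 by default)
across each window junction and keeping the locally strongest junction of
each run exceeding the fold threshold; partial-chromosome events are
surfaced this way for review rather than called automatically.

## Enrichment nulls

The gene null "rains" the observed number of protein-altering mutations
onto the coding genome, each hit landing in gene g with probability
L_g/L_tot (CDS lengths; mutations counted are protein-altering, so CDS is
the relevant target). Only per-gene exceedance counters against the
observed counts are kept, so memory is independent of the iteration count.
The empirical p is exceedances/iterations — the fraction of simulations
with equal or greater hits — with a below-resolution flag when no iteration
reached the observed count (the corrected value then reports the resolution
bound N/iterations); the conservative (k+1)/(n+1) estimator is available
behind a flag. Bonferroni multiplies by the per-species gene count. The
default iteration count is 10⁶; the test suite uses 10⁴–10⁵ so the whole
suite runs in seconds. No mutation-spectrum weighting is applied: UV
mutagenesis is biased toward dipyrimidine contexts, and this null
deliberately does not model that.

The aneuploidy null preserves the strain structure: each observed aneuploid
strain re-draws its observed number of *distinct* aneuploid chromosomes
uniformly from the 16, and per-chromosome strain incidence is compared to
the observed incidence. The matching exact tail is Poisson-binomial
(incidence is a sum of independent Bernoulli(a_i/16)), computed by
dynamic-programming convolution. Co-occurrence of two aneuploidies is
tested by independent uniform subset draws of the two marginals, with the
hypergeometric tail as the exact counterpart. Cross-species pooling
concatenates gene models and hit tables (orthologs sharing an id are merged
by summed length and hits) and corrects over the pooled gene count.

Monte-Carlo agreement with all three oracles within 3 Monte-Carlo standard
errors at 10⁵ iterations, null calibration (uniformity of p over seeds),
seed determinism and monotonicity in the observed count are asserted in the
test suite. The null-calibration check uses a high-granularity
configuration (expected count ≈ 500) because an exceedance p over a
strongly discrete count distribution is only near-uniform when the count
has many achievable values.

## Synthetic data

All generators draw from named substreams of a single seed, so a fixed seed
reproduces every output byte for byte and extending one generator never
perturbs another. Defaults mirror the screen's conditions: 1536-format
plates (32×48), 18 copper concentrations evenly spaced over 0–0.8 mM
(the printed range; individual values are not published, and the AUC
ceiling depends only on the endpoints), Poisson window depth with mean 30,
100 mutants with 20 escapees per dose-response pool, and six ancestor
replicates. The ancestor dose-response is a logistic decline (midpoint
0.25 mM, width 0.06 mM — smooth, monotone, reaching ~0 well before the top
concentration); a resistant mutant's curve is the ancestor's shifted right
by its true shift, drawn uniformly from 0.05–0.55 mM, and escapees
reproduce the ancestor's curve exactly apart from noise. Colony-size noise
is multiplicative lognormal parameterized by its coefficient of variation
(sizes are positive pixel counts; the real noise law is not published, so
this is a package choice). Depth noise is Poisson per window. The coverage
genome is a scaled-down 16-chromosome model (60–100 kb per chromosome):
per-chromosome means at Poisson depth 30 are then tight enough that planted
karyotypes are recovered essentially always, while tracks generate in
milliseconds.

The planted-violation genotype generator constructs, for each filter, sites
violating exactly that filter and passing all earlier ones, on a two-lineage
panel (one ancestor + 10 derivatives each), and records the expected
verdict per site. The aneuploidy fixture mirroring the screen's input uses
eight strains with chromosome counts (1, 1, 1, 1, 2, 3, 7, 2); the
original description names only three of the last four counts, and 2 is
this package's choice for the unstated fourth.

What the generators do not emulate: plate images (only size tables), raw
reads or mapping artifacts (genotype tables are constructed directly), UV
mutation-spectrum bias, spatial correlation of colony sizes beyond the
layer-structured edge effect, and batch effects between plates. Passing
recovery tests therefore shows the estimators are correct under the stated
noise models, not that those models exhaust real plate or sequencing noise.

## Numerical choices and limitations

Copy-number ties (x.5) round up. Relative sizes are capped before the AUC,
so AUC ∈ [0, c_max]. The escapee boundary is inclusive. Bonferroni factors
are explicit configuration, never inferred. Empirical p-values of 0 are
reported with their resolution bound rather than as exact zeros. The
pipeline consumes caller output (GATK-style VCFs, Delly-style SV calls,
depth tracks); variant calling, annotation and image segmentation are out
of scope, as are fluctuation-assay (Luria–Delbrück) rate estimators — the
plating-fraction estimator assumes mutants pre-exist plating at low
frequency and is the screen's own convention.
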