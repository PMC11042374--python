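# Methods

This note records the models implemented in `hybridbarriers`, their
assumptions, the defaults that matter, and the design choices made where
the design was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Ancestry coding and coordinates

Ancestry is coded per haplotype copy as 0 = *X. birchmanni*,
1 = *X. cortezi*; the diploid state at a marker is the *cortezi* dosage
(0/1/2). Physical positions are 1-based; site-index intervals are
half-open `[start, end)`. Marker panels carry genetic positions in
Morgans; linkage never crosses a chromosome boundary (the inter-site
distance at a chromosome start is infinite).

## Synthetic-data generator

The generator's defaults are the study conditions, not tuning knobs.

**Two-cluster population.** Individuals belong to a nearly pure
*birchmanni* cluster (mean *cortezi* proportion μ₁ = 0.019, SD 0.006,
weight 0.62) or an admixed *cortezi*-like cluster (μ₂ = 0.757, SD 0.017,
weight 0.38); 306 individuals and T = 50 generations since admixture by
default. Per-individual target proportions are truncated-normal draws on
[0,1]. Haplotypes follow a two-state Markov process along the genetic
map with switch rate T per Morgan and stationary frequency equal to the
target — the standard admixture-LD approximation with exponential tract
lengths, used instead of explicit pedigrees for populations this old.
Mitochondria are fixed within cluster (cluster 1 *birchmanni*, cluster 2
*cortezi*), as observed in both field clusters.

**Crosses.** F₁s are heterozygous everywhere; gametes recombine under
Haldane's no-interference model. Gametes are simulated directly as
two-state Markov chains at the marker positions with switch probability
equal to the recombination fraction `r = (1 − e^{−2d})/2` — the exact
marker-level law of a Poisson crossover process (one crossover per
Morgan per meiosis), which vectorizes cleanly; tract lists are derived
views of the site-level haplotypes and tile each chromosome copy by
construction. Viability selection at planted loci multiplies fitness
components 1, 1−hs, 1−s for 0/1/2 *birchmanni* copies and resamples
until the requested number of offspring survive (a batch guard raises if
essentially all genotypes are inviable). All F₂s carry the *cortezi*
mitochondria, the viable cross direction.

**Read counts.** Depth per individual × site is Poisson (default mean
1×, the study's coverage); conditional on depth, *cortezi*-supporting
reads are binomial with success probability ε, ½ or 1−ε by dosage
(default per-read error ε = 0.001, consistent with sub-0.1% per-site
error of the upstream pipeline).

**Mother/embryo pairs.** A mother is drawn from the population; the
father comes from her cluster with probability a (the assortment
strength) and from the other cluster otherwise. An embryo's genome-wide
proportion is the midparent value plus zero-mean segregation noise with

    σ_seg = sqrt(H / (4 B)),

where H is the expected fraction of loci at which exactly one parent is
heterozygous for ancestry (per-parent heterozygosity modelled as
2p(1−p)) and B the effective number of independently segregating blocks.
The default B = 2 × (total map length in Morgans + number of
chromosomes) counts the expected recombination-delimited segments
transmitted across both parental meioses (crossovers plus independently
assorting chromosomes); with the default 24-chromosome, 24-Morgan genome
B = 96, giving σ_seg ≈ 0.03–0.05 for admixed parents. B is configurable
because the real quantity depends on the map.

**What the generator does not emulate:** reference bias and mapping
artifacts, ancestry-informative-site ascertainment error, family
structure in the population sample, selection after the sampled
generation, and mitochondrial heteroplasmy. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
generative model, not robustness to those real-data complications.

## Local ancestry HMM

Three diploid states per site; the transition matrix is the two-copy
product of a haploid chain that retains its ancestry with probability
`e^{−T d}` and otherwise redraws from the stationary distribution
(π *cortezi*, 1−π *birchmanni*). Priors follow the study: T = 50 and
π = 0.5 for natural-population samples, T = 2 for F₂s. Emissions are
binomial in the *cortezi* read count; zero-depth sites emit 1 for every
state. The forward–backward recursion runs in log space, vectorized
across individuals; forward and backward total likelihoods are asserted
to agree within 1e−6 relative. Posteriors become hard calls when one
state strictly exceeds the 0.9 threshold, else missing; ties at the
threshold are not called. An optional pre-pass replaces π with each
individual's raw *cortezi* read fraction (clipped to [0.01, 0.99]).

The upstream dual-reference read-mapping stage of the published pipeline
is out of scope: this module starts from the AIM count table. The exact
emission/transition parameterization of the published tool is not
restated in our sources, so this is the standard admixture-LD
construction, validated by brute-force path enumeration on short chains
(agreement to 1e−8) and by hard-call error below 1% on simulated 1× F₂
data at 500 markers per chromosome.

## Dip statistic

The dip is the sup-norm distance between the empirical CDF and the
closest unimodal CDF (convex to the mode, concave after, an atom allowed
at the mode). The implementation collapses the sample to unique knots
with lower/upper ECDF corner heights and enumerates modal knots. For a
candidate tolerance t, a unimodal fit with mode at knot r exists iff

1. a nondecreasing convex function passes through the corner bands
   `[hi_j − t, lo_j + t]` at knots j < r with its limit at v_r under the
   upper band — feasible iff the prefix greatest convex minorant of the
   lower corners stays within 2t of the upper corners (deviations
   counted left of r, hull including r);
2. symmetrically for a concave function on the right via the least
   concave majorant; and
3. the two branches can meet monotonically at the mode: the minimal
   attainable convex endpoint must not exceed the maximal attainable
   concave start. These extremal values have an exact two-point
   support-chain form (descend from an upper corner, touch a lower
   corner, extrapolate), a consequence of LP duality.

A mode between knots always admits a knot-mode certificate at the same
distance, so enumerating knot modes is exhaustive. Band deviations for
all prefixes/suffixes come from one incremental hull sweep per
direction; when the junction binds, the statistic is refined by
bisection on t. The bootstrap p-value uses Hartigan & Hartigan's
Uniform(0,1) null with add-one correction `(b+1)/(n_boot+1)`; each
bootstrap sample needs only a single feasibility evaluation at the
observed dip rather than a full solve. The tests verify exact agreement
with an independent LP oracle that minimizes the sup-distance directly.

For samples with distinct values the dip lies in [1/(2n), ¼]; a sample
of equally spaced points attains the lower bound exactly, and an
all-equal sample has dip 0 (a point mass at the mode is unimodal).

## Cluster assignment

Exact 1-D two-means (best within-cluster sum-of-squares split of the
sorted sample). An individual is flagged *intermediate* when its
distance to each cluster mean exceeds max(0.05, 5 × that cluster's SD);
summaries are recomputed once excluding intermediates. The margin rule
is this package's choice — the study identified intermediates by
inspection plus pedigree simulation, which `classify_intermediate`
covers separately. Samples whose two means are closer than the margin
are refused as single-cluster.

## Assortative mating

Embryo–mother differences are classified within- vs cross-cluster at
the midpoint between the simulated |difference| distributions under
complete assortment (a = 1) and complete disassortment (a = 0); if those
distributions overlap by more than 5% at the midpoint the threshold is
refused. The assortment fit simulates, for each candidate a on an
11-point grid, replicate datasets matched to the observed mothers and
brood sizes, and scores each a by the two-sided consistency of the
observed cross-cluster call count, min(P(count ≤ obs), P(count ≥ obs)).
With zero observed cross-cluster calls this reduces to the probability
of reproducing zero calls — the natural one-sided score for the
observed data — while remaining informative when the observed count is
large; a one-sided score alone cannot recover small a. Ties break toward
larger a. Detection power for a cross-cluster mating rate r over n
sampled mothers is 1 − (1−r)ⁿ, with a Monte-Carlo cross-check.

Pedigree classification of ancestry-intermediate adults is parametric:
each class (pure cluster 1/2, cross-cluster F₁, backcross to either
cluster) is simulated as a joint (genome-wide proportion, heterozygous
fraction) cloud — heterozygosity between parents with proportions p and
q modelled as p(1−q) + q(1−p) with block-scale noise — and the candidate
goes to the class with the highest kernel density, or *unclassified*
outside every class's support (±3 SD box).

## Segregation-distortion scan

Per-site mean *cortezi* ancestry over called F₂s; sites called in fewer
than half the individuals are masked (sparse sites give noisy means).
The null envelope is family-wise: each of n_sim Mendelian replicates
contributes its genome-wide maximum |mean − ½|, and the envelope
half-width is the 95th percentile of those maxima, so 95% of null
genomes sit entirely inside. The max-statistic construction (rather than
pointwise bands) matches the genome-wide-threshold framing and is
calibrated in the tests. Peaks are delimited by R² (squared Pearson
correlation of ancestry dosage over pairwise-complete individuals)
against markers thinned to one per 50-kb window (most-called wins, ties
to the lowest position): the interval is the maximal contiguous thinned
run around the peak with R² ≥ 0.8. Intervals are reported 1-based
inclusive in the API and 0-based half-open in BED output.

## ABC for selection and dominance

Adult F₂ genotype frequencies under viability selection against
*birchmanni* ancestry are the fitness-weighted Mendelian frequencies
renormalized by mean fitness; (s, h) are drawn from Uniform(0,1)²,
N = 163 genotypes simulated per draw, and draws accepted when all three
summary statistics match the observation: heterozygote and
homozygous-*birchmanni* counts within 0.05·N individuals and mean
*birchmanni* ancestry within 0.05 absolute. The absolute-in-N reading of
"within 5%" is deliberate: a relative tolerance is undefined when the
observed count is zero, exactly the recessive-lethal case of interest.
Defaults: 200,000 draws, mandatory seed.

MAP estimates are marginal grid argmaxes (1,000 points) of a Gaussian
KDE with reflection at the [0,1] boundaries (Silverman bandwidth, floor
1e−3); reflection prevents the spurious interior mode a plain KDE shows
when mass piles at a boundary. Credible intervals are 95%
highest-posterior-density super-level sets of the same KDE, reported as
their bounding interval: unlike equal-tailed percentile intervals they
contain the MAP by construction and reach a boundary when the posterior
piles there (a percentile interval can never cover a boundary truth,
which shows up directly as under-coverage at s = 0 or s = 1 in the
recovery grid). With an empty selected-homozygote class, s and h are
only weakly jointly identified at high s; the h interval widens
accordingly, and the tests assert that width rather than pretending
precision. Marginalizing h under its uniform prior also shifts the
marginal mode of s slightly above a mid-range generating value — a
property of the model, visible in the intermediate-selection recovery
scenario. For loci whose incompatibility partner is unknown the same
single-locus model applies; if selection is actually epistatic with
another nuclear locus, s is underestimated (the report carries this
caveat).

## Mitochondrial divergence

Observed divergence is the raw p-distance over pairwise-complete
(non-N, non-gap) columns; Jukes–Cantor mapping of the simulated
substitution density onto the p-distance scale is available but off by
default, matching the raw-divergence framing. The null is a two-lineage
coalescent without migration or recombination: pair coalescence at
T_split + t_anc with t_anc exponential, mean = female_factor × N_anc
generations (female_factor defaults to 0.5: half the diploids are
females, each contributing one transmitted mitochondrial lineage);
substitutions Poisson with mean 2 μ L (T_split + t_anc). T_split, μ and
N_anc have no defaults — they are study-specific and must be supplied.
The empirical quantile of an observed divergence within the null uses
(count+1)/(n+2), strictly inside (0,1). Amino-acid differences count
alignment columns where both groups are monomorphic (ignoring X/gaps)
and differ.

## Small statistics

χ² goodness of fit uses the upper χ² tail (at df = 2 the tail is exactly
e^{−χ²/2}, used as a cross-check); zero-probability categories with
nonzero counts are errors. The two-sided exact binomial test uses the
minimum-likelihood convention, which at p₀ = ½ equals tail doubling.
Strength of preference is (t_cortezi − t_birchmanni)/(total), with
trials flagged when one side holds > 80% of the time. The Wilcoxon
signed-rank test removes zeros, midranks ties, and uses the exact
sign-flip distribution (convolution over doubled ranks) up to n = 25,
the tie-corrected normal approximation beyond.

## Problem sizes and determinism

Test and acceptance runs use reduced panels (tens to hundreds of markers
per chromosome rather than the ~10⁶-site study panel) and a few hundred
null-scan replicates; these sizes are the package's defaults for
synthetic validation and keep every property measurable at high
replication. All stochastic entry points take a seed; one root seed
spawns independent child streams per stage, and identical seeds
reproduce outputs byte for byte.

## Estimator interfaces

The fit/predict-shaped components — `AncestryHMM`, `TwoClusterAssigner`,
`AssortmentModel`, `SelectionABC` — follow scikit-learn conventions
(`get_params`/`set_params`, fitted attributes with trailing
underscores), with module-level functions as thin wrappers; generators,
the dip test, the scan and the small statistics remain plain functions,
and a click CLI (`hybridbarriers`) exposes each stage plus the
file-coupled `replay` driver.
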