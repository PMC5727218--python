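# Methods

This note documents the models and procedures implemented in `nichepop`,
the defaults they use, and the design choices made where several
reasonable options existed.

## Maximum-entropy niche model

**Model.** For a taxon with presence cells and a background sample of the
landscape, the suitability of cell *x* is the Gibbs distribution
`q(x) ∝ exp(w·f(x))` normalized over the background. The feature vector
f(x) contains, per environmental layer, the standardized value
`z = (x − μ)/σ` and its square, with μ, σ computed from the training
background and stored in the model so that projection onto any compatible
grid is reproducible. The weights maximize the penalized presence
log-likelihood

    mean_presence(w·f) − log E_background[exp(w·f)] − Σ_j β_j |w_j|

which is concave in w. It is solved by L-BFGS-B on the split
`w = u − v` (u, v ≥ 0), which renders the L1 term smooth; after the solve
the KKT moment conditions `|presence mean_j − model expectation_j| ≤ β_j`
are verified to 1e-6 and a `ConvergenceError` carrying the last gradient
norm is raised otherwise.

**Features.** Linear + quadratic only. Hinge, threshold and product
features (and the cloglog/logistic output transforms of full Maxent
implementations) are deliberately out of scope: the convex linear+quadratic
core captures unimodal niche responses, is analytically testable (a single
binary feature with presence mean 0.8 on a half/half background must yield
`w = ln 4`), and avoids the sample-size-dependent feature heuristics of the
reference implementations. The raw output (sums to 1 over the unmasked
background universe) is canonical; a min-max display rescaling is provided
and labelled as such.

**Regularization.** `β_j = reg_multiplier × sd_j(background) / √n_presences`
with `reg_multiplier = 1.0` by default — a simplified analogue of tuned
Maxent defaults that shrinks noise features at small sample sizes while
vanishing asymptotically.

**Background.** A uniform random sample of unmasked cells without
replacement, default 10,000 (all cells if fewer), seeded.

**Evaluation.** AUC is the rank-based (Mann–Whitney) probability that a
random presence outscores a random background point, ties counted 0.5,
evaluated on training presences vs the training background (no replicate
scheme is imposed). Permutation importance permutes one layer's values
jointly across the pooled presence+background evaluation points, recomputes
AUC with the fixed model, averages the drop over `n_reps` (default 10)
permutations, floors negative drops at 0 and normalizes the vector to sum
to 100 (all-zero if every drop is 0).

**Occurrence cleaning.** Exact-duplicate coordinates are collapsed, invalid
coordinates removed, and — when per-point reference coordinates are
available — points farther than 50 km (great-circle) from their reference
are rejected. Every rejection is reported with its reason.

## Niche overlap and the background similarity test

Overlap between raw surfaces uses Schoener's `D = 1 − ½Σ|qA − qB|` and the
Hellinger-derived `I = 1 − ½Σ(√qA − √qB)²`; both are symmetric, 1 iff the
maps are identical and 0 iff their supports are disjoint (`I ≥ D` is *not*
generally true and is not asserted).

The background similarity test draws, per iteration and direction, as many
pseudo-occurrences as the randomized taxon has real ones from that taxon's
Gaussian-filtered background (kernel density in great-circle distance,
default bandwidth 200 km — recorded in the result metadata since no
canonical value exists), refits the model, and recomputes D and I against
the other taxon's observed surface. 100 iterations by default. The verdict
is two-sided at α = 0.05 with α/2 per tail: observed overlap above the
97.5% null quantile is "similar", below the 2.5% quantile "divergent",
otherwise "ns". Both directions are always run and reported. A failed
refit is retried up to 3 times with a fresh draw, then recorded as missing
and counted.

## Per-cell Shannon diversity

Given K suitability surfaces on one grid, each cell gets
`H′ = −Σ_i p_i ln p_i` with `p_i = s_i/Σ_j s_j` and `0·ln 0 := 0`, so
`0 ≤ H′ ≤ ln K`. Per-cell normalization is the default because
independently fitted surfaces are not jointly normalized; the un-normalized
mode (p_i taken as given) is retained for sensitivity analysis and flagged
in the output metadata. The sign convention is the standard (non-negative)
Shannon index. Cells whose total suitability falls below `min_total`
(default 1e-12) are masked as signal-free; in scenario comparisons such
cells are tallied separately as "lost" rather than entering the difference
map.

## Population genetics

**QC.** Loci are dropped first on missingness (> 10% missing calls), then
on minor allele frequency (MAF ≤ 0.05, computed on non-missing calls; the
boundary is inclusive). The order is fixed, reported, and idempotent.

**Heterozygosity.** 100 × (heterozygous calls)/(non-missing calls) per
individual; individuals with no calls are reported as missing.

**Diagnostic SNPs.** Per locus, a two-sided Fisher exact test on the 2×2
group × allele count table; loci with p < 5×10⁻⁸ (the conventional
genome-wide threshold, applied raw — no additional multiple-testing
correction) are retained. Monomorphic loci get p = 1.

**Ritland kinship.** Per biallelic locus with allele frequency p and gene
frequencies x = dosage/2,
`r = x_i x_j / p + (1−x_i)(1−x_j)/(1−p) − 1`; the multilocus estimate is
the unweighted mean over loci where both individuals are genotyped and
0 < p < 1 (equal weights are exact for biallelic loci). Allele frequencies
come from the full analyzed sample. The estimator is unbiased around 0 for
unrelated pairs under HWE with known p (verified at 10,000 loci).

**Spatial autocorrelation.** All pairwise great-circle distances are
binned into equal-pair-count classes (default 20; the equal-count design
generalizes a fixed pairs-per-class prescription to any sample size), ties
broken by a stable sort on (distance, pair index). Per class the mean
kinship is reported, together with a 2.5/97.5% envelope from shuffling
coordinate assignments among individuals (default 100 permutations;
shuffling coordinates with genotypes fixed is the same null as the reverse
and simpler to bookkeep). The distance at which kinship first drops to ≤ 0
is reported as the zero-crossing.

**Fst.** Weir & Cockerham (1984) θ for each pair of groups: per-locus
variance components a (between populations), b (between individuals within
populations), c (within individuals), combined as the ratio of sums
`Σa / Σ(a+b+c)` over loci polymorphic in the pair. θ = 1 for groups fixed
for alternate alleles, ≈ 0 for samples from one panmictic population, and
recovers the Balding–Nichols target F of the simulator within sampling
error. θ is invariant to allele relabelling.

**Centroid summary.** Cluster centroids are coordinate-wise means of
member lon/lat — a planar approximation adequate at the regional scales
considered; member distances to the own centroid are great-circle.
Singleton clusters get distance 0 and are flagged.

## Haplotypes

Characters are extracted from an aligned sequence set over {A,C,G,T,N,-}:
substitution columns with ≥ 2 observed bases become SNP characters (N is
missing), and each distinct maximal gap-run extent becomes one binary
presence/absence character — so a 6-bp indel is a single mutational step,
matching how indels are scored in haplotype networks. Sequences identical
across all characters collapse into one haplotype; missing states match
anything, and a sequence compatible with several haplotypes joins the
largest one and is flagged, never silently assigned.

The network is the minimum-spanning network: the union of all minimum
spanning trees of the pairwise character-distance graph, computed by the
cut criterion (an edge of weight w is in some MST iff its endpoints are
disconnected in the subgraph of edges lighter than w). For low-homoplasy
organellar/ribosomal data this reproduces median-joining topologies;
median vectors (true median-joining with ε) are a documented non-goal.
Haplotypes carried by more than one sequence are labelled "major", the
rest "unique" — a reporting label only.

## Synthetic data

The generator produces every input with ground truth, and its defaults are
the study conditions under which the test suite runs:

* **Layers**: white noise convolved with a Gaussian kernel (σ =
  `autocorr_range`, default 4 cells), standardized to mean 0, sd 1; default
  40×40 grid with 3 layers. The "scenario" stack adds a constant shift
  (default 1 sd) — it preserves spatial structure while moving every cell's
  climate, which is all the projection and diversity-difference stages
  need; it does not attempt realistic climate-model covariance.
* **Occurrences**: cells sampled with probability proportional to the
  logistic of a known linear+quadratic score (default 200 points per
  taxon), jittered inside their cell; the true suitability surface is
  returned for recovery tests.
* **Genotypes**: per locus an ancestral frequency ~ U(0.1, 0.9) and
  Balding–Nichols Beta population frequencies at the target Fst (default
  0.2, 2 populations × 50 individuals × 1000 loci). With
  `ibd_strength > 0`, each individual's frequencies blend toward a
  distance-weighted mixture of population frequencies, producing a smooth
  kinship–distance decay; with `ibd_strength = 0` the model is a pure
  island model (used for Fst recovery). Missingness is completely at
  random. F1 hybrids (one gamete from each parental frequency set) and
  fixed diagnostic loci can be planted.
* **Alignments**: a random reference with planted SNP sites and one
  contiguous indel; haplotypes form a stepwise mutation chain (haplotype h
  carries the first h planted changes), so every planted character is
  polymorphic and the true network is a path. Defaults: 50 sequences of
  300 bp, 5 SNPs + one 6-bp indel, 7 haplotypes.

What passing tests on these data do *not* show: real occurrence data carry
sampling bias and spatial error the generator omits; real SNP panels have
linkage, allele-frequency-spectrum skew and non-random missingness; real
alignments can be homoplastic, which the minimum-spanning network does not
resolve the way median-joining with median vectors would.

## Numerical choices and degenerate inputs

* Optimizer: L-BFGS-B, ftol 1e-14, KKT residual checked to 1e-6;
  constant layers yield all-zero features (σ replaced by 1) and zero
  importance.
* Raw suitability sums to 1 within 1e-9 (enforced at construction).
* Raster convention: row 0 is the northernmost row (ESRI ASCII layout);
  cells are half-open `[x, x+cellsize)`, so an edge point belongs to the
  cell with the larger index; floats round-trip exactly through the ASCII
  writer (`%.17g`).
* Distance: haversine on a sphere of radius 6371.0 km everywhere; the
  50-km cleaning rule and the kinship distance classes do not warrant
  ellipsoidal precision.
* Pipeline determinism: one global seed; each stage's seed is derived by
  hashing the stage name, so skipping a stage does not shift the
  randomness of the others. Reruns are byte-identical.
* Problem sizes in the test suite (25–40 cell grids, 50–200 occurrences,
  150–1000 loci, 100 permutations/iterations) were chosen as the smallest
  at which the statistical recovery properties are stable across seeds.

## Known limitations

* No hinge/product features, cross-validated replicates, clamping or MESS
  analysis in the niche model; AUC is training AUC.
* No projected coordinate systems or GeoTIFF I/O.
* The background bandwidth (200 km) and the choice to run the similarity
  test in both directions are package defaults recorded in output
  metadata, not field-wide conventions.
* Median-joining median vectors, STRUCTURE-style admixture inference, PCA
  ordination and neighbor-nets are out of scope.
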