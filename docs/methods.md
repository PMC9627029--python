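# Methods

This note records the statistical procedures `gutsampler` implements, the
defaults it ships with and why, what the synthetic flock generator does and
does not emulate, and the numerical conventions used throughout.

## Study design the package targets

A single broiler flock of `n_birds` (default 9) is destructively sampled at
ten alimentary-tract (AT) locations per bird — crop, proventriculus, gizzard,
duodenum, jejunum, ileum, left and right cecal pouch, colon, and a cloacal
swab — sequenced to a target depth of ~30,000 16S reads per sample, with
unused swabs as extraction negative controls.  Sites carry an anatomical
ordinal (crop = 1 … cloacal swab = 9; both cecal pouches share ordinal 7).
The Methods convention in some protocols enumerates the gizzard before the
proventriculus; the physical flow order (proventriculus = 2, gizzard = 3) is
used here because the distance-decay analysis needs a physical axis.  An
explicit `ordinal` metadata column overrides the built-in convention.

## Preprocessing

**Organelle / kingdom filter.**  Features whose lineage contains
"chloroplast" or "mitochondria" (case-insensitive, any rank) or that lack a
kingdom assignment are dropped.  This can only remove rows; retained counts
are untouched.

**Contaminant scoring ("combo").**  Two independent signals per feature:

* *Frequency*: a reagent contaminant contributes a roughly constant number of
  reads per library, so its relative frequency f varies inversely with sample
  DNA concentration C.  The contaminant model `log10 f = b0 − log10 C` (slope
  fixed at −1) and the null model `log10 f = b0` each have one free
  parameter, so the fit ratio Λ = SSR_contam / SSR_null is compared against a
  permutation null obtained by shuffling concentration labels (default 1000
  permutations, one-sided: small Λ is contaminant-like).  A permutation null
  is used instead of an analytic F-type p-value: with the slope fixed, the
  models are not nested in the usual F-test sense, and the permutation null
  makes no distributional assumption.
* *Prevalence*: a one-sided Fisher exact test on the 2×2 presence table
  (negative controls vs true samples), chosen over a chi-square test because
  negative-control counts are tiny (n = 2 in the emulated design).

The two p-values combine by Fisher's method (X² = −2(ln p_freq + ln p_prev)
against chi-square with 4 df).  Features present in fewer than 3
concentration-bearing samples get no frequency p; the combined score falls
back to prevalence alone.  Flag threshold default 0.1, the customary default
for score-based contaminant callers; presence means count ≥ 1 everywhere.

**Cumulative sum scaling (CSS).**  For sample j, q is the l-th quantile of
the sample's *positive* counts under the nearest-rank-lower convention
(q = sorted_positive[⌈l·n⌉ − 1]); s_j = Σ{c_ij : c_ij ≤ q}; normalized count
= c_ij / s_j × scale.  Defaults l = 0.5, scale = 1000.  The adaptive quantile
selection of the original CSS method is not reproduced; l is a fixed,
documented parameter.  CSS is invariant to per-sample depth rescaling and
equivariant under feature permutation (both property-tested).

## Diversity

* **Shannon** H = −Σ p_i ln p_i over positive entries, in nats by default;
  the log base is a parameter since conventions differ.
* **Bray-Curtis** via `scipy.spatial.distance.pdist`.
* **Weighted UniFrac**: d(A,B) = Σ_b l_b |p_A(b) − p_B(b)| over all branches
  b, where p_X(b) is the fraction of sample X's reads on leaves below b.  The
  raw (unnormalized) variant is the default, matching the common default of
  the reference ecosystem; the normalized variant divides by
  Σ_b l_b (p_A(b)+p_B(b)).  The implementation accumulates branch
  proportions in one postorder pass and is verified against a brute-force
  branch-enumeration oracle and against scikit-bio.
* **PCoA**: classical metric scaling (double-centred −½D², `eigh`).
  Negative eigenvalues — common for non-Euclidean dissimilarities — are
  reported, never silently dropped; coordinates are returned only for
  positive eigenvalues and proportion explained is relative to the positive
  spectrum.
* **ANOSIM**: R = (mean between-group rank − mean within-group rank)/(M/2),
  M = n(n−1)/2, mid-ranks for ties.  p = (1 + #{R_perm ≥ R_obs})/(n_perm+1)
  with label permutations; when the requested permutation count meets the
  number of distinct label arrangements the null is enumerated exactly
  (via multiset permutations), which makes small-sample p-values
  deterministic.  Default 999 permutations, consistent with a p floor of
  0.001.

Distances in the pipeline are computed on CSS-normalized counts; relative
abundance can be substituted.

## Sample-size sufficiency

For each site, the replication units are birds — except the cecum, where each
pouch is its own unit (a flock of 9 birds yields 18 cecal units).  For an
ordering of units, new(k), cumulative(k) and unique(k) are plain set
operations on ASV presence (count ≥ 1).  Curves average 100 random orderings
by default (seeded); when the requested count reaches n! all orderings are
enumerated.  Averaging over orderings removes the arbitrariness of bird
numbering, in the tradition of pan-genome accumulation plots.

`new_fraction(k) = mean_new(k) / mean_cumulative(k−1)` — novelty relative to
the *running* union.  A site is sufficiently sampled at n units for
threshold t when `new_fraction(n+1) < t`.  Measuring against the running
union is the default because "x % new ASVs added" most naturally refers to
what was known before the new bird; a `denominator="final"` variant
(novelty relative to the full-flock union) is provided since the phrase is
genuinely ambiguous.  Summaries report mean/min/max over sites that reached
the threshold and list unreached sites separately; note the cecum's count is
in pouches, so site-level and bird-level means differ.

## Cecal pair similarity

* **Shared-abundance fraction**: read mass on ASVs present in both pouches,
  averaged over the two pouches' own fractions (default).  Pooled and
  min-based variants exist because the normalization of a "shared relative
  abundance" statistic is a genuine convention choice.
* **Shared-ASV fraction**: Jaccard index |A∩B|/|A∪B| of the presence sets
  (default), with a per-pouch mean variant.  Presence threshold is 1 read and
  configurable — shared-fraction statistics are sensitive to singletons.
* **Nearest-neighbour concordance**: within the cecum-only distance matrix,
  whether each pouch's nearest neighbour is its own pair mate (ties broken
  lexicographically, logged).

## Cloacal-swab proxy and site contrasts

**Distance to swab**: for each bird, the distance from every non-swab sample
to that bird's own swab; cecal pouches are averaged within bird first to
avoid pseudo-replication.  Per-site mean ± sd across birds.

**Family correlation**: one family's aggregated normalized counts per bird at
a site, correlated with the same birds' swab values.  Pearson by default
(with p from the t distribution, n−2 df); Spearman available.

**Distance-decay**: within one bird, similarity = 1 − distance for every
site pair; physical distance is the absolute ordinal gap (no centimetre
measurements are assumed).  Slope and intercept by least squares of
similarity on gap, r by Pearson, and a one-sided Mantel-style permutation p
(site-to-ordinal assignment permuted within the bird, default 999
permutations, exhaustive when feasible).  Note the effective p floor is
2/(n_perm+1), because reversing the ordinal axis reproduces the observed
gaps exactly.

**Cecal enrichment (`permutation-LFC`)**: a deliberate, surfaced substitute
for a negative-binomial Wald test — this package's purpose is the
sampling-methodology analysis, not a GLM reimplementation.  Counts are
transformed to log2(x + ε) (ε = 1) and centred within each sample; the
statistic is the cecal-minus-rest difference of group means, with a two-sided
permutation p (default 9999 permutations — with several hundred features a
1/1000 p floor cannot pass a Benjamini-Hochberg cut at α = 0.01) and BH
q-values.  The reported log2 fold change is the same centred difference, so
effect sign and test decision always agree.  The sample-wise centring (a CLR
style transform) matters: per-sample scaling factors left behind by any
normalization — CSS factors, in particular, track community evenness, which
differs systematically between the ceca and the rest of the tract — would
otherwise appear as a global pseudo-fold-change on every feature.  Alpha
defaults: 0.05 for the general analyses, 0.01 for the enrichment contrast.

## Synthetic flock generator

The generator provides ground-truthed data with the same design as the
targeted study; all parameters live in `FlockModel` and are recorded in the
ground-truth manifest, from which a flock regenerates bit-identically.

* **Site gradient**: site base log-compositions follow a directional random
  walk along the ordinal axis — each feature gets a persistent drift slope
  (scaled by `gradient_step_sd`, default 0.55) plus smaller per-site noise,
  centred on the mid-tract.  Persistent drift makes community distance grow
  with ordinal separation in each realized flock (not only in expectation),
  so distance-decay and the monotone swab-distance profile hold by
  construction; centring keeps the rank-abundance spread comparable across
  sites.  Site logs are kept on the log-relative-abundance scale so planted
  cross-site contrasts are not confounded by per-site normalizing constants.
* **Within-flock clonality**: the shared feature pool (default 560 features,
  rank-abundance spread `base_log_sd` = 1.2) splits into a *core* carried by
  every bird (`core_fraction` = 0.6) and a *flicker* pool each bird carries
  with probability drawn from `occupancy_range` = (0.3, 0.6) — the U-shaped
  occupancy-abundance pattern of real flocks.  Carried features are further
  jittered by a per-bird lognormal effect (`bird_effect_sd` = 0.45) shared
  across that bird's sites, and each bird owns `rare_pool_per_bird` = 1
  private low-abundance ASV.  This occupancy spectrum is what shapes the
  accumulation curve: a geometric-mixture decay of per-bird novelty that
  crosses the 10 % threshold around 2–3 birds and the 1 % threshold around
  6–8 units at most sites, the regime reported for real single-flock
  surveys.  A constant private pool alone cannot do this — it yields a flat
  novelty tail that never drops below 1 % — which is why occupancy, not the
  private pool, is the main clonality control.
* **Cecal pairs**: both pouches are Dirichlet-multinomial draws around a
  shared bird-cecum composition.  The Dirichlet concentration is calibrated
  at generation time by bisection on a small Monte-Carlo estimate of the
  expected shared-abundance fraction (no closed form maps concentration to
  shared mass), targeting `pair_overlap` (default 0.95).  An unreachable
  target (e.g., at very low depth) raises before any sample is drawn;
  `pair_overlap = 1` is the degenerate copy-the-pouch mode.
* **Contamination**: `n_contaminants` = 6 features appear in every true
  sample at expected frequency `contaminant_strength / dna_conc` with
  lognormal noise (sd 0.3) — exactly the inverse-concentration signature the
  frequency test assumes, so sensitivity tests are well-posed.  DNA
  concentrations are lognormal (median 12 fluorometer units, log-sd 0.5);
  negative controls get concentrations in the lowest decile, are dominated by
  the contaminant profile (90 % of mass plus 10 % cross-talk from the mean
  true community) and are sequenced shallowly (~1/10 depth).
* **Enrichment**: `n_planted_enriched` = 10 mid-abundance core features are
  set, at the cecum, to `enrichment_fold` = 8 times their rest-of-tract mean
  log-relative abundance, so the planted contrast is not confounded by each
  feature's own gradient drift.
* **Depths** are Gamma-Poisson around `depth_mean` = 30,000
  (`depth_dispersion` = coefficient of variation, default 0.1).
* **Taxonomy** is drawn from a fixed 12-lineage pool (including
  Enterobacteriaceae and Lactobacillus, so family-level operations and
  named-taxon removal are exercised); the phylogeny is a random bifurcating
  tree with exponential branch lengths over all features.

**What the generator does not emulate**: real taxon identities beyond the
label pool, chimeras and PCR/sequencing error, phylogenetic signal in the
site gradient (the tree is independent of the compositions, so weighted
UniFrac results on synthetic flocks are structurally but not
phylogenetically realistic), batch effects, and between-flock variation.
Tests passing on synthetic flocks therefore demonstrate the correctness and
calibration of the statistics under the stated generative model — not that
any particular real flock will show the same thresholds.

## Numerical conventions and reproducibility

* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` substreams (generation, pair calibration,
  tree); identical seeds give byte-identical outputs, and run outputs embed
  no timestamps.
* Permutation p-values use the add-one convention
  p = (1 + #extreme)/(n_perm + 1), with exact enumeration replacing sampling
  whenever the requested permutation count covers the permutation group.
* Distance matrices are validated to symmetry within 1e-9 and exactly
  symmetrized after validation; ties in ranks use mid-ranks; nearest-
  neighbour ties break lexicographically and are logged.
* Samples present in a count table but absent from metadata are a hard
  error — silent dropping hides labelling bugs.  All-zero samples are
  dropped (with a warning) only where an operation defines it (relative
  abundance); CSS refuses them by design.
* The test suite and the acceptance script use reduced problem sizes chosen
  for fast iteration (e.g., 100 orderings for accumulation curves, 199
  permutations inside null-calibration loops, small flocks for parameter
  ladders); each size is stated where used.

## Known limitations

* The frequency test assumes presence in ≥3 concentration-bearing samples;
  very rare contaminants are judged on prevalence alone.
* `new_fraction` thresholds are sensitive to sequencing depth through the
  detection limit; the package makes no attempt to extrapolate richness
  (no Chao/ACE) or to rarefy.
* The enrichment contrast treats samples as exchangeable under the null;
  within-bird correlation across sites is not modelled (no mixed model), so
  its p-values are calibrated for the whole-sample permutation null it
  states, not for a bird-level null.
* ANOSIM's vectorized permutation path holds an (n_perm × n) label matrix in
  memory; for very large sample sets pass smaller permutation counts.
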