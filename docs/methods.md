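# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Data model and conventions

The central object is a sample × OTU table of non-negative integer read
counts (classic TSV dialect on disk, OTUs-as-rows by default), aligned
with a rooted Newick phylogeny over the OTUs, a phylum/family/genus
taxonomy map, and per-sample metadata: age (years) and BMI (kg/m²) as
continuous covariates; sex (F/M), race (white/non-white), alcohol (Y/N),
tobacco (Y/N) and sequencing batch as categorical ones. Categorical levels
are canonicalized case-insensitively on load ("female" → F). Samples with
a missing value for the covariate under test are dropped for that test
only (complete-case per analysis). Tips present in the tree but absent
from the table are pruned before any UniFrac computation (unrepresented
lineages carry no branch mass); table OTUs absent from the tree are a hard
error unless pruning is requested explicitly.

## α-diversity: coverage standardization

Richness comparisons at unequal depth are biased, and comparisons at equal
depth still compare samples at unequal *completeness*. The package
therefore standardizes at a target sample coverage, by default the
minimum estimated coverage across samples (so no sample needs
extrapolation):

- Coverage at full depth: Ĉ(n) = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁+2f₂)], the
  bias-corrected Good–Turing estimate, with f_k the number of OTUs seen
  exactly k times.
- Coverage at smaller m: the exact expectation
  Ĉ(m) = 1 − Σᵢ (xᵢ/n)·C(n−xᵢ,m)/C(n−1,m).
- Richness at m ≤ n: the exact hypergeometric expectation
  Ŝ(m) = S_obs − Σᵢ C(n−xᵢ,m)/C(n,m); at m > n the Chao1-based
  extrapolation S_obs + f̂₀[1 − (1 − f₁/(n·f̂₀+f₁))^{m−n}] with
  f̂₀ = ((n−1)/n)·f₁²/(2f₂).
- Shannon at m < n: the exact expectation over hypergeometric subsamples,
  accumulated per frequency class with the probability mass windowed ±10
  standard deviations around the hypergeometric mean (absolute truncation
  error far below 1e-12); at m > n the blend
  H(n+j) = (n·H_obs + j·Ĥ∞)/(n+j), where Ĥ∞ is the low-bias asymptotic
  entropy estimator built from the Good–Turing adjusted tail.

All binomial-coefficient ratios are computed in log space (gammaln), so
depths of several hundred thousand reads are unproblematic. The size m\*
solving Ĉ(m\*) = target is found by monotone bisection for interpolation
and in closed form for extrapolation; extrapolation is capped at m\* ≤ 2n
(reliability degrades beyond twice the observed depth) and capped results
carry an explicit flag. Richness and Shannon are evaluated at the same
m\*; whether Shannon "should" be coverage-standardized at all is not
settled usage, so the raw per-sample Shannon remains available via
`shannon()` while the pipeline reports the standardized value.

**Singleton correction.** Sequencing errors mainly manufacture spurious
singletons, inflating f₁ and hence depressing estimated coverage. Before
any coverage computation the pipeline (by default; `--no-singleton-correction`
disables it) replaces f₁ by an estimate driven by the error-robust
doubleton/tripleton counts. The implemented closed form is the
Good–Turing/Cauchy–Schwarz ladder one rung above the Chao1 bound:

  f̂₁ = ((n−1)/n) · 2f₂²/(3f₃)  (when f₃ > 0; otherwise the observed f₁
  is kept — with f₂, f₃, f₄ all zero there is no higher-order information).

The depth is adjusted to n′ = n − f₁ + f̂₁ so Σ k·f_k stays consistent.
The correction is isolated behind `correct_singletons` precisely so that a
different estimator can be swapped in without touching anything else.

## β-diversity

Rarefaction (single seeded draw, multivariate hypergeometric, default
depth = minimum sample depth) precedes distance computation; each sample's
subsample stream is keyed by the *content* of its count vector, so
identical rows subsample identically and results are order-independent.
The number of rarefaction draws (single vs averaged) is a genuine open
choice; a single seeded draw keeps the pipeline deterministic and is the
common field default.

Unweighted UniFrac is (branch length leading only to tips present in
exactly one community)/(branch length leading to tips present in either);
weighted UniFrac is Σ_e b_e|p_A(e) − p_B(e)| normalized by
Σ_e b_e(p_A(e)+p_B(e)) so it lies in [0,1] (the raw form is available via
`normalized=False`). The edge above the root is ignored by convention —
it cannot separate the communities. Pairwise computation shares a single
edge × sample mass matrix, so full cohorts are a few matrix products.

Gower centering G = (I−11ᵀ/n)(−d²/2)(I−11ᵀ/n) and PCoA follow the
standard construction; negative eigenvalues (UniFrac is non-Euclidean) are
dropped with a diagnostic and explained fractions are relative to the
positive-eigenvalue total.

## Association tests and effect sizes

Every covariate X is tested one at a time with the model
`Microbiota ~ Batch + X + X:Batch`, *jointly* over the main and
interaction terms (the null is "no association in either batch"). The
interaction is omitted (with a warning) when only one batch level exists;
covariate columns aliased with batch are dropped with a logged report and
p is the rank increment of the full over the reduced design.

- α-diversity: OLS fits of reduced and full models; LRT statistic
  n·ln(RSS_r/RSS_f) against χ²_p (the standard large-sample
  normal-likelihood form; the exact F flavor would differ negligibly at
  these sample sizes).
- β-diversity: PERMANOVA with
  pseudo-F = [(tr(H_fGH_f) − tr(H_rGH_r))/p] / [tr((I−H_f)G(I−H_f))/(n−rank_f)].
  Projections are computed from SVD orthonormal bases, so rank-deficient
  permuted designs are handled without special cases. p-values use the
  add-one convention (1+#{F_perm ≥ F_obs})/(1+n_perm), ties counting as
  exceedances (conservative). Permutations shuffle the covariate values
  *within batch strata* by default, preserving the batch structure under
  the null; unrestricted shuffling is available (`permute_within_batch=False`)
  for parity with implementations whose default is unrestricted.

Effect size is the distance-based R² = tr(HGH)/tr(G). One R² is reported
per covariate; it is defined *sequentially after batch* — the increment
tr(H_fGH_f) − tr(H_rGH_r) over tr(G) — so batch variance is never credited
to the covariate (a marginal, batch-ignored variant is exposed via
`scope="marginal"` for sensitivity analysis). The small-sample adjustment
R²_adj = 1 − (1−R²)(n−1)/(n−p−1) may be negative; it is floored at zero
only in display columns, never internally.

## Taxon signatures

Counts are aggregated to phylum/family/genus (labels carry the phylum
prefix below phylum; unmapped ranks aggregate to "(phylum); unclassified",
and fully unmapped OTUs to "unclassified"), converted to proportions, and
filtered to taxa with prevalence > 10% *and* median nonzero proportion
> 0.05%. Each remaining taxon's √-proportion is tested with the same
joint batch-adjusted design, but by permutation F (taxon data are far from
normal); √ stabilizes variance and leaves F invariant to rescaling a
taxon. BH-FDR is controlled within each rank × covariate family (whether
the original analyses pooled ranks is unknowable; a per-family scope is
the conservative, self-contained choice). Reports carry arithmetic means
of the raw proportions per group — for continuous covariates the groups
are display-only discretizations (BMI at 30 kg/m², age at 50 y); the tests
always use the continuous values — and log2(mean_exposed/mean_reference),
with no pseudo-count: a zero group mean yields an explicit undefined value
rather than a silently shifted number. Age is excluded from the default
taxon screen (it shows no overall association and is entangled with batch
in a two-round design) but can be included by flag.

## Synthetic cohorts

The generator emulates the structure of a two-batch, ~118-subject,
~1,745-OTU gut survey; it is the package's ground-truth instrument, not a
fit to any particular dataset.

- **Composition:** Dirichlet-multinomial with log-normal base
  concentrations, σ = 2.2 and total concentration θ = 250. These defaults
  were calibrated once against the descriptive profile such surveys
  report — they give a median OTU prevalence of ~10%, ~6% of OTUs in >95%
  of samples, and ~420 detected OTUs per subject at the default depths —
  and are not revisited.
- **Depths:** log-uniform over 30,000–390,000 reads (the printed range of
  the reference cohort); configurable.
- **Covariates:** drawn from the reference cohort's marginal frequencies
  (51% female, 87% white, 68% alcohol, 14% tobacco; BMI ~ N(27.3, 4.9²)
  clipped to [16, 55], so P(BMI > 30) ≈ 0.29). Batch is assigned by
  index blocks; with two batches the first block draws ages 20–49 and the
  second 50–79, reproducing the age–batch entanglement of a two-round
  recruitment design.
- **Effects:** magnitudes are log2 fold changes (0 = exact null).
  Presence-mode effects multiply the per-sample occupancy probability
  (baseline 0.2) of a designated clade for exposed subjects; the clade is
  a random internal node holding 3–12% of tips *and* at most 2% of base
  abundance mass, so the planted signal genuinely lives in the rare
  biosphere — which is what makes the unweighted-UniFrac-dominant
  detection pattern reproducible by construction. Abundance-mode effects
  tilt the concentrations of a random 10% OTU subset; batch effects tilt
  another random subset with random signs. Exposure is the covariate's
  "active" level (Y, F, non-white) or a threshold for continuous
  covariates (BMI > 30, age > 50).
- **Seeding:** one master seed; every stochastic stage consumes a named
  substream, so stages can be re-run independently and two runs with one
  config are byte-identical.

What the generator does *not* emulate: sequencing error and chimeras,
primer/extraction bias, overdispersion structure beyond
Dirichlet-multinomial (e.g. OTU-OTU correlation networks), longitudinal
structure, or realistic taxonomy (labels are nested blocks along the
tree). Passing the validation battery therefore demonstrates that the
*statistics* behave as designed under a faithful null and a controllable
alternative — calibration, FDR control, effect-size recovery, oracle
agreement — not that any particular real-data effect size will be
reproduced.

## Validation battery (problem sizes)

The sizes below were chosen so the full battery runs in a few minutes on
one CPU; all are stated in `microdemog.validation`.

- UniFrac vs brute-force edge enumeration: 50 random trees of ≤8 tips,
  both metrics, agreement to 1e-12 (observed ~1e-16). scikit-bio's
  implementations serve as an additional external cross-check in the unit
  tests.
- PERMANOVA type-I error: 500 signal-free distance matrices (n = 50,
  Euclidean of i.i.d. normals), 200 permutations each; rejection at
  α = 0.05 must fall in the 95% binomial band [0.032, 0.072].
- Euclidean equivalence: pseudo-F equals the classical joint ANOVA F to
  1e-8 when distances are Euclidean of a scalar response.
- Effect-size recovery: presence-mode magnitudes (0, 1.5, 3), 20
  replicates each (n = 60, 200 OTUs) with common random numbers; the null
  mean adjusted R² must be within ±0.01 of zero and the three means
  strictly increasing (rank correlation > 0).
- Coverage-standardized richness: equals the exhaustive-subsample
  expectation for samples of depth ≤ 12, to 1e-9.
- FDR control: 200 replicates of 50 all-null Dirichlet taxa (n = 60, 200
  permutations); empirical FDR at q < 0.10 must stay ≤ 0.15
  (Monte-Carlo slack over the nominal 0.10).
- Membership dominance: 20 planted rare-lineage BMI cohorts (n = 70, 300
  OTUs, magnitude 2); unweighted UniFrac must give the smaller PERMANOVA p
  in ≥ 70% of replicates. This study uses 999 permutations because two
  p-values tied at the permutation floor cannot be ordered.

## Known limitations

- The singleton-correction closed form is one defensible member of the
  Good–Turing family; alternatives would change coverage targets slightly
  (never the interpolation machinery).
- Interpolated coverage Ĉ(m < n) is computed from the raw frequency
  counts even when the full-depth coverage uses the corrected f₁; a fully
  coherent corrected interpolation would require pseudo-data and is out of
  scope.
- PERMANOVA p-values assume exchangeability within batch strata; covariates
  structurally confounded with batch (constant within batches) are
  untestable by design and raise rather than returning a misleading p.
- The LRT for α-diversity is asymptotic; at very small n an exact F test
  would be preferable.
- No compositional (log-ratio) modeling, zero-inflated models, PERMDISP
  dispersion tests, or generalized-UniFrac α family — all deliberately out
  of scope.
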