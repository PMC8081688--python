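# Methods

This note documents the models the package implements, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot show.

## Relationship kernels

**Pedigree (A).** Henderson's tabular method over a topologically sorted
pedigree: diagonal 1 + ½A(p₁,p₂), off-diagonals ½(A(j,p₁) + A(j,p₂)).
Unknown parents are unrelated, non-inbred founders. Dense construction —
the package targets desk-scale populations (hundreds to a few thousand
lines), not national evaluations, so sparse Henderson inverse rules are out
of scope.

**Genomic (G).** VanRaden's method 1, G = WW′ / 2Σₗ pₗ(1−pₗ), with
W = Z + 1 − 2p on the −1/0/+1 coding and pₗ the frequency of the +1 allele
computed from the exact matrix being assembled. Monomorphic loci are
excluded from the denominator sum; their centered columns are zero, so they
contribute nothing to the numerator either. Because the columns of W sum to
zero when p is estimated from the data, G is always singular (the ones
vector is in its null space). This is harmless: the mixed-model algebra
only ever inverts K + λI with λ = σ²_e/σ²_G > 0. The fitting routine
therefore accepts positive *semi*definite kernels and rejects only
indefinite ones, with an error that suggests blending with the identity.

**Family-level genotypes.** The mid-parent row MP = ½(m + f) is the
expected genotype of a cross (equivalently its F1); the family-bulk row is
the weighted mean allele call of the family members actually pooled, which
emulates a quantitative (GBS-like) read-out of a pooled DNA sample.
Rounding to +1 / 0 / −1 at the ±0.5 thresholds emulates a discrete SNP
array call on the pool; values at exactly ±0.5 map to 0, the conservative
choice toward the heterozygous code (the rounding rule itself is stated
with strict inequalities and leaves the boundary open). Validation lines
are assigned their family's row inside W before allele frequencies and G
are computed, so training and family rows share one frequency base. Lines
of one family then have identical rows and G is exactly singular, hence
the returned kernel is G_mod = αG + βI with α = β = 0.5. Blending with
plain I treats the families as independent non-inbred founders; an I(1+F)
blend could be argued for fully inbred material but the plain identity is
used, matching the convention of the comparison the package implements.

**Single-step (H).** The genomic block is first rescaled to the pedigree
base by solving a + b·mean(diag G) = mean(diag A₂₂) and
a + b·mean(G) = mean(A₂₂) (G_adj = a + bG), then blended,
G_w = 0.95·G_adj + 0.05·A₂₂. H replaces A₂₂ by G_w and propagates the
update to non-genotyped relatives:

    H11 = A11 + A12 A22⁻¹ (G_w − A22) A22⁻¹ A21
    H12 = A12 A22⁻¹ G_w,   H22 = G_w
    H⁻¹ = A⁻¹ + [[0, 0], [0, G_w⁻¹ − A22⁻¹]]

The sign of the H11 correction is the one under which the closed-form
inverse identity holds; the equivalence of the inverse with a dense
inversion of H is tested on 100 random pedigree/G instances at 1e−8. In
the intended breeding scenario the genotyped block is the training
population and the non-genotyped block the selection candidates.

## REML and BLUP

The core model is y = Xβ + g + e, g ~ N(0, Kσ²_G), e ~ N(0, Iσ²_e). With
one eigendecomposition K = UDU′ the restricted likelihood is profiled over
λ = σ²_e/σ²_G on a log grid (65 points over 10⁻⁸–10⁸) followed by bounded
refinement — derivative-free, monotone in practice, and exact for this
model class because the transformed covariance is diagonal. σ²_G is
profiled out in closed form; a floor of 1e−10·var(y) keeps degenerate fits
finite. Predictions use

    ĝ = K[·, obs] (K_oo + λI)⁻¹ (y − Xβ̂)

for observed and unobserved ids alike; for observed ids this equals the
mixed-model-equation solution and for unobserved ids the
conditional-expectation extension — the two are algebraically identical,
and the equivalence is a test, not an assumption. Note that (K_oo + λI) is
what gets inverted, never K_oo alone, so singular kernels and duplicated
family rows pose no numerical problem.

With an identity kernel and one record per line, σ²_G and σ²_e are not
separately identifiable (the likelihood is flat in λ); recovery tests
therefore use structured kernels (genomic or family-block), where the
ratio is identified by the covariance between relatives.

**Trait-assisted model.** A secondary trait or a pre-existing record of the
target trait enters as a fixed covariate: y = μ + γx + g + e, and
GEBV = μ̂ + γ̂x + ĝ uses the candidate's own observed covariate. A constant
covariate makes γ inestimable and is rejected.

**Two-group model.** Pooling training records with candidates' pre-existing
records uses y = μ + s_h + g + e with a fixed two-level group contrast
(drop-first coding) and, by default, one residual variance per group,
reflecting the different data quality of replicated multi-environment
training records versus preliminary-trial candidate records. This
three-variance model has no diagonalizing basis, so it is fitted by
Nelder–Mead on log-variances (initialized from the homogeneous fit,
likelihood tolerance 1e−8) with a dense-Cholesky restricted likelihood.
Candidates' predictions then combine their own noisy record with
relationship information from the training group.

**Heritability.** From a homogeneous fit, h² = (σ²_P − σ̂²_e)/σ²_P with
σ²_P the unbiased sample variance of the phenotypes, clipped to [0, 1]
with a warning if estimation noise pushes it outside.

## Two-stage phenotype analysis

Stage 1 fits each trial as a randomized complete block: replicates fixed,
lines random for the genetic variance, lines fixed for the BLUEs. The mean
variance of a difference (MVD) is the average prediction-error variance of
all pairwise line-BLUE contrasts from the fixed fit's coefficient
covariance, and repeatability is h² = σ²_G/(σ²_G + ½MVD); for a balanced
r-replicate trial MVD reduces to 2σ²_e/r. Spatial row/column trend models
with autoregressive structures are deliberately not implemented — they are
orthogonal to the relationship-model comparison this package exists for —
so the trial stage assumes a randomized design. Trials with h² > 0.2
(strict) proceed. Stage 2 solves fixed line + fixed trial effects per year
(ordinary least squares, drop-first contrasts, connectivity of the
line-by-trial graph checked and disconnected designs rejected with their
components listed), then an across-year mixed model with fixed lines and a
random year effect estimated by the same profiled REML (K = Z_year Z′_year).
BLUEs are reported centered on the grand mean. The protein-yield index is
(protein % / 100) × grain yield (dt/ha), computed from across-year BLUEs;
at component means of 14.0% and 68.6 dt/ha it gives 9.604 ≈ 9.6 dt/ha,
which the acceptance script recomputes.

## Synthetic breeding program

The generator emulates the data a small line-breeding program accumulates:

- **Map**: default 21 chromosomes × 100 markers on 150 cM (2100 loci);
  tests and the acceptance script use 5 × 100 on 150 cM to stay within
  desk-scale budgets — a deliberate scaled-down study size, stated here as
  the package's own choice.
- **Founders**: fully homozygous mosaics of a pool of ancestral haplotypes
  (default 20) with exponential segment lengths (mean 50 cM). The mosaic
  induces both relatedness among founders and linkage disequilibrium along
  chromosomes; independent loci would understate the family structure that
  drives the model contrasts. Per-locus minor-allele frequencies are drawn
  uniformly within the QC-safe range (0.05, 0.5).
- **Pedigree depth**: pool lines are DH progeny of recorded crosses among
  base founders, so the pedigree connects training lines, crossing parents
  and candidates through one recorded ancestral generation. Without any
  recorded generation, pedigree-based prediction would be exactly
  degenerate (all candidate relationships zero) whenever parents are
  excluded from training — an artifact no real program with a genealogy
  shows.
- **Meiosis**: crossover counts per chromosome are Poisson with mean equal
  to the map length in Morgan and positions uniform — the Haldane,
  no-interference model. Progeny default to DH from the F1 (fully
  homozygous, matching advanced-generation line material); selfing to Fₖ
  is available, with residual heterozygosity (½)^(k−1) per segregating
  locus.
- **Trait**: N_QTL = 100 loci (default) with α ~ N(0, 1), the other
  N_SNP = 2000 markers reserved for relationship building; TBV = Qα.
  Records are TBV plus N(0, σ²_e) noise with σ²_e = σ²_tbv(1 − h²)/h²,
  where σ²_tbv is the sample variance of the population being noised —
  training and validation sets are noised at their own scales.
- **RNG discipline**: every generator takes an explicit seed; experiment
  replicates use base_seed + replicate index. All outputs are
  bit-reproducible.

What the simulator does **not** emulate: genotyping error and missingness
mechanisms of real assays (QC is exercised with injected patterns),
dominance/epistasis, genotype-by-environment interaction, selection during
line derivation, and technical pooling error beyond the explicit
overrepresentation stress test. Passing tests therefore demonstrate the
correctness and qualitative behavior of the estimators, not field-scale
performance figures.

A consequence worth knowing: with a disjoint SNP set, REML heritability
estimates from the QTL-architecture trait sit systematically below the
target (imperfect SNP–QTL linkage; "missing heritability"), by roughly
0.05–0.1 at the reduced map scale. The estimator-recovery checks therefore
draw the genetic effect from the kernel model itself, which isolates the
estimator from this data property.

## Validation designs

- **Empirical-style cross-validation**: per replicate, 45 training and 15
  validation families sampled disjointly, 4 lines each (180/60 lines),
  parents excluded, 100 replicates by default.
- **Scheme A (pre-selection)**: candidates drawn from the full progeny pool
  (30 families × 90 DH by default) or from its best fraction (0.3–1.0) by
  TBV before genotyping; training lines come from the earlier-cycle pool,
  either excluding the crossing parents or including all p of them in
  place of p random lines. Training records at h² ∈ {0.3, 0.5, 0.7} pair
  with candidate pre-existing records at {0.1, 0.3, 0.5}.
- **Scheme B (family size)**: an equal number of lines (1–5, 10, 20, 40)
  sampled per family; the family bulk pools exactly the sampled candidates,
  so one line per family makes F-BLUP collapse to a blended
  individual-genotype kernel — a tested identity.
- **Metrics**: ability/accuracy is the Pearson correlation of predictions
  with observed records / true breeding values; relative selection gain is
  the observed mean of the predicted-best fraction minus the overall mean,
  as a percentage of the absolute overall mean (the absolute value keeps
  the sign meaningful for negative-mean traits); co-selection is the
  overlap of predicted and observed top-k sets with k = ⌈fraction·n⌉ and
  ties broken by stable line-id order for determinism.
- **Model comparison letters**: pairwise paired t-tests on Fisher-z
  transformed abilities, α = 0.05 two-sided, compact letter display from
  maximal cliques of the non-significance graph. The choice of test is this
  package's documented convention; no multiplicity correction is applied
  beyond the letter-display convention itself.
- **Overrepresentation stress test**: one random member of each affected
  family receives an inflated pooling weight; as the factor grows the bulk
  row converges to that member's genotype. In the synthetic setting the
  direction of the effect on accuracy depends on scale — with small bulks a
  mildly overweighted member can even help, because its genotype carries
  real Mendelian-sampling information — and a clear mean degradation
  appears only for strong bias (e.g. factor 20 with every family biased),
  which is what the test asserts.

Within each replicate, variance components are re-estimated (refit per
replicate); candidates never contribute to training, and all metrics are
computed on the validation set only.

## Cost model

One genotyping assay is one unit of cost, for individual and pooled samples
alike — the sample-count arithmetic is only consistent under that
assumption. Full genomic strategy: every candidate (n_candidates assays).
Mid-parent: only the advanced-generation training lines, which are the
crossing parents (n_training assays). Family bulk: the training lines plus
one pooled sample per cross. The denominator of the percentage is the full
strategy's candidate count alone (1000 for the worked 100/1000/50 program,
giving 10% and 15%), not candidates + training.

## Known limitations

- Dense linear algebra throughout: fine to a few thousand lines, not for
  national-scale evaluations.
- Single-trait models only; no multi-kernel or multi-trait REML, no
  marker-effect (RR-BLUP) parameterization, no Bayesian variable selection.
- The empirical-style cross-validation approximates prediction across
  breeding cycles by resampling within one population; like any such
  approximation it flatters models that exploit within-population
  structure.
- Compact-letter significance letters are a display convention, not a
  simultaneous-inference procedure.
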