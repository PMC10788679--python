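# Methods

## Metric decomposition

For one variant, let `x` be the true alleles (haploid, 0/1) or genotype
doses (diploid, 0/1/2) over n imputed haplotypes/individuals and `y` the
imputed dosages. All variances and covariances use the population
convention (divisor n). With `p` the alternative allele frequency of the
imputed dosages (mean(y) divided by the ploidy dose):

* `Rsq = Var(y) / (d · p(1−p))` with `d = 1` (haploid) or `2` (diploid);
* `EmpRsq = Cov(x,y)² / (Var(x) Var(y))` — the regression-SS share of the
  total SS in the simple linear regression of y on x;
* `MARE = (1 − EmpRsq) · Rsq`; `β_imp = sqrt(EmpRsq · Rsq)`.

`Rsq = EmpRsq·Rsq + MARE` is then an exact algebraic identity, and
`Rsq = β_imp² + MARE` holds with β_imp defined as above; β_imp coincides
with the raw OLS slope `Cov(x,y)/Var(x)` exactly when the truth and dosage
allele frequencies agree (`Var(x) = d·p(1−p)`). The population-variance
convention is what makes the identities exact; a sample-variance (n−1)
convention would break them by O(1/n).

Degenerate cases are reported as missing values with flags rather than
dropped or crashed on: `monomorphic_imputed` (p ∈ {0,1} or Var(y) = 0,
Rsq and/or EmpRsq undefined), `monomorphic_true` (Var(x) = 0, EmpRsq
undefined), and `negative_slope` (x and y negatively correlated; EmpRsq is
still the squared correlation but β_imp is deliberately not assigned the
negative branch and is reported missing). Downstream summaries use only
unflagged records and report how many were excluded.

The diploid formulas are the scaled-binomial-variance reading: the
denominator doubles and EmpRsq correlates DS against the 0/1/2 dose;
MARE/β_imp formulas are unchanged. Phased evaluation at the haploid level
is the package default; diploid dosages are always the pairwise sum of two
haploid dosage columns.

## Copying model

The hidden state at marker m is the reference haplotype being copied
(H states). Transitions between adjacent markers use the uniform-redraw
kernel: with probability θ_m the template is redrawn uniformly over all H
haplotypes (self included), otherwise it is kept — i.e. stay probability
`(1−θ) + θ/H`, each specific switch `θ/H`. Emissions at typed markers
match the copied template's allele with probability `1−ε_m`. Untyped
markers emit nothing; a missing target allele at a typed marker is treated
as untyped for that haplotype. The imputed haploid dosage is the
posterior-weighted panel allele, `HDS(m) = Σ_h γ_m(h)·a(m,h)`.

Numerics: scaled (per-marker renormalised) forward/backward recursions, no
log-space needed; posteriors renormalised per marker; dosages clipped to
[0,1] against rounding. The per-target forward pass is stored in
memory-bounded chunks of targets (~160 MB cap), so batches of targets are
vectorised without blowing memory. Single-region operation is bounded at
1e5 markers × 1e3 haplotypes; larger inputs are rejected with instructions
to window.

Leave-one-out dosages at a typed marker are computed in the same sweep by
combining the transition-propagated forward vector (without the marker's
own emission) with the standard backward vector — algebraically identical
to re-running imputation with just that marker hidden, verified as such in
the tests.

## Parameter estimation

θ and ε are estimated from the panel alone by leave-one-haplotype-out EM:
each panel haplotype in turn is the target against the remaining H−1
(the uniform kernel then uses H−1), all markers typed. The E-step collects,
per target, the posterior probability of a template redraw in each interval
(for the uniform kernel this is available in closed form from the forward
and backward vectors) and the posterior mismatch mass at each marker; the
M-step sets `θ_i = E[#redraws]/H` and `ε_j = E[#mismatches]/H`. Iteration
stops at relative parameter change < 1e-4 or 20 iterations; the held-out
log-likelihood is recorded per iteration and is non-decreasing (EM on the
product of leave-one-out conditionals). Initial values θ=0.01, ε=1e-3 are
fixed for reproducibility. Estimates are clamped to (1e-10, 1−1e-10) and
(1e-6, 0.49). A degenerate panel (all haplotypes identical) carries no
switching information and returns floor θ with a `degenerate_panel` flag.
A pooled mode (single shared θ) is available for small panels where
per-interval estimates are noisy; provenance records which mode produced
the values. Whether production imputation software estimates ε jointly is
not documented; joint estimation with a floor is this package's choice,
and `estimate_epsilon=False` pins it.

The genetic-map route sets θ over an interval equal to its centimorgan
length (0.01 cM ↔ 1% switching rate), clamped; positions off the map grid
are linearly extrapolated from the terminal segments and logged.

## Panel simulator

Ancestral divergence follows Balding–Nichols: per-ancestry allele
frequencies are Beta-distributed around a shared base frequency
(uniform on [0.02, 0.98] by default) with variance F·p(1−p). LD comes from
a founder-mosaic process: per ancestry, a small founder set (default 20) is
drawn independently per marker from the ancestry frequencies, and every
haplotype is a founder mosaic with per-interval redraw probability
`copy_rate` (default 0.02) and per-marker flip probability `mutation_rate`
(default 1e-3). The mosaic process is exactly the generative counterpart of
the copying HMM, which is what makes the calibration and recovery
experiments well-posed. Array genotyping is emulated by a uniformly random
typed subset with both endpoint markers forced typed, so untyped sites are
always interpolations (matching how array scaffolds bracket imputed
regions). Everything derives deterministically from the `PanelSpec` seed
through named sub-streams.

The standard benchmark used across modules: two ancestries at FST 0.1,
150+150 panel haplotypes, 1000 markers, 20 founders each, copy rate 0.02,
mutation 1e-3, 30+30 held-out target haplotypes, 25% typed, seed 20240113.

What the simulator does *not* model: demographic history (growth,
admixture dating), sequencing error, indels, phasing error, and the sheer
scale of real panels (thousands of samples, 1e5+ markers). Passing the
synthetic benchmarks therefore demonstrates the *mechanism* — θ shapes
dosage certainty and Rsq while EmpRsq is insensitive; θ estimates fall
with panel size and rise with diversity — not the absolute metric values
of any real panel, which are data- and implementation-specific (absolute
total-θ values in particular are not comparable across estimators).

## Experiments and evaluation conventions

* Accuracy at typed markers is evaluated leave-one-out; untyped markers are
  evaluated against held-out truth. Summaries pool both; per-variant tables
  carry a `typed` column so either surface can be read separately.
* Threshold counts use strict inequalities exactly as conventionally
  printed: confident alleles HDS > 0.9, high-Rsq variants Rsq > 0.7 (with
  0.3 available as the conventional global filter).
* MAF bins: common (MAF ≥ 5%), low-frequency (0.5% ≤ MAF < 5%), rare
  (0.1% < MAF < 0.5%), doubleton (MAC = 2), singleton (MAC = 1); MAC rules
  take precedence at MAC ≤ 2.
* The deviation is always oriented Rsq − EmpRsq. Binned bootstrap CIs
  resample variants (not samples) within bins, 1000 draws, 2.5%/97.5%
  quantiles; both EmpRsq-bin and Rsq-bin axes are supported since either
  can be the natural diagnostic axis.
* Replicated θ-estimation studies redraw the subpanel from a larger
  simulated pool per replicate (ancestry proportions preserved). The
  estimator here is invariant to sample order, so literal order shuffling
  would produce zero replicate variation; subset redrawing reproduces the
  intended variation at the level that matters.
* Scale choices for the shipped studies (chosen once as desk-scale study
  conditions): trend studies use 150-marker regions, pools of 1000
  haplotypes, 10 replicates, EM capped at 4 iterations (the trends are
  driven by the E-step statistics and stabilise within a few iterations);
  recovery and calibration use 300–800 markers with full EM settings.

## Design decisions that were genuinely open

* `p` in the Rsq denominator comes from the imputed dosages (the metric's
  own convention); an override argument allows truth-frequency sensitivity
  checks.
* β_imp's negative branch is reported missing rather than negative —
  negative slopes indicate a broken imputation rather than a quality level.
* Haploid targets only (pre-phasing is out of scope); diploids are two
  haploid columns paired at I/O time.
* VCF writing is hand-formatted text (3-decimal DS/HDS) so the printed
  precision is an exact contract; reading goes through pysam/htslib.
  Biallelic SNVs only, strict validation, fail-fast with the offending
  position.

## Known limitations

* The EM estimator is a surrogate for production parameter estimation, not
  a reimplementation of any specific tool's internals; absolute θ values
  differ from other estimators even on identical data.
* No state-space compression: panels beyond ~1e3 haplotypes per region are
  rejected rather than approximated.
* Unphased-diploid dosage r² differs slightly from haploid EmpRsq; the
  package evaluates at the haploid level and does not model that gap.
* Metric means across conditions are computed over each condition's
  defined-metric variants; at extreme θ scalings (100-fold) many variants
  become monomorphic-imputed and the evaluation set shrinks accordingly
  (counts are reported alongside).
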