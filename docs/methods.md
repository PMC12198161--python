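# Methods

## The estimation problem

The package estimates receptor-level quantities — the agonist–receptor
dissociation constant K_d (fitted as logK_d, log10 molar) and the fraction
q of receptors left operable after partial irreversible inactivation —
from concentration–effect curves alone. The SABRE model supplies the
curve family:

    E/Emax = q·ε·γ·cⁿ / ((q·ε·γ − q·ε + 1)·cⁿ + K_dⁿ)

with ε the receptor-activation efficacy (0–1), γ the post-receptor gain
(dimensionless; amplification when γ > 1), n a Hill-type slope and q = 1
on naïve tissue. Two structural facts drive everything else:

* q and ε enter only as the product q·ε, so a partial agonist
  (ε < 1) and a receptor-depleted full agonist (q < 1) produce *identical*
  curves — depletion data cannot tell them apart, and the pipeline fixes
  ε = 1 for known full agonists rather than pretending to estimate it.
* For n = 1 the curve is an exact hyperbola with asymptote
  q·ε·γ/(q·ε·γ − q·ε + 1) and EC50 = K_d/(q·ε·γ − q·ε + 1). At high gain
  the asymptote saturates near 1 and the EC50 collapses to K_d/(q·ε·γ):
  a single curve then constrains only the ratio K_d/γ. This is the ε·γ
  (or γ–K_d) identifiability ridge; fits along it are flat to first order
  and must be detected, not papered over.

## Global fitting

`fit_global` pools unweighted residuals on the fractional-effect scale
across datasets; each model parameter of each dataset resolves to a named
slot that is fixed, free, or shared by a group. Scale parameters (γ, τ)
are optimised as log10 values; binding affinity as logK_d. Bounds:
ε ∈ [10⁻⁶, 1], q ∈ (10⁻⁶, 1], γ and τ ∈ (10⁻³, 10⁶) on the log scale,
n ∈ (0.2, 5], logK_d within the pooled concentration range ± 3 decades.
Initialisation is deterministic: γ and τ start at both 1 and 100 (the
cartesian product over such parameters gives the multi-start set), logK_d
at the Hill-fit logEC50 of the relevant naïve curve, q at 0.5; the start
with the lowest SS wins, ties to the first start. The inner minimiser is
scipy's trust-region-reflective least squares with a 10⁻¹⁰ relative-SS
convergence tolerance and a bounded iteration budget per start. Nothing
in the fitting path is stochastic; seeds exist only in the synthetic-data
generator.

The four strategies encode sharing schemes over the 3-agonist × (N, X)
study (Eq. with q = 1 on N curves, free shared q on X curves):

1. all six curves, γ shared everywhere, q shared among X, logK_d free per
   curve (6);
2. the three N curves only, γ shared, logK_d per curve;
3. one agonist pair at a time: γ and logK_d shared within the pair, q free
   on the X curve;
4. all six with each agonist's logK_d *fixed* to the strategy-3 estimate,
   leaving only shared γ and shared q.

Each has an initial stage with ε and n free (shared) and a final stage
with ε = n = 1; the final stage is the default and is what the drivers
and acceptance checks run. Strategies 1 and 2 intentionally reproduce the
ridge failure (dependency 1, open CIs); 3 breaks the ridge through the
within-pair asymptote contrast; 4 gives the sharpest shared estimates.

The operational-model comparison fit mirrors strategy 3: n = 1, logK_d
shared within the pair, τ free per curve. Under receptor depletion with
linear stimulus scaling, τ_X/τ_N estimates q.

## Diagnostics

* **Dependency**: 1 − 1/VIF_i with VIF_i from the inverse correlation
  matrix of the Gauss–Newton covariance (JᵀJ)⁻¹, computed in the
  numerically equivalent form "uncentred R² of Jacobian column i on the
  others", which stays finite and → 1 under exact collinearity.
  Thresholds: > 0.9 high, > 0.99 unacceptably high, > 0.9999 ambiguous
  (flags the whole fit). A single free parameter has dependency 0. This
  VIF construction is a declared definition; the proprietary software the
  thresholds originate from does not publish its exact formula.
* **Asymmetrical CIs**: profile likelihood. A bound for parameter θ is
  where the SS, re-optimised over all other free parameters, crosses
  SS_min·(1 + F(1, N−p; level)/(N−p)); a side that never crosses inside
  the parameter's bounds is reported open (`None`, rendered "?"). Profile
  intervals are transformation-equivariant, so log-scale parameters are
  profiled internally and reported on the natural scale.
* **Bands**: first-order (delta-method) propagation of the covariance
  s²(JᵀJ)⁻¹ through the model gradient with a t quantile; the prediction
  band adds s² under the same quantile and therefore encloses the
  confidence band pointwise. Exact second-order bands are out of scope.
* **AICc**: n·ln(SS/n) + 2k + 2k(k+1)/(n−k−1) with k = free parameters
  + 1 (the residual variance); the +1 convention matters only if compared
  fits counted k differently, and here both models are counted
  identically. Akaike weights exp(−Δ/2)/Σ are reported as "relative
  probability of correctness" percentages.

## Normalization

All effects are expressed as percent of the *system* maximum, defined as
the largest Hill-fit Emax among the naïve curves (Emax, logEC50, nH all
free; three deterministic starts; unweighted on means — SEMs are carried
as metadata, with optional SEM weighting off by default). Only naïve
curves compete for the maximum: inactivated curves cannot define the
system ceiling.

## Furchgott's method

Equieffective concentrations are read off *fitted* Hill curves (raw grids
rarely align), 12 levels spanning 10–90% of the lower curve's maximum to
avoid the asymptote region; (q, K_d) come from OLS of 1/A on 1/A′. The
double-reciprocal transform concentrates leverage in the lowest-effect
pairs, so under realistic noise the intercept — hence K_d — can turn
inadmissible (≤ 0) for an individual agonist even when the slope (q) is
sensible; this is raised as an estimation failure and recorded per
agonist by the pipeline rather than silently clipped.

## Synthetic studies

The generator emulates the target design: 3 agonists × (N, X), 10
log-spaced concentrations from 1 nM to 100 μM, 5 replicates per point,
i.i.d. Gaussian noise of SD 0.03 (fraction of system maximum) on each
replicate, truncated at zero; stored are the per-point mean, SEM
(sample SD/√reps) and replicate count. Truncation introduces a small
positive bias only where the true effect is within ~2 SD of zero —
accepted at the default SD and excluded from the noise-model tests.
Dataset i draws from `SeedSequence(seed, spawn_key=(i,))`, so each curve
is reproducible in isolation. Defaults take the published final estimates
for the emulated system as ground truth: per-agonist logK_d (NECA −5.88,
CPA −5.93), shared γ = 86.84 and shared q = 0.22; pairwise reference
values (NECA γ = 66.86, q = 0.31; CPA γ = 136.8, q = 0.17) serve
single-agonist scenarios. The CHA pair values (logK_d = −5.50, γ = 100,
q = 0.25) are package defaults declared inside the published per-agonist
ranges (γ 66–137, q 0.17–0.31), the individual CHA estimates not being
available for transcription; no headline quantity depends on them.

What the generator does *not* emulate: contractile-force time series,
baseline drift, heteroscedastic or correlated errors, pacing artifacts,
FSCPX washout kinetics. Tests passing on this generator therefore
demonstrate correctness of the estimation machinery under the stated
noise model, not robustness to every pathology of real atrial data.

## Simulation grid

`simulate_grid` crosses ε ∈ {0.17, 1} with γ ∈ {0.3, 1, 136.8} at
n = 1, logK_d = −5.93 over 20 log-spaced concentrations (10⁻¹⁰–10⁻³ M, a
range wide enough to resolve the high-gain left shift; the grid choice
does not affect any of the closed-form equivalences). The Hill refits of
these noise-free unit-slope curves are exact (SS < 10⁻¹⁶), quantifying
how amplification both left-shifts the EC50 (K_d/γ for a full agonist)
and lifts a weak partial agonist's maximum from 0.17 to 0.97.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at its native
desk scale: six 10-point curves per study, 400 Monte-Carlo replicates for
the profile-CI coverage check (95 ± 4% band), 9 replicates per rung of
the noise-ladder consistency check. Degenerate inputs are handled
explicitly: all-zero curves refuse a Hill fit; zero-residual fits
collapse CIs and bands to the point estimate/curve; rank-deficient
Jacobians yield dependency 1 and the ambiguous flag instead of an
exception. Percent effects live at the I/O boundary, fractions
internally; the conversion is a single factor of 100.

## Known limitations

* Dependency and bands are first-order (Jacobian-based); strongly curved
  SS surfaces may understate uncertainty even when dependency is low.
* The profile-CI walker caps its bracket expansion at the parameter
  bounds; a CI side genuinely beyond the bounds is reported open rather
  than extrapolated.
* AICc comparison assumes both models were fitted to identical
  observations by unweighted least squares; no nested-model F tests are
  offered.
* Furchgott estimation inherits the classical method's leverage
  sensitivity (see above); its q is more robust than its K_d.
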