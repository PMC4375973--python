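# Methods

## The model

Chemical-shift restraints enter structure simulations through a hybrid
energy, E_hybrid = w·E_data + E_physical.  Rather than fixing the restraint
weight w empirically, the inferential-structure-determination (ISD) view
treats the prediction error of each nucleus class j ∈ {Cα, Cβ, C, N, H, Hα}
as a random variable with an unknown positive scale, and samples those
scales alongside the structure.  Writing Δδ_ij = δ_pred,ij − δ_exp,ij and
χ²_j = Σ_i Δδ²_ij, the joint posterior over structure X and scales θ
factorises over classes, and its negative logarithm (in units of k_B·T,
additive constants dropped) is the hybrid energy this package evaluates:

* **Gaussian + Jeffreys prior** p(σ_j) ∝ 1/σ_j:
  E = Σ_j [(n_j+1)·ln σ_j + χ²_j/(2σ_j²)] + E(X)/k_BT,
  with MAP σ²_j = χ²_j/(n_j+1).
* **Gaussian + conjugate prior** σ²_j ~ Inverse-Gamma(α, β):
  E = Σ_j [(n_j+2α+2)·ln σ_j + (2β+χ²_j)/(2σ_j²)] + E(X)/k_BT,
  with MAP σ²_j = (2β+χ²_j)/(2α+2+n_j), strictly positive for β > 0.
* **Gaussian, σ marginalised**: E = Σ_j (n_j/2)·ln χ²_j + E(X)/k_BT.
* **Cauchy + Jeffreys prior** (Student's t, ν = 1):
  E = Σ_j [(n_j+1)·ln γ_j + Σ_i ln(1+(Δδ_ij/γ_j)²)] + E(X)/k_BT.

Log-likelihood functions keep their full normalisation constants (so unit
integrals are testable); energies drop constants (what a sampler needs).
The physical energy E(X) is a pluggable callable and defaults to zero:
force fields and shift predictors are out of scope, predicted shifts arrive
as data.

The Cauchy family is the robust alternative: a single 10 ppm outlier at
unit scale costs ln(101) ≈ 4.6 k_BT instead of the Gaussian's 50 k_BT, so
sporadic gross mispredictions (known to occur for Hα) do not dominate the
fit.  The Cauchy likelihood does not reduce to a function of χ², which is
why summary-only inputs (n_j, χ²_j pairs) are accepted by the Gaussian
family only.

## Sampling the scales

The single move in uncertainty space is multiplicative: ξ' = ξ·exp(z),
z ~ N(0, σ_μ²), with σ_μ = 0.1 by default (rapid, stable convergence for
both families).  A multiplicative proposal is asymmetric in ξ, so the
Metropolis–Hastings test includes the log-correction ln(ξ'/ξ) = z; the
chain's stationary density in ξ is then exactly exp(−E(ξ)).

Which variable plays the role of ξ follows the measure the prior is written
in.  The Jeffreys prior is a density in the scale itself, so for the
Jeffreys-Gaussian and Cauchy families ξ = σ_j (or γ_j).  The conjugate
prior is a density in the *variance*, and the conjugate energy above is the
negative log of the σ²-posterior expressed in σ symbols; there one ξ-move
multiplies σ² by exp(z) (the scale by exp(z/2)).  With this convention the
conjugate chain's stationary law is σ²_j ~ Inverse-Gamma(α+n_j/2, β+χ²_j/2)
— the analytically known posterior — which the exact sampler
`gibbs_exact_conjugate` draws i.i.d. and the test suite compares against by
a two-sample Kolmogorov–Smirnov test.  Either mishandling the Hastings
factor or mixing up the measure shifts the stationary shape parameter by
1/2 (a ~2 % shift of the posterior mean), which those tests detect.

Each frozen-mode step updates one populated class chosen uniformly at
random; the per-class posteriors are independent, so the schedule only
affects mixing.  Scales start at 1 ppm; the burn-in absorbs the transient.
Statistics are taken over the final fraction of the chain
(`burn_in_fraction` = 0.9 by default, i.e. averaging the last 10 %,
mirroring the convention of averaging the last 10⁶ of 10⁷ steps).  Standard
errors use batch means with 50 batches, which stays honest under
autocorrelation (the integrated autocorrelation time at σ_μ = 0.1 is ~25
steps for the conjugate target).

## Fixed weights

For fixed-weight operation the package ships the per-class maximum-
likelihood scales from the CamShift training set, by preset name:
`camshift-trainingset-gaussian` σ = {Cα 1.22, Hα 0.26, N 2.78, H 0.56,
C 1.12, Cβ 1.19} ppm and `camshift-trainingset-cauchy` γ = {Cα 0.70,
Hα 0.19, N 1.87, H 0.31, C 0.74, Cβ 0.77} ppm.

## Data handling

Pairing of experimental and predicted tables is by exact
(residue_index, nucleus) key; records present in only one table are ignored
and counted in a log line, and residue-type disagreements between matched
records warn rather than fail (deposited files often disagree on tags).
Isoleucine Cβ pairs are excluded by default: predictors whose side-chain
bond geometry is frozen mispredict Ile Cβ by several ppm, so those
deviations measure a modelling artefact, not the error law.  Glycine (no
Cβ) and proline (no amide H) need no special casing — pairing handles
absence naturally.  The minimal NMR-STAR reader consumes only the
`_Atom_chem_shift` loop columns Seq_ID/Comp_index_ID, Comp_ID, Atom_ID and
Val; atom IDs H, HA, HA2 map to the H/Hα classes (HA3 and all other atoms
are skipped and counted), C/CA/CB/N map directly.  The amide-H convention
(H means backbone amide proton) follows standard predictor usage.

## Synthetic data

The generator draws predicted shifts around typical per-class baselines
(Cα 56, Cβ 35, C 176, N 119, H 8.3, Hα 4.3 ppm, spread 1.5 ppm) and sets
experimental = predicted − noise, so the recovered Δδ equal the drawn noise
exactly.  Baselines cancel in Δδ and are cosmetic.  One noise family
(Gaussian or Cauchy) applies to all classes per data set, with true scales
defaulting to the training-set values above; residue types are uniform over
the 20 amino acids so the structural absences and the Ile-Cβ filter are
exercised by construction.  An optional contamination mechanism adds ±5 ppm
spikes to a chosen fraction of deviations (default 0), emulating
outlier-prone classes.  What the generator does **not** emulate: secondary-
structure-dependent shift surfaces, correlated errors along the sequence,
referencing offsets, or any structure → shift mapping.  Passing recovery
tests therefore demonstrates correctness of the inference machinery under
the stated error laws, not predictor realism.

## Problem sizes and numerical choices

Parameter-recovery runs use 500 residues per class (posterior s.d. ~2 % of
the scale) and chains of 2.4×10⁵ steps; the headline frozen-chain
computation uses 2×10⁶ steps with burn-in fraction 0.5, giving the 10⁶
averaged post-burn-in steps of the published convention at a fraction of
the 10⁷-step original run.  χ² accumulation uses compensated (fsum) or
pairwise (numpy) summation.  Degenerate inputs follow each variant's
character: the Jeffreys MAP at χ² = 0 returns σ = 0 with a warning, the
marginal energy raises (its integral diverges), and the conjugate MAP stays
positive.  Quadrature oracles in the tests integrate in ln-scale with the
peak value factored out, since the integrands span hundreds of orders of
magnitude.

## The Jeffreys pathology and its demonstration

With a maximally flexible structure surrogate — the predicted-shift vector
itself, random-walked with width 0.1 ppm — the Gaussian/Jeffreys joint
posterior rewards χ² → 0 without bound: the chain ratchets the misfit and
σ down together until the surrogate freezes.  The demonstration (24
Cα shifts, 10⁶ steps) flags collapse when some class reaches σ < 0.01 ppm
with χ² < 10⁻³ ppm².  The conjugate prior removes the singular mode: its
scale is floored near √(2β/n) and the chain never collapses.  Stationarity
is additionally assessed by requiring the mean of ln(scale) over the two
halves of the averaging window to differ by less than 0.2.

A known limitation of this flat toy: for the conjugate model the marginal
law of χ² above its floor is close to log-uniform (radially
∝ r^(−1−2α) with α = 0.001), so ln σ wanders slowly over a wide range even
though it never collapses — the two-halves drift statistic is therefore
noisy for the conjugate family and can exceed 0.2 depending on the run,
while the collapse/no-collapse distinction is robust.  In real structure
simulations, conformational entropy and the force field pin χ², which is
why sampled conjugate scales are stable in practice; the optional
physical-energy hook of the toy sampler can emulate such pinning.

## Other limitations

No Student's-t generalisation beyond ν = 1 and ν = ∞, no per-residue
weighting, no re-referencing of deposited shifts, no structural move sets
or replica exchange — the sampler covers uncertainty space only, with the
structure surrogate of the toy mode as the single deliberately minimal
exception.
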