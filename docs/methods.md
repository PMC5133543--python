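# Methods

This note records the models implemented in `incellfold`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Maximum-entropy reconstruction of NUS spectra

A 2D plane is acquired on a regular `n1 × n2` complex grid of which only a
pseudo-random subset (the sampling schedule) is measured; the first
increment (0, 0) is always kept. The reconstruction `h` is a real,
non-negative intensity grid minimizing

    C(h) = L(h) − λ S(h),
    L(h) = ½ Σ_{p∈schedule} |IDFT(h)_p − D_p|²,
    S(h) = Σ_i [h_i − A − h_i ln(h_i / A)].

`L` is kept in raw intensity units. The Gaussian measurement model
(per-component noise σ) enters the posterior as `exp(−(L − λS)/σ²)`, so the
multiplier λ carries the noise variance: re-analyzing noisier data demands
a larger λ for the same entropy weight. The default level is `A = σ`
(estimated if not given); the entropy gradient diverges at `h = 0`, so the
minimum is interior and a floor of `10⁻¹⁰ A` suffices for positivity.

*Optimization.* Bound-constrained L-BFGS with the analytic gradient
(`∇L = Re FFT(residual)/n`, `∇(−λS) = λ ln(h/A)`), relative tolerance
10⁻⁶ for stand-alone use. A first-order projected-gradient scheme was
tried first and abandoned: it stalls far from the optimum on the
ill-conditioned small-λ problems that the evidence scan must solve,
corrupting the λ selection.

*Automatic λ.* The evidence is Laplace-approximated with a diagonal
Hessian,

    log p(D|λ) = −C(h*)/σ² + ½ Σ_k log(2π / H_kk) + (n/2) log(λ_p / 2πA),

with `H_kk = m/(n²σ²) + λ_p/h_k` and `λ_p = λ/σ²` the prior precision of
the probability model. The last term is the per-bin normalization of the
entropy prior (`Z_S^{1/n} ≈ sqrt(2πAσ²/λ)` by Laplace at `h = A`); without
it the evidence is monotone in λ and has no interior maximum. Selection
scans 13 log-spaced λ values over `(10⁻⁴, 10⁴)·σ²` and refines the best
interior bracket by golden-section search on log λ; the inner solves are
tightened to 10⁻¹⁰ because evidence differences near the optimum are tiny
relative to C. A non-unimodal scan returns the grid argmax with a warning.
This selector implements the evidence-maximization principle, not any
published closed form.

*Peak picking* takes 8-neighborhood local maxima above a noise multiple
and converts bin indices to ppm through the axis metadata
(`ppm(i) = carrier + (size/2 − i)·sw/size/obs`).

*Noise estimation* is the scaled median absolute deviation (×1.4826) of
the real and imaginary parts of the half of the sampled points with the
largest normalized index sum, where the decaying signal contributes least.

## Polypeptide model

Conformations are parameterized by rotatable torsions only: backbone φ/ψ
(φ undefined for residue 1; ψ of the last residue orients its carbonyl)
and side-chain χ1/χ2. The peptide bond ω is fixed trans (180°); deeper
side-chain torsions are frozen at ideal-template values. Bond lengths,
angles and fixed torsions come from a text geometry table measured on
ideal residue templates (Chemical Component Dictionary), so a build with
template internal coordinates reproduces those templates exactly,
including L-chirality. Seventeen residue types are supported; proline
(cis/trans and ring closure coupled to φ), cysteine and methionine (S–C
bonds fall outside the table's length invariant) are rejected with a clear
error.

Coordinates are built by sequential NeRF placement in a canonical frame
(N₁ at the origin, Cα₁ on +x, C′₁ in the xy-plane); the build is exactly
invertible (`measure ∘ build = id` to < 10⁻⁶ deg, property-tested) and
local (torsion k moves only downstream atoms).

*Prior energy.* The conformational prior is deliberately simple:

    E = k_rep Σ_{nonbonded heavy pairs} max(0, r_min,ij − r_ij)²
      + k_tor Σ_{rotatable torsions} (1 + cos 3θ),   [k_B T units]

with `r_min,ij = 0.85 (r_i + r_j)` from core radii H 1.0, C 1.55, N 1.40,
O 1.35 Å, reduced to a 0.70 factor for atoms three bonds apart, and pairs
up to two bonds apart excluded; defaults `k_rep = 1.0 Å⁻²`,
`k_tor = 0.2`. The 0.85/0.70 scales were set so that ideal secondary
structures and staggered rotamers are exactly clash-free (soft-core
convention). This term plays the role of prior information in the Bayesian
model — it is not a molecular-mechanics force field, carries no
electrostatics or solvation (the bulk-water dielectric 78.5 is recorded as
a constant but unused), and no claim of energetic realism is made. Because
the posterior is data-dominated wherever restraints exist, this simplicity
costs little in the regimes the package addresses.

## NOE interpretation

Matching is exhaustive over ordered proton pairs within 0.04 ppm per ¹H
dimension (0.4 ppm would apply to heavy dimensions; the simulated NOESY
classes are 2D ¹H–¹H lists). The network-support filter keeps an option
linking residues (i, j), |i−j| ≥ 2, only if at least `min_support` other
peaks link residue pairs within ±1 on both sides — a deliberately simple
surrogate for network anchoring that removes isolated spurious long-range
options; `min_support = 0` disables it.

Calibration uses `upper = clip((C/I)^{1/6}, 2.4, 6.0) Å` (van der Waals
contact to NOE detection limit). Auto-calibration solves
`C = median(I) · 4⁶` so the median calibrated distance is 4.0 Å, a
mid-range target for observable NOEs; both the target and the clip window
are configurable. Long-range means |i−j| ≥ 5, sequential 1, medium 2–4.
Hydrogen-bond restraints are never generated. The target function is the
sum of squared bound violations of effective distances plus dihedral
interval violations weighted by 0.0025 Å²/deg² (a 5° torsion violation
counts like a 0.25 Å distance violation).

## Annealing

Torsion-angle dynamics is replaced by multi-start Metropolis annealing —
the same search role at a fraction of the complexity. Energy =
target function + 0.05 × prior energy; geometric temperature schedule
50 → 0.1 (target units) and single-torsion move width 30° → 2° over the
run; best-so-far state retained per trajectory. Defaults are 100 starts ×
10000 steps; the tests and acceptance runs use 10 × 4000, which suffices
on the 12-mer scenario (the refinement stage does the precision work).
Per-start seeds derive from the master seed and the start index, so runs
are reproducible and starts independent.

## Bayesian refinement

The joint posterior is

    log π(X, c, σ) = Σ_s Σ_{k∈s} [ −(ln I_k − (c_s − 6 ln r_eff,k(X)))² /
                        (2σ_s²) − ln σ_s ]
                   + Σ_s ln N(c_s; μ₀, τ₀²)
                   + Σ_s ln IG(σ_s²; α₀, β₀) − E_prior(X).

The likelihood is normal on *log* intensities: this choice makes the
stated normal/inverse-gamma priors exactly conjugate, respects intensity
positivity, and matches the multiplicative noise of the simulator. The
conjugate conditionals are

    c_s | · ~ N( (μ₀/τ₀² + Σ(ln I + 6 ln r_eff)/σ_s²) / ρ , 1/ρ ),
              ρ = 1/τ₀² + n_s/σ_s²,
    σ_s² | · ~ IG(α₀ + n_s/2, β₀ + SS_s/2),

verified against 1-D quadrature to 10⁻⁶ in mean and variance. Defaults:
τ₀ = 2 (log units), α₀ = 2, β₀ = 0.5, and μ₀ centered on the
auto-calibration constant — weakly informative on the scale the data
themselves suggest.

Sampling is replica exchange over a geometric ladder (default 4 replicas
at desk scale, 10 × 300–400 K available via config), tempering the full
log-posterior with β_k = T₁/T_k. Each segment runs a compiled
single-torsion Metropolis sweep, with probability 0.2 one collective MALA
move over all torsions (finite-difference gradients, proposal-asymmetry
correction — the surrogate for a molecular-dynamics leg), then tempered
Gibbs updates of (c_s, σ_s); adjacent replicas then attempt swaps with
acceptance `min(1, exp((β_i − β_j)(U_i − U_j)))`, `U = −log π`. Snapshots
are recorded from the 300 K chain at every exchange boundary;
`burn_and_thin` keeps every stride-th recorded step after burn-in (the
stride must be a multiple of the record interval). All random streams
derive from `(master seed, replica, segment)`, so the replica count does
not perturb per-replica reproducibility. A scalar variant of the same
scheme (`run_rexmc_scalar`) exists solely to validate the sampler against
closed-form posteriors.

Desk-scale defaults (4 replicas × 2·10⁵ steps, exchange every 100) give
healthy exchange rates (0.1–0.5 on the hairpin scenario) and, on noiseless
data, recover the reference fold to ≈ 0.03 Å backbone RMSD and the true
ln C_s within a posterior standard deviation.

## Ensemble analytics

Kabsch superposition via SVD with a reflection guard (proper rotations
only; degenerate/collinear selections rejected). The mean structure is
iterative (superpose-all, re-average, repeat to Δ < 10⁻⁶ Å). Per-residue
RMSD superposes globally on the backbone first, then reports per-residue
values and member standard deviations; the side-chain selection is
Cβ/Cγ*/Cδ*/Cε* plus side-chain nitrogens (ζ atoms intentionally omitted);
glycine reports NaN in side-chain mode. PCA operates on flattened selected
coordinates after superposition, without mass weighting, via
scikit-learn. Subsampling keeps ⌊fraction·N⌋ members uniformly without
replacement, order-preserving, seeded.

## Synthetic data: what it does and does not emulate

The generator produces exactly the study conditions of the tests: preset
folds designed in torsion space to be clash-free with ≥ 10 long-range
proton contacts; per-class normal chemical shifts with either guaranteed
0.04 ppm separation (unambiguous assignment) or a forced fraction of
near-degenerate pairs; NOE peaks for every proton pair under 5.5 Å with
`I = C_s/r⁶` and log-normal noise (`ln ε ~ N(0, σ_s²)`), partitioned into
an amide-proton and a carbon-proton 2D class; and NUS planes of decaying
complex sinusoids with white complex noise.

Deliberate simplifications: methyl protons are treated as individually
resolved resonances (no rotor averaging); there is no spin diffusion,
relaxation weighting, in-cell background signal, or solvent artifact; 3D
NOESY dimensionality is reduced to classed 2D ¹H–¹H lists (the heavy
dimension is bookkeeping at this scale); intensities are strictly
`C/r⁶·ε`. Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms under their own statistical model — not
performance on real in-cell spectra, where assignment error modes
(overlap, missing peaks, artifacts) are harsher than anything simulated
here.

Problem sizes in the shipped tests and acceptance runs were chosen so the
whole suite completes in minutes on one CPU: 32 × 16 reconstruction
planes at 25% sampling, a 12-residue scenario, 10 annealing starts × 4000
steps, and 4 replicas × 2·10⁵ refinement steps; the production-scale settings
(48 × 22 grids, 100 starts × 10⁴ steps, 10 replicas, 5000-step thinning)
remain the configuration defaults of the pipeline.

## Known limitations

* No proline, cysteine, methionine; single chain; no cis peptide bonds;
  side chains rigid beyond χ2.
* The physical prior is repulsion + staggering only; ensembles sampled
  with few restraints reflect that prior, not a force field.
* The λ selector is an evidence surrogate; its absolute λ values are
  implementation-specific even though its selection behavior (smoothing
  grows with noise, bracket-independent optimum) is tested.
* Stereospecific assignment, spin-diffusion correction and
  hydrogen-bond restraints are out of scope.
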