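# incellfold

Desk-scale protein structure determination from in-cell NMR data.

Proteins observed inside living cells give sparse, noisy NMR spectra:
measurement time is cut by non-uniform sampling (NUS) of the indirect
dimensions, background signals bury weak NOESY cross peaks, and the few
distance restraints that survive are ambiguous. `incellfold` implements the
complete computational chain that turns such data into a structure
ensemble, for people who want to study, test or teach these methods on
synthetic data with known ground truth:

1. **MaxEnt reconstruction of undersampled spectra.** The spectrum `h`
   (real, non-negative) minimizes `C(h) = L(h) − λS(h)` where
   `L(h) = ½ Σ_p |IDFT(h)_p − D_p|²` is the residual over the sampled
   points and `S(h) = Σ_i [h_i − A − h_i ln(h_i/A)]` is the Skilling
   entropy relative to a flat default level `A`. The multiplier λ is chosen
   automatically by maximizing a Laplace-approximated evidence
   `log p(D|λ)`, so it reflects the error of the experimental data —
   noisier data select a larger λ.
2. **NOESY interpretation.** Cross peaks are assigned by exhaustive
   chemical-shift matching (tolerance 0.04 ppm for ¹H, 0.4 ppm for
   ¹³C/¹⁵N), pruned by a network-support filter, and calibrated to upper
   distance bounds through the isolated-spin-pair relation `I = C/r⁶`.
   Ambiguity is retained: a multi-option restraint acts through
   `r_eff = (Σ r⁻⁶)^(−1/6)`.
3. **Torsion-space annealing.** Multi-start Metropolis annealing against
   the squared-violation target function produces the refinement seed.
4. **Bayesian refinement.** The joint posterior over the conformation and
   per-spectrum nuisance parameters — log calibration constants `c_s` with
   normal priors and noise scales `σ_s` with inverse-gamma priors on
   `σ_s²`, under a normal likelihood on log intensities — is sampled by
   replica-exchange Monte Carlo (default ladder geometric over
   300–400 K), with conjugate Gibbs updates for the nuisances and a
   gradient-informed collective move. The ensemble is the thinned 300 K
   chain; the MAP member is its highest-posterior state.
5. **Ensemble analytics.** Kabsch superposition, iterative mean structure,
   global and per-residue RMSD (backbone N/Cα/C′; side-chain
   Cβ/Cγ/Cδ/Cε + side-chain N), PCA of the superposed coordinates, and
   seeded subsampling for display.

A first-class synthetic-data module generates ground-truth folds (a 12-mer
β-hairpin, a 16-mer helix-turn, a 20-mer α/β fold), shift tables with
controllable degeneracy, NOE peak lists with `I = C/r⁶` log-normal noise,
and NUS time-domain planes, so every stage is testable without downloads.

## Worked example

Simulate a noisy hairpin scenario and run the pipeline:

```
incellfold simulate --preset hairpin12 --seed 1 --noise-sigma 0.1 --outdir demo
incellfold assign --peaks demo/peaks_noesy_n15.list --peaks demo/peaks_noesy_c13.list \
                  --shifts demo/shifts.prot --out demo/restraints.upl
incellfold anneal --seq KTVSINGKTVSE --upl demo/restraints.upl \
                  --n-starts 10 --n-steps 4000 --seed 1 --out demo/seed.pdb
incellfold refine --seed-structure demo/seed.pdb --upl demo/restraints.upl \
                  --replicas 4 --steps 100000 --burn 20000 --stride 400 \
                  --seed 1 --out demo/ensemble.pdb
incellfold analyze --ensemble demo/ensemble.pdb --reference demo/reference.pdb \
                   --outdir demo/analysis
```

which prints

```
scenario 'hairpin12' written to demo
demo/peaks_noesy_n15.list: 218 peaks -> 218 restraints
demo/peaks_noesy_c13.list: 473 peaks -> 473 restraints
classes: {'intra': 365, 'sequential': 195, 'medium': 90, 'long': 41}
best target 42.59 -> demo/seed.pdb
200 conformers -> demo/ensemble.pdb; exchange rates [0.486 0.04  0.119]
mean backbone rmsd to mean: 0.105 A; 40 subsampled members
```

Reading the numbers: the two simulated NOESY spectra yield 691 restraints
(41 long-range, |i−j| ≥ 5 — the contacts that define the fold). Annealing
leaves a best squared-violation target of 42.6 Å² (the restraints carry
10% multiplicative intensity noise, so they cannot all be satisfied at
once); Bayesian refinement then absorbs that noise into the σ_s nuisance
parameters and tightens the ensemble to a 0.105 Å mean backbone RMSD about
its mean — a well-defined fold. `demo/analysis/` holds the per-residue
RMSD profile, PCA projections and a 20% subsampled bundle; the full
pipeline can also be driven from one YAML file via `incellfold run`.

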