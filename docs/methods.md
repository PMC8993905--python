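# Methods

`masdyn` quantifies the dynamics and functional role of a mobile protein
loop from solid-state NMR observables and companion sequence/structure
analyses.  This note records the models, the numerical choices, and what
the synthetic-data generators do and do not emulate.

## REDOR simulation (`spin_sim`)

**Model.** The observable is the rotational-echo double-resonance (REDOR)
dephasing fraction ΔS/S₀ of ¹³C methyl coherence coupled to one ¹H, under
magic-angle spinning.  For each crystallite orientation the secular dipolar
frequency ν(t) is obtained by Wigner rotation of the motion-averaged
coupling tensor from its principal-axis system through (α, β, γ) into the
rotor frame and then into the laboratory frame at the magic angle, giving
the usual two-harmonic modulation at ω_r and 2ω_r.  The accumulated phase
is φ = 2π ∫ s(t) ν(t) dt, where s(t) = ±1 flips at every π pulse, and
ΔS/S₀ = 1 − ⟨cos φ⟩ over the powder.

**Conventions.** `anisotropy` is the *full tensor span* in Hz, i.e. twice
the dipolar coupling constant d = (μ₀/4π) γ_H γ_C ħ / (2π r³); a rigid H–C
pair at 1.115 Å gives 43,588 Hz.  Fast threefold methyl rotation scales
the static tensor by |P₂(cos 109.47°)| = 1/3 (rigid methyl limit
14,529 Hz).  The asymmetry η ∈ [0, 1] enters through the full orientation
dependence of the rotated tensor, not as a perturbation.

**Pulse-sequence layout.** Two ¹H π pulses per rotor period, one shifted
off-centre so that the edge-to-edge delays between successive ¹H π pulses
are 0.5 and 7.5 μs at 55.555 kHz MAS (5 μs ¹H and 6 μs ¹³C π pulses) —
the shift scales down the recoupled coupling so slow dephasing is sampled
accurately.  A single ¹³C π pulse at the sequence midpoint refocuses the
chemical shift.  A subtle but load-bearing choice: the central ¹³C π
*replaces* the ¹H π pulse at that rotor-period boundary.  If instead an
extra sign inversion were inserted on top of a strictly periodic ¹H train,
the per-period dipolar phase (which is constant for a rotor-synchronised
train) would be refocused exactly and the curve would be identically zero.
With the replacement, s(t) alternates strictly periodically, the
accumulated phase after n rotor periods is n times the one-period phase,
and the simulator reproduces the closed-form universal REDOR curve
1 − (√2π/4) J₊¼(√2λ) J₋¼(√2λ), λ = d·t, to RMS ≲ 4·10⁻⁴.  Phase cycling
is ignored in ideal-pulse mode (it compensates pulse imperfections that an
ideal simulation does not have).

**Finite pulses.** In finite-pulse mode the dipolar term is scaled by the
cosine of the nutation angle of the pulsed spin while an rf pulse is
active (the first-order finite-pulse treatment), integrated piecewise
analytically.  This converges to the ideal-pulse result as durations → 0
and perturbs the 5/6 μs experimental case by at most a few percent of
ΔS/S₀.

**Powder averaging.** A golden-ratio (ZCW-type) spiral over (α, β) with an
even γ grid.  The default is 377 × 24 = 9048 orientations: γ sampling
limits accuracy for strong couplings at long dephasing times, and 377 × 24
is the smallest scheme of this family for which doubling the orientation
count moves no default-grid curve point by more than 10⁻³.  A built-in
convergence check (`check_convergence=True`) warns when a custom scheme is
too coarse.

**Time grid.** Dephasing is sampled at even rotor-period multiples
(2, 4, …, 48 by default, 36–864 μs), chosen so the rigid-limit curve passes
its first plateau and a highly flexible site (S² ≈ 0.15) still reaches
λ ≈ 2.  Motional averaging is represented entirely by the reduced,
possibly asymmetric tensor; no explicit jump dynamics are propagated.

## Grid fitting and order parameters (`tensor_fit`)

Curves are fitted by exhaustive search over a precomputed grid —
anisotropy 1030–15,000 Hz in 30 Hz steps × η 0–1 in 0.05 steps, 466 × 21 =
9786 simulations with inclusive endpoints — minimising the noise-weighted
chi-square Σ(obs − sim)²/σ².  Whether the original analysis weighted by
noise is not documented; weighted is the default here (with σ constant per
curve the arg-min is unchanged).  Ties break deterministically toward
lower anisotropy, then lower asymmetry.  Because the ideal-pulse phase is
linear in the tensor components, the orientation/time integrals are
computed once per timing and each grid point costs a single cosine pass;
the full grid builds in seconds and can be cached on disk keyed by a hash
of timing and grid parameters.

Uncertainties: 1000 synthetic curves are drawn around the best-fit
simulation with normal noise of SD equal to the spectral noise level,
truncated at ±3σ (the literal reading of the source protocol; a
plain-normal option exists), refitted, and the SDs over replicate
anisotropy/asymmetry/S² are reported (±1 SD error bars).  S² =
(anisotropy / 14,529 Hz)²; best-fit anisotropies above the rigid limit
(the grid extends to 15,000 Hz) are clipped to the limit for the S²
conversion, and `order_parameter` itself rejects super-rigid inputs.

## Relaxation and NERRD (`relaxation`)

R1 and R1ρ come from two-parameter monoexponential fits I(t) = I₀e^(−Rt)
with log-linear start values; R is unconstrained during optimisation and
floored at zero afterwards, so residual diagnostics stay honest.  Rate SDs
are MC resampling at the intensity noise (1000 replicates by default).
A NERRD profile orders R1ρ points by spin-lock field (fields at or above
the MAS frequency are rejected — the n = 1 rotary-resonance condition);
its "non-flat" call uses the highest-minus-lowest-field rate difference
against 3× its propagated SD.  The 3-SD rule is a package choice (the
visual assessment in the source has no quantitative criterion) and the
multiplier is configurable.  Quantitative exchange-model (Bloch–McConnell)
fitting of the dispersion is out of scope.  The water-shift thermometer is
T/°C = 455 − 90·δ_H2O(ppm).

## Chemical-shift perturbations (`shift_perturbation`)

CSP = √(Δδ_H² + 0.1·Δδ_N² + 0.3·Δδ_CA²) per residue present in both
states.  The significance line is 3× the sample SD (ddof = 1) of all
computed CSPs, untrimmed by default (a trimmed option exists); residues
missing an atom in either state contribute only the available terms and
are flagged `partial`, since the source protocol does not state its
handling.

## Enzyme kinetics (`kinetics`)

Traces are blank-subtracted, converted to product concentration with
ε = 8800 M⁻¹cm⁻¹ and a 0.375 cm path, and the initial rate is a linear
(lmfit) fit over the first 10% of points or up to 10% substrate depletion,
whichever is shorter — keeping the linear-regime assumption testable
against an integrated-rate-law oracle.  All rates (duplicates included)
enter one unweighted least-squares Michaelis–Menten fit (a weighted option
exists; whether the original fit weighted by slope SEs is not stated);
k_cat = V_max/[E]_sites with the active-site concentration defaulting to
5 ng/μL of a 39 kDa subunit, one site per subunit.  K_M/k_cat SDs are SDs
over 1000 MC refits with per-point normal noise at the slope SE; k_cat/K_M
is reported alongside.

## Co-evolution evaluation (`coevolution_eval`)

Sequences with more than 25% gaps are removed (inclusive boundary: exactly
25% is kept).  Reweighting: weight 1/k where k counts sequences (self
included) with identity strictly above 0.9; identity counts the gap as a
21st symbol over the full alignment length by default (a gap-excluding
option is exposed, since the original convention is unknown); B_eff is the
weight sum.  Evaluation drops pairs separated by ≤ 4 positions, takes the
top-k survivors (top 2N is the convention used for an N-position model),
and scores a pair as a true positive when the minimum heavy-atom distance
is below 8 Å in *any* chain-pair realization — coupling scores cannot
distinguish intra- from inter-molecular contacts.  PPV is reported both
over all evaluated pairs and restricted to structurally defined positions.
Coupling inference itself (pseudo-likelihood DCA) is external; the bundled
scorer is weighted mutual information with average-product correction and
a symmetric pseudocount, provided only so the pipeline runs end to end.

## Trajectory contacts (`contact_analysis`)

Contacts are minimum inter-residue heavy-atom distances (hydrogens
excluded by element, robust to naming dialects): 5 Å for direct contacts,
7 Å when checking co-evolution predictions against frames.  Multi-model
PDB files are one frame per MODEL; frame stride is configurable.
"Transient contact" means a contact in at least one analysed frame by
default (threshold configurable, since the required persistence in the
source is unstated).  A predicted pair agrees with the trajectory when any
chain-pair realization of its residue numbers satisfies the loose cutoff.

## Synthetic data (`synthetic_data`)

Every generator is seeded and bit-reproducible, emits valid inputs for its
target module plus a truth record, and defaults to the study conditions
the analyses assume:

- REDOR: a flexible site with S² = 0.15 (η = 0.3) and rigid sites in the
  0.7–1 band; truncated-normal (±3σ) noise with σ = 0.105 in ΔS/S₀ units,
  calibrated once so the MC SD of S² at the flexible truth is ≈ 0.02.
- Relaxation: monoexponential decays on the canonical 0.05–2.5 s delay
  grid (compressed 20× for spin-lock decays), with one flat and one
  rising NERRD profile.
- CSP: 100 residues, five carrying a +0.5 ppm ¹⁵N offset over 0.01 ppm
  noise.
- Kinetics: integrated progress curves (closed form via Lambert W) on a
  0.1–6.4 mM duplicate substrate series, 60 s fast-read traces sampled at
  0.5 s so the initial-rate window stays in the linear regime; 3%
  multiplicative noise mirrors the observed duplicate spread.
- MSA: independent Dirichlet-profile columns with imposed covarying pairs
  (random bijection coupling), optional gaps.
- Toy assembly: two chains with a mobile loop whose tip engages a
  designated active-site residue in a designed fraction of frames.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: spectrometer artefacts (phase errors, rf
inhomogeneity, t₁ noise), multi-spin couplings and relaxation during
recoupling, peak overlap and assignment errors, instrument drift and
temperature gradients in plate reads, phylogenetic correlation structure
of real alignments beyond simple reweighting, and force-field physics of
real trajectories.  Closed-loop recovery demonstrates correctness of the
estimators under their own noise model, not robustness to model violation.

## Numerical notes and limitations

- Chi-square over the grid is evaluated with the expanded-product matrix
  form for speed and recomputed by direct subtraction at the arg-min, so a
  noiseless grid member reports exactly 0.
- Monoexponential and Michaelis–Menten fits use scipy least squares with
  data-driven start values; degenerate inputs (all-zero, rising, or
  saturated data) warn rather than fail.
- The grid fit is discrete by design (no off-grid refinement), matching
  the reference protocol; quoted SDs are therefore quantised at small
  noise.
- Problem sizes in the test-suite and acceptance runs (50-seed recovery
  experiments, 30-residue contact maps, 400-sequence alignments) are
  desk-scale choices; all estimators accept larger inputs unchanged.
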