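# masdyn

Analysis toolkit for quantifying the dynamics and functional role of
mobile protein segments — built around the solid-state NMR and
bioinformatics workflow used to characterise the catalytic-chamber loop of
a large oligomeric aminopeptidase, and exercisable end to end on seeded
synthetic data.

It is aimed at magic-angle-spinning (MAS) NMR spectroscopists and
structural bioinformaticians who need, in one place:

- **REDOR dipolar recoupling**: forward simulation of ¹H–¹³C dephasing
  curves ΔS/S₀(t) under MAS for a motion-averaged coupling tensor
  (anisotropy δ, asymmetry η), including the shifted-pulse variant that
  scales down the recoupling (0.5/7.5 μs ¹H gaps at 55.555 kHz).
- **Tensor fitting and order parameters**: grid chi-square fits over
  δ ∈ [1030, 15000] Hz × η ∈ [0, 1] (9786 simulations), Monte Carlo
  errors from ±3σ truncated noise, and S² = (δ / 14 529 Hz)², where
  14 529 Hz is the rigid methyl limit (one third of the 43 588 Hz static
  coupling of an H–C pair at 1.115 Å).
- **Relaxation**: monoexponential R₁/R₁ρ fits, NERRD profiles
  (R₁ρ versus spin-lock field approaching the MAS frequency — a rising
  profile reports microsecond motion), and the water-shift thermometer
  T = 455 − 90·δ_H2O.
- **Chemical-shift perturbations**:
  CSP = √(Δδ_H² + 0.1 Δδ_N² + 0.3 Δδ_CA²) with a 3-SD significance line.
- **Enzyme kinetics**: plate-reader absorbance → product concentration
  (ε = 8800 M⁻¹cm⁻¹, 0.375 cm path), initial-rate extraction, joint
  Michaelis–Menten fits of v(S) = V_max S/(K_M + S) with 1000-replicate
  Monte Carlo errors.
- **Co-evolution evaluation**: MSA coverage filtering (≤ 25% gaps),
  identity reweighting at 90% with B_eff, and positive predictive value of
  top-2N ranked couplings against 8 Å heavy-atom contacts (pairs separated
  by more than four residues).
- **Trajectory contacts**: minimum heavy-atom inter-residue distances over
  multi-frame coordinates, 5 Å direct / 7 Å loose contact sets, and
  agreement of predicted pairs with the frames.

The fitting stages are scikit-learn-style estimators
(`TensorGridFitter`, `MonoexponentialFitter`, `MichaelisMentenFitter`)
with `fit`/`predict` and trailing-underscore fitted attributes; every
stage also has plain functions and a `masdyn` command-line entry point.
The `masdyn.synthetic_data` module generates seeded inputs for every
stage (noisy REDOR curves from known tensors, exponential decays, peak
lists with localized perturbations, integrated Michaelis–Menten progress
curves, covarying alignments, and a toy two-chain assembly with a mobile
loop), so the whole pipeline runs without any experimental download.

## Worked example: order parameter of a flexible methyl site

```python
import numpy as np
from masdyn import spin_sim, tensor_fit
from masdyn.synthetic_data import make_redor_dataset, REDOR_NOISE_SIGMA

timing = spin_sim.PulseTiming.shifted()          # 55.555 kHz, 0.5/7.5 us gaps
truth = spin_sim.DipolarTensor(5627.0, 0.3)      # S^2 = 0.15
data = make_redor_dataset({"V120": truth}, timing, seed=11)
curve, _ = data["V120"]

grid = tensor_fit.build_grid(timing)             # 466 x 21 = 9786 curves
est = tensor_fit.TensorGridFitter(grid, noise_sigma=REDOR_NOISE_SIGMA,
                                  n_mc=1000, seed=1)
est.fit(curve.dephasing_times, curve.dephasing)
print(f"anisotropy = {est.anisotropy_:.0f} +/- {est.anisotropy_sd_:.0f} Hz")
print(f"eta        = {est.asymmetry_:.2f} +/- {est.asymmetry_sd_:.2f}")
print(f"S^2        = {est.s_squared_:.3f} +/- {est.s_squared_sd_:.3f}")
```

prints

```
anisotropy = 5590 +/- 361 Hz
eta        = 0.00 +/- 0.30
S^2        = 0.148 +/- 0.019
```

The fitted tensor span (5590 Hz, one grid step from the 5627 Hz truth)
translates to a squared order parameter S² = 0.148 ± 0.019: a highly
flexible site, far below the 0.7–1 band of rigid methyls.  The asymmetry
is poorly constrained at this noise level — its MC standard deviation
(0.30) spans much of the [0, 1] range, which the error bar makes explicit.

The same analysis from the shell:

```bash
masdyn simulate --seed 1 --outdir fixtures/
masdyn build-grid --out grid.npz
masdyn redor-fit --curves fixtures/redor_curves.csv --grid grid.npz \
                 --mc 1000 --seed 1 --out fits.csv
```

## Layout

```
src/masdyn/
  spin_sim.py           REDOR forward simulation (ideal + finite pulses)
  tensor_fit.py         grid chi-square fit, MC errors, order parameters
  relaxation.py         R1/R1rho fits, NERRD assembly, thermometry
  shift_perturbation.py combined CSP mapping and significance
  kinetics.py           initial rates + Michaelis-Menten with MC errors
  coevolution_eval.py   MSA filtering/reweighting, PPV evaluation, MI-APC
  contact_analysis.py   heavy-atom contact series over coordinate frames
  synthetic_data.py     seeded generators for every stage + truth records
  cli.py                `masdyn` command-line interface
docs/methods.md         models, conventions, numerical choices, limits
```
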