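# paibind

Analysis pipeline for studying how the structural stability of the Sleeping
Beauty (SB) transposase's primary DNA-recognition subdomain (PAI) shapes its
binding to transposon DNA.  The package re-implements, as tested, reusable
code, the quantitative analyses such a study rests on:

- **Binding isotherms (MST / FA / FLT)** — mono- and biphasic Hill fits of
  dose-response curves, `F(c) = baseline + Σ_m ΔF_m·c^{n_m}/(K_{D,m}^{n_m} + c^{n_m})`,
  with SEM weighting, multistart optimization, AICc mode selection and
  covariance standard errors.  Full-length transposase titrations are
  biphasic: a nanomolar specific mode plus a micromolar nonspecific mode.
- **CD pH-folding thermodynamics** — mean residue ellipticity
  `[θ] = θ_mdeg/(10·l·C·N_res)`, two-state folded fraction from `[θ]₂₂₂`,
  isodichroic-point location, and the modified Henderson–Hasselbalch fit
  `f_h(pH) = (f_b + f_a·10^{n(pKa−pH)})/(1 + 10^{n(pKa−pH)})` with free Hill
  slope, giving the pKa of the helix-formation transition (histidine
  deprotonation range, ≈ 6).
- **Time-resolved fluorescence** — biexponential decays
  `A₁e^{−t/τ₁} + A₂e^{−t/τ₂}` convolved with the measured IRF, Poisson-weighted
  global fitting with lifetimes linked across waveforms, steady-state
  anisotropy `FA = (I_vv − g·I_vh)/(I_vv + 2g·I_vh)`, the intensity-weighted
  lifetime `τ = (A₁τ₁² + A₂τ₂²)/(A₁τ₁ + A₂τ₂)` and integral intensity
  `A₁τ₁ + A₂τ₂`, and K_D extraction from FA/FLT titrations.
- **NMR titration analysis** — weighted chemical-shift perturbations
  `Δδ = √(Δδ_H² + 0.15·Δδ_N²)` with 1/2-SD thresholds, active-residue
  selection for docking restraints (> 2 SD and > 50% relative SASA), and
  Stejskal–Tanner PFG diffusion fits
  `I(g) = I₀·exp(−D(γgδ)²(Δ − δ/3))` with monomer/dimer calling against
  predicted references.
- **Rigid-body protein–DNA docking** — a knowledge-based, distance- and
  orientation-dependent potential `E = Σ E⁰_ij(r, φ)` (inverse-Boltzmann,
  binned over sidechain-centroid/base-ring distance r and
  sidechain-to-base-plane angle φ), independent Metropolis Monte Carlo
  searches over rigid 6-DOF moves, complete-linkage pose clustering at 3 Å
  Cα RMSD, ranking by lowest-energy cluster representative, 5 Å interface
  annotation with hydrogen-bond detection, Kabsch superposition, and
  Shrake–Rupley SASA.
- **Synthetic data** — every input above can be generated with known ground
  truth (`paibind.synthetic`), so the full pipeline is testable with no
  instrument data: seeded Hill dose responses with replicate noise, pH
  sigmoids, IRF-convolved Poisson decays, gradient attenuation, peak lists
  with planted perturbations, and an idealized fiber-model B-DNA duplex
  (3.38 Å rise, 36°/bp twist) with a poly-alanine helix.

## Worked example

```python
from paibind.synthetic import SimScenario, gen_titration
from paibind.binding import fit_binding, select_binding_model

# a specific transposase/DR-core titration: 16 log-spaced points, 3
# replicate curves, 2%-amplitude noise, ground truth KD = 25.3 nM
scenario = SimScenario("titration", {"kd_nM": 25.3},
                       {"sigma": 0.02, "replicates": 3}, seed=1)
series = gen_titration(scenario)
n_modes, fit = select_binding_model(series)
print(n_modes, round(fit.kd_nM, 1), round(fit.modes[0].kd_se, 1))
```

prints `1 25.3 0.4`: the AICc comparison keeps the monophasic model and the
Hill fit recovers the dissociation constant (25.3 ± 0.4 nM against a 25.3 nM
ground truth) from one noisy realization.

The numbered drivers under `analysis/` run each stage end to end and write
tables under `results/`:

```bash
python analysis/01_binding_affinity.py    # biphasic fits + KD recovery
python analysis/02_ph_folding.py          # pKa and isodichroic point
python analysis/03_fluorescence.py        # reconvolution, FLT/FA KDs
python analysis/04_nmr_csp_diffusion.py   # CSP map, restraints, diffusion
python analysis/05_docking.py             # potential, MC docking, clusters
```

A thin CLI mirrors the library (`paibind simulate|fitbind|phfold|trf|csp|
diffusion|potential|dock`); see `paibind --help`.

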