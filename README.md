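# nanoconj

Quantifies the composition of gold nanoparticle–protein conjugates from
label-free tryptophan-fluorescence measurements. The package is aimed at
bioconjugation and nanobiotechnology labs that functionalize colloidal gold
with proteins (antibodies, albumin, protein G, enzyme inhibitors, ...) and
need per-particle stoichiometry and binding constants without labelling the
protein or correcting for nanoparticle quenching.

## The method

Proteins fluoresce intrinsically (tryptophan, excitation 280 nm, emission
read at 350 nm). After conjugating protein to particles and pelleting the
conjugates, the residual fluorescence of the supernatant measures the
*unbound* protein, free of any particle–fluorophore interaction. Comparing
a calibration series (intensity F₀ at added concentration C₀, prepared in
the same supernatant matrix) with the post-separation reading F gives the
bound amount by mass balance:

    C_conjugated = C₀ − C_unbound = C₀ · (F₀ − F)/F₀

Dividing by the particle concentration converts this to molecules bound
per particle,

    RL = [(F₀ − F)/F₀] · [L₀]/[R₀]

where [R₀] follows from the colloid arithmetic (sphere volume at the TEM
mean diameter × gold density → particle mass; gold mass concentration ÷
particle mass → particles/mL → molarity). The isotherm RL([L₀]) is then
analysed in Scatchard coordinates,

    RL/[L] = (N − RL)/K_D

a straight line for one class of N independent sites (slope −1/K_D,
x-intercept N). Adsorption on a crowding particle surface is
anti-cooperative, so the cloud is convex and is summarized by two tangent
lines: K_D⁽¹⁾ at low coverage, K_D⁽²⁾ near saturation, and N from the
x-intercept of the near-saturation line. Finally the measured N is checked
against an analytic monolayer capacity — the number of protein footprint
disks that tile the sphere carrying the protein centers,
`⌊φ · 4π(R + r_p)² / (π r_p²)⌋` with hexagonal packing fraction φ = 0.9069.

A synthetic-experiment generator (`nanoconj.simulate`) reproduces the
laboratory design — a two-fold dilution series (1000 → 8 µg/mL), exact
mass-action equilibrium with ligand depletion, perfect separation, and a
noisy linear fluorescence readout with left-censoring at the 0.5 µg/mL
detection limit — so every stage can be validated against known ground
truth. See `docs/methods.md` for model details and limitations.

## Worked example

```python
from nanoconj import (ParticleBatch, ProteinSpec, BindingModelSpec,
                      SyntheticExperiment, generate_experiment,
                      fit_calibration, build_isotherm, select_analysis_window,
                      scatchard_transform, two_regime_fit, molar_concentration,
                      PackingModel, footprint_from_mw, monolayer_capacity,
                      monolayer_consistency)

batch = ParticleBatch(diameter_nm=24.0)          # 0.05 g/L gold, 5x enriched
bsa = ProteinSpec("BSA", molecular_weight_kda=66.0)
print(f"[R0] = {molar_concentration(batch, apply_factor=True):.2f} nM")

exp = SyntheticExperiment(BindingModelSpec.langmuir(6.0, 90.0), batch, bsa,
                          noise_cv=0.01, seed=2)
calib, supernatant, truth = generate_experiment(exp)

curve = fit_calibration(calib)
print(f"calibration: slope {curve.slope:.2f} /(ug/mL), r = {curve.correlation_r:.4f}")

iso = build_isotherm(curve, supernatant, bsa, batch)
x, y = scatchard_transform(select_analysis_window(iso))
res = two_regime_fit(x, y)
print(f"Kd(1) = {res.kd1_nM:.1f} nM, Kd(2) = {res.kd2_nM:.1f} nM, N = {res.n_sites:.1f}")

model = PackingModel(batch.diameter_nm, footprint_from_mw(bsa))
ratio, verdict = monolayer_consistency(res.n_sites, model)
print(f"monolayer capacity {monolayer_capacity(model)}, ratio {ratio:.2f} -> {verdict}")
```

prints

```
[R0] = 2.97 nM
calibration: slope 19.75 /(ug/mL), r = 1.0000
Kd(1) = 5.2 nM, Kd(2) = 3.1 nM, N = 88.5
monolayer capacity 109, ratio 0.81 -> monolayer-consistent
```

The simulated BSA experiment (true K_D = 6 nM, N = 90, 1% measurement
noise) comes back with a site count within 2% of truth and a low-coverage
dissociation constant of the right magnitude — at 1% noise the Scatchard
slopes, which divide by small free-ligand concentrations, scatter much
more than the x-intercept. The recovered N sits below the ideal monolayer
capacity for a 5.3 nm BSA footprint, consistent with single-layer
adsorption.

The same pipeline runs from the shell over CSV/config inputs:

```bash
nanoconj simulate --config scenario.yaml --seed 1 --out-dir sim
nanoconj run --config run.yaml
```

with subcommands `particles`, `calibrate`, `bind`, `scatchard`, `pack` for
the individual stages.

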