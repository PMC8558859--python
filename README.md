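# sitekit

Analysis machinery for locating and characterising small-molecule binding
sites on helical amyloid fibrils, built around the cationic
bi-thiophene-vinylene-benzothiazole (bTVBT4) ligand and the
Alzheimer's-disease tau protofilament as the worked system.

The package covers the full desk-side pipeline that surrounds (but does
not include) molecular-dynamics and quantum-chemistry engines:

* **Fibril building** — forced-periodic helical supercells from a single
  protofilament layer under 2₁ screw symmetry.  The generating operation
  from layer *k* to *k+1* is a rotation by `360/s + twist` degrees about
  the fibril axis plus a translation by the rise; a periodic cell of *n*
  layers closes when `n · twist · s ≡ 0 (mod 360°)`.  For the tau fibril,
  185 layers at a rise of 4.8 Å give a twist of 0.97°/layer.
* **Trajectory analysis** — axis-collapsed ligand density maps (with
  screw "untwisting" so symmetry-equivalent sites superpose),
  classification of the four major binding modes (ethyl group up/down ×
  left/right in a His→Ile site frame) and four torsional minor modes,
  occupancy fractions with binomial confidence intervals, residence
  times, backbone planarity `Σᵢ |cos θᵢ|`, and per-residue Lennard-Jones
  / Coulomb interaction-energy aggregation.
* **Free energies** — 1-D WHAM over umbrella-sampling windows
  (`Wham(windows).fit()` returns a `PMFProfile` results object with
  window shifts, convergence diagnostics, optional block-bootstrap
  errors and a `summary()`), binding energies as bulk-plateau minus
  global minimum, Boltzmann mode populations
  `pᵢ = exp(Eᵢ/kT) / Σⱼ exp(Eⱼ/kT)`, and detection of intermediate
  minima along the exit path.
* **Spectra** — snapshot-averaged absorption line shapes with Gaussian
  or vibronic (0-0 line + progression) broadening, λmax extraction,
  eV↔nm conversion (λ = 1239.84193/E), band-shift analysis and
  conformer-population averaging.
* **Synthetic data** — generators for every input above with planted
  ground truth: a toy C-shaped protofilament layer with labelled site
  triads, planted-occupancy ligand trajectories, umbrella windows drawn
  from analytic potentials by Metropolis sampling, and snapshot
  energy/interaction records.  Every statistical stage is validated by
  recovering what was planted.

## Worked example

```python
import numpy as np
import sitekit as sk

# 1. a labelled toy protofilament layer, stacked under 2-fold screw symmetry
layer = sk.generate_toy_layer(73, 4.0, seed=1)
fibril = sk.build_supercell(layer, 10, rise=0.48, twist=sk.twist_from_layers(185))
print(round(sk.twist_from_layers(185), 3), np.max(sk.verify_symmetry(fibril)))
# 0.973 1.8611815729210437e-14

# 2. a planted-occupancy trajectory, classified back
cfg = sk.SyntheticConfig(seed=3, n_frames=2000, n_ligands=10, bulk_fraction=0.3)
traj = sk.generate_ligand_trajectory(cfg, fibril)
labels = sk.classify_trajectory(traj, fibril, fibril.template.sites["A"])
print(sk.mode_populations(labels).summary())
# Binding-mode populations
# ==========================================================
# bound configurations: 14037 / 20000
#   mode   fraction              95% CI   residence (ps)
#     UL     0.4709 [ 0.4626,  0.4792]             29.8
#     UR     0.2984 [ 0.2908,  0.3059]             25.3
#     DL     0.1937 [ 0.1872,  0.2002]             22.9
#     DR     0.0370 [ 0.0339,  0.0402]             20.5

# 3. a PMF from umbrella windows sampled out of a known binding well
pot = sk.AnalyticPotential.multi_well([30.0], [0.5], [0.3], domain=(0.0, 2.2))
wins = sk.generate_umbrella_windows(pot, np.linspace(0, 2.2, 25), 600.0, 3000, seed=4)
pmf = sk.Wham(wins, bin_width=0.02).fit(reference="bulk-zero", bulk_last=0.5)
print(round(sk.binding_energy(pmf, (1.7, 2.2)), 1))
# 29.8
```

The classifier recovers the planted 47/30/19/4 % major-mode weights
within binomial sampling error, and the WHAM binding energy recovers the
planted 30 kJ/mol well depth — the same pattern of checks used for the
tau/bTVBT4 system, where binding at the Ile360/Thr361/His362 pocket is
strongest, per-mode binding energies span roughly 26–33 kJ/mol, and the
resulting Boltzmann populations rank UR > UL > DR > DL.

A `sitekit` command-line interface wraps the same operations
(`sitekit synth ...`, `sitekit build`, `sitekit density`, `sitekit modes`,
`sitekit energies`, `sitekit pmf`, `sitekit spectrum`); see `--help`.

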