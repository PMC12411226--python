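# lietsim

Simulation and analysis toolkit for **self-illuminating tunnel-junction
metasurface biosensors** — devices in which inelastic electron tunnelling
across a thin oxide barrier generates light that a plasmonic nanowire
metasurface couples to the far field, and in which analyte layers are read
out refractometrically through changes of the emitted spectrum.

The emitted intensity is modelled as a product of two independent factors:

* an **electronic factor H(ω, V_b)** — the density of tunnelling state pairs
  able to emit a photon of energy ħω under bias V_b, built from per-metal
  densities of states and Fermi–Dirac occupations, with the quantum cut-off
  ħω ≤ eV_b emerging from the occupation factors;
* a **photonic factor G(ω)** — the antenna-mediated outcoupling efficiency
  of the surface-normal dipoles in the tunnelling gap, computed by optical
  reciprocity on a 1D-periodic rigorous coupled-wave (RCWA) solver
  (in-plane and conical incidence, Li-factorized TM rules), integrated over
  the collection cone of the objective (NA-limited, optionally
  azimuth-integrated).

On top of the emission model the package provides the tunnel-junction
current model (mean-barrier formula with effective mass), Fowler–Nordheim
analysis and barrier fitting, refractometric sensing metrics (band-integrated
differential signal, peak fold-change, 3×-noise limit of detection), and
seeded synthetic measurement generators so that the entire pipeline is
testable offline.

## Layout

| module | role |
| --- | --- |
| `lietsim.device_config` | device geometry, material optical models, detection geometry |
| `lietsim.electronic_h` | spectral electronic contribution H(ω, V_b) |
| `lietsim.photonic_g` | RCWA/reciprocity photonic contribution 𝒢(ω, θ, φ) and G(ω) |
| `lietsim.emission_combine` | emission spectra and angle-resolved maps (H × G) |
| `lietsim.iv_simmons` | tunnelling I–V forward model, FN representation, fitting |
| `lietsim.sensing_metrics` | sensing readout and limit of detection |
| `lietsim.synthetic_data` | seeded synthetic spectra, I–V curves, images, dose series |
| `lietsim.cli` | `lietsim` command-line entry point |
| `lietsim._tmm`, `lietsim._rcwa` | low-level planar / periodic Maxwell solvers |

## CLI

All commands take a YAML config (strictly validated — unknown keys are
rejected) and write their outputs, a resolved-config copy and a log into the
chosen output directory:

```bash
lietsim spectrum  -c config.yaml -o out/   # emission spectra vs bias + peak report
lietsim angle-map -c config.yaml -o out/   # angle-resolved emission map (CSV)
lietsim iv-fit    measured_iv.csv -o out/  # barrier fit + Fowler-Nordheim report
lietsim sense     -c config.yaml -o out/   # synthetic dose-response + LOD report
lietsim synth     --kind iv -o out/        # standalone synthetic measurements
```

Minimal config:

```yaml
variant: characterization      # or: sensing / a full device section
biases_v: [1.5, 1.7, 1.9, 2.1, 2.3]
solver:
  n_harmonics: 41
  n_theta: 14
  n_phi: 4                     # azimuth-integrated collection
  wavelength_nm: {min: 500, max: 950, step: 3}
seed: 1
```

## Conventions

Lengths in nm, energies in eV, bias in volts (ħω[eV] = 1239.841984/λ[nm]);
fields use the exp(−iωt) convention so passive media have Im ε ≥ 0. Polar
angles are parameterized by their in-air equivalent (k∥ = k0 sin θ), so the
numerical aperture bounds sin θ directly; emission is collected through the
glass substrate. All absolute intensities are in arbitrary units; quantities
of interest are ratios and peak positions, with normalization divisors
stored on every spectrum object.
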