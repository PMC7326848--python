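# ops-imaging

Feasibility modelling of **ortho-positronium mean-lifetime imaging with
2γ + prompt-γ triple coincidences** on total-body PET scanners.

In roughly 30% of PET events the positron first forms a positronium atom.
The triplet state, ortho-positronium (oPs), lives 142 ns in vacuum but only a
few ns in tissue, where pick-off and conversion processes make it annihilate
into two 511 keV photons: for a tissue lifetime τ = 2 ns the 2γ channel is
(1 − τ/τ_vac)/(τ/τ_vac) = 70 times more frequent than the intrinsic 3γ decay.
Because the oPs lifetime tracks tissue nanostructure and bio-active molecule
concentrations, a spatially resolved map of the *mean oPs lifetime* is a
candidate diagnostic observable alongside the standard uptake image.

The experimental handle is a radiopharmaceutical labelled with ⁴⁴Sc, whose
β⁺ decay is accompanied by a 1160 keV prompt photon that timestamps the
positronium creation.  A triple coincidence — two back-to-back 511 keV
photons plus the prompt — gives, per event,

- the annihilation point along the line of response (LOR) from time of
  flight, **x = x_mid + û · c·(t₁ − t₂)/2** (30 ps ↔ 4.5 mm),
- the annihilation time t_a = (t₁ + t₂)/2 − |r₁ − r₂|/(2c),
- the positron emission time from the prompt hit, t_e = t_p − |r_p − x|/c,

so Δt = t_a − t_e is an estimate of the oPs lifetime that can be histogrammed
per voxel; the voxel mean recovers the local mean lifetime with statistical
error ≈ √(τ² + σ_eff²)/√N ≈ τ/√N.

The package implements the full study around this idea:

| module | contents |
|---|---|
| `ops_imaging.physics` | constants, material presets (LYSO, plastic, water), branching arithmetic, closed-form detection efficiency 1 − e^(−μd/sinθ) and phantom attenuation e^(−μ_w R/sinθ) |
| `ops_imaging.sensitivity` | numeric evaluation of the sensitivity integral S = ∫dz [∫(ε_a·Att_a)² sinθ dθ][∫ε_p·Att_p sinθ dθ], gain curves vs axial field of view (AFOV), parity ("crossover") AFOVs, projected count rates |
| `ops_imaging.generator` | synthetic ⁴⁴Sc decays: six point sources in a NEMA-style arrangement with lifetimes 2.0–3.0 ns, isotropic independent photon directions, exponential lifetimes |
| `ops_imaging.detector` | idealised plastic total-body scanner (R = 43 cm, AFOV = 200 cm, 6 cm plastic): ray tracing, exponential interaction sampling, Klein–Nishina Compton deposits, Gaussian position/time smearing, (200, 400) keV triple selection |
| `ops_imaging.reconstruct` | TOF event reconstruction, direct (histogram) images, list-mode TOF-FBP with deconvolution, PSF extraction |
| `ops_imaging.lifetime` | per-voxel mean-lifetime images, estimator cross-checks, resolution-vs-statistics law, generated-vs-reconstructed comparisons |
| `ops_imaging.pipeline` | config-driven end-to-end runs with manifests and deterministic seeding |

## Worked example

`examples/` contains one short script per capability.  For instance:

```bash
$ python examples/01_sensitivity_gains.py
lyso     AFOV=200 cm: triple gain  13.5x, 2-gamma gain  46.1x, parity AFOV  56.0 cm
plastic  AFOV=200 cm: triple gain   5.2x, 2-gamma gain  27.0x, parity AFOV  86.2 cm
```

A 200-cm LYSO (plastic) scanner registers and selects 13.5× (5.2×) more
image-forming triple coincidences than a conventional 20-cm LYSO scanner
collects plain 2γ events — positronium imaging on a total-body scanner is
*more* sensitive than today's metabolic imaging, reaching parity already at
56 cm (87 cm) axial length.  And:

```bash
$ python examples/05_resolution_law.py   # abridged
tau = 2 ns, sigma_eff = 190 ps (CRT = 500 ps chain noise):
    n   rms_ps  analytic_ps
10000    19.91        20.09
```

with N = 10⁴ triple coincidences per voxel — the statistics a 370 MBq,
20-min total-body scan is projected to deliver per cm³ — the voxel mean
lifetime is determined to ≈ 20 ps RMS, essentially independent of the
scanner's coincidence resolving time (CRT) between 10 and 500 ps, because
the exponential-lifetime variance dominates the timing noise.

Other examples print the registration-efficiency-vs-threshold table, the
direct-image and TOF-FBP point-spread functions as a function of CRT, and
the per-source reconstructed-vs-generated lifetime comparison.

A thin CLI mirrors the library (`ops-imaging sensitivity|crossover|generate|
efficiency|resolution|run-study`), e.g.
`ops-imaging run-study --n 200000 --seed 7 --outdir run1` writes activity and
lifetime NIfTI volumes, PSF and lifetime summary tables and a JSON manifest.

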