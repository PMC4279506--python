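# lumiderm

Monte Carlo simulation of transcutaneous optical power delivery: how much
near-infrared light from a wearable LED source gets through skin to an
implanted photovoltaic cell, and how much electric power that cell can
return for recharging implantable biosensors.

The package is for biomedical-optics and implantable-device engineers who
need seedable, validated photon-transport numbers for layered skin — per-layer
absorbed fractions, diffuse/specular reflectance, energy-density maps,
energy-versus-depth curves, detector capture fractions and recoverable-power
estimates — from plain-text configuration, with every run reproducible
bit-for-bit from its seed.

## Model

Skin is four plane-parallel slabs — epidermis (0.065 mm), dermis (1.25 mm),
fat (12 mm), semi-infinite muscle — each with tabulated absorption and
scattering coefficients μa, μs (cm⁻¹), Henyey–Greenstein anisotropy g and
refractive index n at 800–900 nm. Photons execute the standard
layered-media random walk: exponential steps in optical depth −ln ξ / μt,
partial weight deposition μa/μt per interaction, Henyey–Greenstein
deflection, unpolarised Fresnel reflection / Snell refraction at index
mismatches, Russian-roulette termination. Tallies accumulate on a
cylindrical (r, z) grid (0.05 mm bins by default).

The LED spectrum is Gaussian, f(λ) = a1·exp(−((λ−b1)/c1)²) with a1 = 0.5494,
b1 = 850 nm, c1 = 24.93 nm, discretised at 800/825/850/875/900 nm
(proportions 0.0098/0.2010/0.5494/0.2010/0.0098); per-wavelength runs are
combined with normalised spectral weights. Source optics reduce to a spot of
diameter d = D·l/((n−1)·R) with irradiance I = 4P/(πd²), checked against the
ICNIRP skin limit 2.0×10³·C_A W/m².

## Worked example

```python
from lumiderm import default_skin_stack, default_source, run_spectrum, RunSettings
from lumiderm.pipeline import energy_at_depth, estimate_electric_power

stack = default_skin_stack()            # tabulated four-layer skin
source = default_source()               # 850 nm LED, 10 mm spot radius
settings = RunSettings(n_photons=100_000, seed=1)

result = run_spectrum(stack, source, settings, incident_energy_J=10.0)
for key, value in result.summary().items():
    print(f"{key}: {value:.4f}")
print("muscle-arrival energy:",
      round(energy_at_depth(result, 12.0, within_radius_mm=10.0), 3), "J")
```

prints

```
incident_energy_J: 10.0000
specular_reflectance: 0.0211
diffuse_reflectance: 0.1338
transmittance: 0.0000
absorbed_fraction_epidermis: 0.6190
absorbed_fraction_epidermis_binned: 0.4821
absorbed_fraction_dermis: 0.0347
absorbed_fraction_dermis_binned: 0.1712
absorbed_fraction_fat: 0.1133
absorbed_fraction_fat_binned: 0.1137
absorbed_fraction_muscle: 0.0781
absorbed_fraction_muscle_binned: 0.0782
muscle-arrival energy: 0.475 J
```

Reading: 2.1% of the light is lost to specular reflection at the air–skin
interface and 13.4% re-emerges as diffuse reflectance; the rest is absorbed
on the way down (the `_binned` fractions attribute absorption to layers via
the 0.05 mm depth grid, the reporting convention of layered-media MC codes;
the unsuffixed values use exact layer boundaries — see `docs/methods.md`).
Of 10 J incident, about 0.48 J reaches the muscle layer within the 10 mm
effective spot. A photovoltaic cell receiving 34 mW of optical power at
10–20% efficiency returns 3.4–6.8 mW of electric power
(`estimate_electric_power(34, 0.10, 0.20)`).

The same runs are available from the shell:

```sh
lumiderm spectrum                       # discrete spectral weights
lumiderm safety-check                   # ICNIRP irradiance check
lumiderm simulate --wavelength 850 --photons 100000 --seed 42 --out run850/
lumiderm spectral-run --seed 7 --incident-joules 10 --out spectral/
lumiderm validate                       # built-in physics oracles
```

Outputs are plain CSV plus a `manifest.json` with seeds and SHA-256
checksums sufficient to re-run bit-identically.

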