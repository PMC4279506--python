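# Methods

## Problem and model

`lumiderm` estimates how much optical energy a wearable near-infrared LED
delivers through skin to an implanted photovoltaic cell, and the electric
power that cell can return for recharging an implantable biosensor.

Tissue is modelled as four plane-parallel, laterally infinite slabs —
epidermis (0.065 mm), dermis (1.25 mm), fat (12 mm) and an effectively
semi-infinite muscle layer (10^8 mm, so no photon ever reaches the lower
boundary) — each with tabulated absorption coefficient mu_a, scattering
coefficient mu_s (cm^-1), Henyey–Greenstein anisotropy g and refractive
index n for the five simulation wavelengths 800, 825, 850, 875, 900 nm.
Epidermis properties vary so little over this band that a single row is
used.  Dispersion is ignored: n is wavelength-independent per layer.  Air
(n = 1.0) sits above the stack; the lower boundary is index-matched to
muscle (no bottom-boundary physics, consistent with a terminal layer).
Coefficients are stored in cm^-1 exactly as tabulated and converted once to
mm^-1 at run time; all lengths are mm.

A note on the default thicknesses: the layer thicknesses carried by the
property table (0.065 / 1.25 / 12 mm) are used, because the interface depths
they imply (0.065, 1.315, 13.315 mm) are the ones the downstream energy
analysis refers to.  Alternative thicknesses can be supplied through the
YAML config.

## LED source

The source spectrum is a Gaussian proportion
f(λ) = a1·exp(−((λ−b1)/c1)²) with defaults a1 = 0.5494, b1 = 850 nm,
c1 = 24.93 nm, discretised at the five simulation wavelengths, giving the
proportions 0.0098 / 0.2010 / 0.5494 / 0.2010 / 0.0098.  These raw values
sum to 0.971, so spectral aggregation uses weights normalised to sum to 1;
otherwise the combined energy would silently lose 2.9% of the incident
energy.  The raw values remain accessible.

The lens optics are reduced to spot geometry: a planoconvex lens of
aperture D, curvature radius R and index n illuminates a spot of diameter
d = D·l/((n−1)·R) at distance l from the focus; incident irradiance is
I = 4P/(πd²).  Defaults (D = 25 mm, R = 12.5 mm, n = 1.5, l = 5 mm) give a
20 mm spot, i.e. the 10 mm beam radius used by the transport runs.  The
LED's 60° divergence half-angle and the reflector are not modelled
optically; the transport model sees a normally incident flat-top disk of
the stated radius, because no angular distribution at the skin is
specified for the assembled source.  Irradiance is checked against the
ICNIRP skin limit for 400–1400 nm, 2.0×10³·C_A W/m² (exposure ≤ 8.33 h);
C_A defaults conservatively to 1 and is configurable.  The bound is applied
inclusively (irradiance exactly at the limit passes).

## Photon transport

The engine is the standard variance-reduced random walk for layered turbid
media:

- **Launch** — uniform over the beam disk (r = R√ξ), direction (0,0,1),
  weight 1; a pencil-beam mode exists for closed-form oracles.  The Fresnel
  normal-incidence specular fraction ((n_air−n_epi)/(n_air+n_epi))² = 0.0211
  is deducted deterministically at entry.
- **Steps** — dimensionless optical depth −ln ξ, converted by the local
  mu_t; the residual depth is carried across boundaries and rescaled by the
  new layer's mu_t.
- **Interaction** — weight fraction mu_a/mu_t is deposited into the
  cylindrical (r, z) tally and the per-layer accumulator; the direction is
  then deflected by a Henyey–Greenstein angle (inverse-CDF sampling) with
  uniform azimuth.
- **Boundaries** — unpolarised Fresnel reflection probability (total
  internal reflection beyond the critical angle); on transmission Snell
  refraction and a layer-index update; photons leaving the top/bottom are
  tallied as diffuse reflectance/transmittance by exit radius.
- **Termination** — Russian roulette below weight 10^-4 with survival
  probability 0.1 (the conventional defaults).  Roulette is unbiased only
  in expectation, so the kernel additionally tracks the net weight it
  destroys/injects; including that term, every run's energy budget
  (specular + diffuse reflectance + transmittance + absorption) closes to
  float precision, which the tests assert at 1e-9.

The hot loop is compiled with numba; all single-photon primitives are the
same compiled helpers the Python-level API exposes, so the unit tests
exercise exactly the arithmetic of the full runs.  Randomness comes from
numba's Mersenne-Twister stream seeded per run; identical (seed, settings,
stack) inputs give bit-identical tallies, and the per-wavelength child
seeds are derived from the master seed via `numpy.random.SeedSequence`
(recorded in the run manifest).

Default tallies: dr = dz = 0.05 mm, 1600 radial bins (to 80 mm) and 400
depth bins (to 20 mm), plus one overflow bin per axis so no deposit is ever
lost.  A separate radially resolved tally records each photon's *first*
downward crossing of every z-plane; this is the basis of the
energy-versus-depth curve and the detector capture fractions.

## Validation oracles

The built-in suite (`lumiderm validate`, also run by the tests) checks the
engine against independent closed forms: Beer–Lambert transmittance
exp(−mu_a·L) for scattering-free slabs at three optical depths; the
normal-incidence Fresnel value 0.02111 for air/epidermis; the
Henyey–Greenstein mean cosine E[cos θ] = g for g ∈ {0, 0.62, 0.85}; exact
budget closure; and bit-identical seed determinism.  During development the
engine was additionally checked against the H-function plane albedo of a
matched semi-infinite isotropic medium (albedo 0.9: measured 0.4146, exact
0.4152) and against an independently written vectorised NumPy random walk
for the index-mismatched case (agreement within MC error).

## Reporting conventions

Two conventions matter when comparing with published figures for this kind
of simulation, and the package computes both:

- **Per-layer absorbed fractions.**  The exact tally attributes each
  deposit to the layer the photon was in (`absorbed_fraction_by_layer`).
  The *grid-attributed* convention (`..._binned`) — standard in
  layered-media MC codes whose layer totals are summed from the depth grid —
  assigns each 0.05 mm depth bin to the layer containing its centre, so the
  0.065 mm epidermis owns only the first bin and the straddling bin counts
  toward the dermis.  With the default properties the two conventions give
  epidermis/dermis 0.62/0.035 (exact) versus 0.48/0.17 (grid-attributed) at
  850 nm while agreeing on fat, muscle and every total.  Summary outputs
  report both; headline layer fractions quote the grid-attributed values.
- **Energy versus depth.**  `energy_at_depth(z)` is the downward-crossing
  energy through the full infinite plane at z; with
  `within_radius_mm` set it is restricted to a coaxial disk — e.g. the
  source's 10 mm effective spot radius, or a photovoltaic aperture.  The
  headline "energy reaching the muscle layer" quotes the effective-area
  value, since far-field energy spread over tens of mm of radius cannot be
  captured by a centimetre-scale implant.  Both values appear in
  `energy_vs_depth.csv` / `capture_report.csv`.

Fractions are expressed per unit of *launched* energy, with specular
reflection part of the budget.

## Energy density and capture

Absorbed energy maps are emitted in two unit conventions: areal (J/mm²,
deposited energy per annulus area per depth bin) and volumetric (J/mm³).
`captured_fraction(radius, depth)` integrates the radially resolved
crossing tally at the nearest plane, with the straddling bin weighted by
annular-area overlap, and is nondecreasing in the radius by construction.
The recoverable electric power band multiplies the captured optical power
by a flat photovoltaic efficiency range (default 10–20%); the capture
report expresses it per second of exposure at the stated incident energy.

## Problem sizes and numerical choices

Reference runs use 10^5 photons per wavelength (5×10^5 per spectral run),
which resolves the headline fractions to a standard error of about 0.0015
and completes in a few seconds per wavelength; unit tests use 10³–3×10⁴
photon ensembles against 3σ Monte Carlo bounds.  Linear interpolation is
used both for optical properties at non-tabulated wavelengths and for the
energy-depth curve between tally planes.  Ties at layer boundaries resolve
by the half-open convention [boundary_i, boundary_{i+1}); a photon exactly
on a boundary belongs to the lower-indexed interval.  Layers with
mu_t = 0 are rejected (vacuum transport is unsupported).

## Limitations

- The simulated beam is an idealisation (flat-top, normally incident); the
  real source's angular spread and reflector losses are not modelled.
- No polarisation, coherence or interference (the source is incoherent by
  premise), and no time-resolved transport.
- The synthetic tissue stack is plane-parallel and homogeneous per layer;
  real skin has curvature, appendages and lateral heterogeneity, so
  passing tests demonstrate correctness of the transport model under the
  stated conditions, not predictive accuracy for any individual patient.
- The dermis index (1.55) exceeding both neighbours is taken as printed;
  its physical plausibility is not adjudicated.
- Thermal and photochemical safety are out of scope beyond the ICNIRP
  irradiance bound.
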