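"""Monte Carlo engine API: run settings, tallies, results and primitives.

``run_single_wavelength`` is the main entry point: it transports a photon
ensemble through a :class:`~lumiderm.tissue.TissueStack` at one wavelength
and returns a :class:`SimResult` with normalised tallies.  The module also
exposes the single-photon primitives (launch, step sampling, deposition,
Henyey-Greenstein scattering, Fresnel boundary interaction, roulette) as
plain functions operating on :class:`PhotonState`, thin wrappers over the
same compiled helpers the kernel uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .tissue import OpticalProperties, TissueStack

__all__ = [
    "RunSettings",
    "PhotonState",
    "TallyGrid",
    "SimResult",
    "launch",
    "specular_reflect",
    "sample_step",
    "deposit",
    "scatter_hg",
    "fresnel_reflectance",
    "boundary_interact",
    "roulette",
    "run_single_wavelength",
]

_MAX_SEED = 2**31


@dataclass(frozen=True)
class RunSettings:
    """Photon count, seeding, beam and tally-grid configuration.

    The beam is either a flat-top disk of ``beam_radius_mm`` (default 10 mm,
    uniform launch density, normal incidence) or an on-axis pencil.  Tallies
    use a cylindrical grid of ``nr`` radial bins of width ``dr_mm`` and
    ``nz`` depth bins of width ``dz_mm`` (defaults resolve 0-80 mm radially
    and 0-20 mm in depth at 0.05 mm), plus one overflow bin per axis.
    Russian roulette triggers below ``roulette_threshold`` with survival
    probability ``roulette_survival``.
    """

    n_photons: int = 100_000
    seed: int = 1
    beam_radius_mm: float = 10.0
    beam_profile: str = "flat"
    dr_mm: float = 0.05
    dz_mm: float = 0.05
    nr: int = 1600
    nz: int = 400
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1

    def __post_init__(self) -> None:
        if self.n_photons <= 0:
            raise ValueError("n_photons must be > 0")
        if not 0 <= self.seed < _MAX_SEED:
            raise ValueError(f"seed must be in [0, 2^31), got {self.seed}")
        if self.beam_profile not in ("flat", "pencil"):
            raise ValueError("beam_profile must be 'flat' or 'pencil'")
        if self.beam_profile == "flat" and self.beam_radius_mm <= 0:
            raise ValueError("flat beam needs beam_radius_mm > 0")
        if self.dr_mm <= 0 or self.dz_mm <= 0 or self.nr <= 0 or self.nz <= 0:
            raise ValueError("tally grid bins must be positive")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette_survival must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_photons": self.n_photons,
            "seed": self.seed,
            "beam_radius_mm": self.beam_radius_mm,
            "beam_profile": self.beam_profile,
            "dr_mm": self.dr_mm,
            "dz_mm": self.dz_mm,
            "nr": self.nr,
            "nz": self.nz,
            "roulette_threshold": self.roulette_threshold,
            "roulette_survival": self.roulette_survival,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunSettings":
        allowed = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"run config: unknown keys {sorted(unknown)}")
        return cls(**d)


@dataclass
class PhotonState:
    """One photon's position, direction cosines, weight and bookkeeping."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    ux: float = 0.0
    uy: float = 0.0
    uz: float = 1.0
    weight: float = 1.0
    layer: int = 0
    alive: bool = True

    @property
    def r(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass
class TallyGrid:
    """Raw weight tallies of one run (not yet normalised per photon).

    Radial index ``nr`` and depth index ``nz`` of each array are overflow
    bins.  ``crossing_energy[ir, p]`` holds weight first crossing the plane
    at depth ``p * dz_mm`` downward, binned by radius at the crossing point.
    ``roulette_net`` is the weight destroyed minus injected by roulette;
    adding it closes the energy budget exactly.
    """

    dr_mm: float
    dz_mm: float
    nr: int
    nz: int
    n_layers: int
    n_launched: int = 0
    specular: float = 0.0
    roulette_net: float = 0.0
    absorption: np.ndarray = field(default=None)  # type: ignore[assignment]
    reflectance_diffuse: np.ndarray = field(default=None)  # type: ignore[assignment]
    transmittance: np.ndarray = field(default=None)  # type: ignore[assignment]
    per_layer_absorbed: np.ndarray = field(default=None)  # type: ignore[assignment]
    crossing_energy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.absorption is None:
            self.absorption = np.zeros((self.nr + 1, self.nz + 1))
        if self.reflectance_diffuse is None:
            self.reflectance_diffuse = np.zeros(self.nr + 1)
        if self.transmittance is None:
            self.transmittance = np.zeros(self.nr + 1)
        if self.per_layer_absorbed is None:
            self.per_layer_absorbed = np.zeros(self.n_layers)
        if self.crossing_energy is None:
            self.crossing_energy = np.zeros((self.nr + 1, self.nz + 1))

    def radial_bin(self, r_mm: float) -> int:
        return min(int(r_mm / self.dr_mm), self.nr)

    def depth_bin(self, z_mm: float) -> int:
        return min(int(z_mm / self.dz_mm), self.nz)

    @property
    def budget_residual(self) -> float:
        """(specular + reflected + transmitted + absorbed + roulette_net) - launched."""
        total = (
            self.specular
            + self.reflectance_diffuse.sum()
            + self.transmittance.sum()
            + self.per_layer_absorbed.sum()
            + self.roulette_net
        )
        return float(total - self.n_launched)


@dataclass(frozen=True)
class SimResult:
    """Normalised outcome of one single-wavelength transport run.

    Fractions are per unit of *launched* energy (specular reflection is part
    of the budget).  ``incident_energy_J`` scales the energy-density and
    crossing-energy accessors.
    """

    wavelength_nm: float
    stack: TissueStack
    settings: RunSettings
    grid: TallyGrid
    incident_energy_J: float = 1.0

    @property
    def n_photons(self) -> int:
        return self.grid.n_launched

    @property
    def specular_reflectance(self) -> float:
        return self.grid.specular / self.n_photons

    @property
    def diffuse_reflectance(self) -> float:
        return float(self.grid.reflectance_diffuse.sum()) / self.n_photons

    @property
    def transmittance(self) -> float:
        return float(self.grid.transmittance.sum()) / self.n_photons

    @property
    def absorbed_fraction_by_layer(self) -> np.ndarray:
        return self.grid.per_layer_absorbed / self.n_photons

    @property
    def total_absorbed_fraction(self) -> float:
        return float(self.grid.per_layer_absorbed.sum()) / self.n_photons

    @property
    def absorbed_fraction_by_layer_binned(self) -> np.ndarray:
        """Per-layer absorbed fractions attributed via the depth tally grid.

        Each z-bin's absorption is assigned to the layer containing the bin
        centre (the conventional grid-based layer attribution of layered-media
        MC codes); a bin straddling a boundary therefore counts wholly toward
        the layer owning its centre, unlike the exact-boundary tally in
        :attr:`absorbed_fraction_by_layer`.  The depth-overflow bin goes to
        the last layer.
        """
        grid = self.grid
        per_depth = grid.absorption.sum(axis=0)  # includes radial overflow
        centers = (np.arange(grid.nz) + 0.5) * grid.dz_mm
        bounds = self.stack.boundaries_mm
        layer_of_bin = np.clip(
            np.searchsorted(bounds, centers, side="right") - 1, 0, self.stack.n_layers - 1
        )
        out = np.zeros(self.stack.n_layers)
        np.add.at(out, layer_of_bin, per_depth[: grid.nz])
        out[-1] += per_depth[grid.nz]
        return out / self.n_photons

    @property
    def budget_closure(self) -> float:
        """Sum of all fractions plus the roulette correction; 1.0 exactly."""
        return (
            self.specular_reflectance
            + self.diffuse_reflectance
            + self.transmittance
            + self.total_absorbed_fraction
            + self.grid.roulette_net / self.n_photons
        )

    def mc_standard_error(self, fraction: float) -> float:
        """Binomial-style standard error of a tallied fraction."""
        f = min(max(fraction, 0.0), 1.0)
        return math.sqrt(f * (1.0 - f) / self.n_photons)

    # -- grid coordinate helpers -------------------------------------------------

    @property
    def r_centers_mm(self) -> np.ndarray:
        return (np.arange(self.grid.nr) + 0.5) * self.grid.dr_mm

    @property
    def r_edges_mm(self) -> np.ndarray:
        return np.arange(self.grid.nr + 1) * self.grid.dr_mm

    @property
    def z_centers_mm(self) -> np.ndarray:
        return (np.arange(self.grid.nz) + 0.5) * self.grid.dz_mm

    @property
    def plane_depths_mm(self) -> np.ndarray:
        return np.arange(self.grid.nz + 1) * self.grid.dz_mm

    @property
    def annulus_areas_mm2(self) -> np.ndarray:
        edges = self.r_edges_mm
        return math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)

    # -- energy accessors --------------------------------------------------------

    def absorbed_energy_rz(self) -> np.ndarray:
        """Absorbed energy (J) per (r, z) bin, overflow bins excluded."""
        core = self.grid.absorption[: self.grid.nr, : self.grid.nz]
        return self.incident_energy_J * core / self.n_photons

    def energy_density_areal(self) -> np.ndarray:
        """Absorbed energy per annulus area, J/mm^2, shape (nr, nz)."""
        return self.absorbed_energy_rz() / self.annulus_areas_mm2[:, None]

    def energy_density_volumetric(self) -> np.ndarray:
        """Absorbed energy per bin volume, J/mm^3, shape (nr, nz)."""
        return self.energy_density_areal() / self.grid.dz_mm

    def crossing_energy_J(self) -> np.ndarray:
        """Energy (J) first crossing each tally plane downward, radially summed."""
        return self.incident_energy_J * self.grid.crossing_energy.sum(axis=0) / self.n_photons

    def summary(self) -> dict:
        fracs = self.absorbed_fraction_by_layer
        out = {
            "wavelength_nm": self.wavelength_nm,
            "n_photons": self.n_photons,
            "seed": self.settings.seed,
            "specular_reflectance": self.specular_reflectance,
            "diffuse_reflectance": self.diffuse_reflectance,
            "transmittance": self.transmittance,
        }
        binned = self.absorbed_fraction_by_layer_binned
        for layer, f, fb in zip(self.stack.layers, fracs, binned):
            out[f"absorbed_fraction_{layer.name}"] = float(f)
            out[f"absorbed_fraction_{layer.name}_binned"] = float(fb)
        return out


# -- single-photon primitives ----------------------------------------------------


def launch(settings: RunSettings, rng: np.random.Generator) -> PhotonState:
    """Create a photon at the surface, normally incident, unit weight.

    Flat profile: radial position r = R * sqrt(xi) uniform over the disk.
    """
    if settings.beam_profile == "pencil":
        return PhotonState()
    r = settings.beam_radius_mm * math.sqrt(rng.random())
    phi = 2.0 * math.pi * rng.random()
    return PhotonState(x=r * math.cos(phi), y=r * math.sin(phi))


def specular_reflect(n_above: float, n_first_layer: float) -> float:
    """Normal-incidence Fresnel fraction reflected at the entry surface."""
    r = (n_above - n_first_layer) / (n_above + n_first_layer)
    return r * r


def sample_step(mu_t_per_mm: float, rng: np.random.Generator) -> float:
    """Exponential free path (mm) with mean 1/mu_t."""
    if mu_t_per_mm <= 0:
        raise ValueError("mu_t must be > 0 (non-interacting layers unsupported)")
    return _kernel.step_from_xi(1.0 - rng.random(), mu_t_per_mm)


def deposit(photon: PhotonState, props: OpticalProperties, grid: TallyGrid) -> float:
    """Deposit the interaction's absorbed share mu_a/mu_t of the weight.

    Updates the (r, z) absorption grid and the per-layer accumulator;
    returns (and sets) the photon's reduced weight.
    """
    dw = photon.weight * props.mu_a / props.mu_t
    grid.absorption[grid.radial_bin(photon.r), grid.depth_bin(photon.z)] += dw
    grid.per_layer_absorbed[photon.layer] += dw
    photon.weight -= dw
    return photon.weight


def scatter_hg(
    ux: float, uy: float, uz: float, g: float, rng: np.random.Generator
) -> tuple[float, float, float]:
    """New direction cosines after a Henyey-Greenstein scattering event."""
    cos_t = _kernel.hg_cos_from_xi(g, rng.random())
    phi = 2.0 * math.pi * rng.random()
    return _kernel.rotate_direction(ux, uy, uz, cos_t, phi)


def fresnel_reflectance(n1: float, n2: float, cos_i: float) -> float:
    """Unpolarised Fresnel reflectance for incidence cosine ``cos_i``."""
    return _kernel.fresnel_unpolarized(n1, n2, cos_i)[0]


def boundary_interact(
    photon: PhotonState,
    stack: TissueStack,
    rng: np.random.Generator,
    wavelength_nm: float,
) -> bool:
    """Resolve a boundary hit for a photon sitting on a layer interface.

    The crossing direction follows the sign of ``uz``.  Returns True if the
    photon transmitted (refracting by Snell's law, updating the layer index,
    or escaping the stack), False if it reflected (``uz`` negated).  Escaped
    photons are marked dead.
    """
    going_down = photon.uz > 0
    n1 = stack.properties_at(photon.layer, wavelength_nm).n
    if going_down:
        exiting = photon.layer == stack.n_layers - 1
        n2 = (
            stack.n_below_effective(wavelength_nm)
            if exiting
            else stack.properties_at(photon.layer + 1, wavelength_nm).n
        )
    else:
        exiting = photon.layer == 0
        n2 = stack.n_above if exiting else stack.properties_at(photon.layer - 1, wavelength_nm).n
    r_f, cos_t = _kernel.fresnel_unpolarized(n1, n2, abs(photon.uz))
    if rng.random() < r_f:
        photon.uz = -photon.uz
        return False
    scale = n1 / n2
    photon.ux *= scale
    photon.uy *= scale
    photon.uz = cos_t if going_down else -cos_t
    if exiting:
        photon.alive = False
    else:
        photon.layer += 1 if going_down else -1
    return True


def roulette(photon: PhotonState, settings: RunSettings, rng: np.random.Generator) -> PhotonState:
    """Russian roulette: unbiased termination of low-weight photons."""
    if photon.weight >= settings.roulette_threshold:
        return photon
    if rng.random() < settings.roulette_survival:
        photon.weight /= settings.roulette_survival
    else:
        photon.weight = 0.0
        photon.alive = False
    return photon


# -- full run ---------------------------------------------------------------------


def run_single_wavelength(
    stack: TissueStack,
    settings: RunSettings,
    wavelength_nm: float,
    incident_energy_J: float = 1.0,
) -> SimResult:
    """Transport an ensemble through ``stack`` at one wavelength.

    Deterministic for fixed (seed, settings, stack): identical inputs give
    bit-identical tallies.
    """
    n_lay = stack.n_layers
    mu_a = np.empty(n_lay)
    mu_s = np.empty(n_lay)
    g = np.empty(n_lay)
    n_idx = np.empty(n_lay)
    for i in range(n_lay):
        p = stack.properties_at(i, wavelength_nm)
        mu_a[i] = p.mu_a / 10.0  # cm^-1 -> mm^-1
        mu_s[i] = p.mu_s / 10.0
        g[i] = p.g
        n_idx[i] = p.n
        if mu_a[i] + mu_s[i] <= 0:
            raise ValueError(
                f"layer {stack.layers[i].name!r} has mu_t = 0 at {wavelength_nm} nm; "
                "non-interacting layers are unsupported"
            )
    beam_radius = settings.beam_radius_mm if settings.beam_profile == "flat" else 0.0
    out = _kernel.run_photons(
        settings.n_photons,
        settings.seed,
        beam_radius,
        settings.dr_mm,
        settings.dz_mm,
        settings.nr,
        settings.nz,
        settings.roulette_threshold,
        settings.roulette_survival,
        stack.boundaries_mm,
        mu_a,
        mu_s,
        g,
        n_idx,
        stack.n_above,
        stack.n_below_effective(wavelength_nm),
    )
    specular, refl, trans, absorb, per_layer, crossing, roulette_net = out
    grid = TallyGrid(
        dr_mm=settings.dr_mm,
        dz_mm=settings.dz_mm,
        nr=settings.nr,
        nz=settings.nz,
        n_layers=n_lay,
        n_launched=settings.n_photons,
        specular=float(specular),
        roulette_net=float(roulette_net),
        absorption=absorb,
        reflectance_diffuse=refl,
        transmittance=trans,
        per_layer_absorbed=per_layer,
        crossing_energy=crossing,
    )
    return SimResult(
        wavelength_nm=wavelength_nm,
        stack=stack,
        settings=settings,
        grid=grid,
        incident_energy_J=incident_energy_J,
    )
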