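"""Wearable LED source model: Gaussian spectrum, lens/spot geometry, safety.

The LED emits an incoherent near-infrared band modelled as a Gaussian
spectral density f(lambda) = a1 * exp(-((lambda - b1) / c1)^2), discretised
onto a small set of simulation wavelengths.  A planoconvex lens focuses the
beam; the illuminated spot diameter on the skin follows thin-lens geometry
from the lens aperture D, curvature radius R, index n and the skin-to-focus
distance l.  Incident irradiance is checked against the ICNIRP skin-exposure
limit for 400-1400 nm light.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectrumModel",
    "SourceGeometry",
    "SafetySpec",
    "SourceSpec",
    "SafetyResult",
    "spectral_proportion",
    "discretize_spectrum",
    "spot_diameter",
    "spot_area",
    "power_density",
    "check_safety",
    "default_source",
]

#: Default simulation wavelengths (nm) spanning the LED's 800-900 nm band.
DEFAULT_WAVELENGTHS = (800.0, 825.0, 850.0, 875.0, 900.0)


@dataclass(frozen=True)
class SpectrumModel:
    """Gaussian LED spectrum with a discrete wavelength comb.

    ``a1`` is the peak spectral proportion, ``b1`` the central wavelength
    (nm) and ``c1`` the Gaussian width (nm).  ``discrete_wavelengths`` are
    the wavelengths actually simulated; their weights come from evaluating
    the Gaussian there.
    """

    a1: float = 0.5494
    b1: float = 850.0
    c1: float = 24.93
    discrete_wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        if self.a1 <= 0:
            raise ValueError("a1 must be > 0")
        if self.c1 <= 0:
            raise ValueError("c1 must be > 0")
        if not self.discrete_wavelengths:
            raise ValueError("need at least one discrete wavelength")

    def proportion(self, wavelength_nm: float) -> float:
        return spectral_proportion(self, wavelength_nm)

    def discretize(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return discretize_spectrum(self)


@dataclass(frozen=True)
class SourceGeometry:
    """Lens and beam geometry of the wearable source.

    ``D_mm``/``R_mm``/``n_lens`` describe the planoconvex lens (aperture,
    curvature radius, index); ``l_mm`` is the distance from the lens focus to
    the skin surface, which sets the defocused spot size.  ``power_mW`` is
    the total optical power delivered to the spot.  The LED half-angle
    ``divergence_theta_deg`` is retained for reference; the transport model
    reduces the optics to a normally incident spot of the stated diameter.
    """

    D_mm: float = 25.0
    R_mm: float = 12.5
    n_lens: float = 1.5
    l_mm: float = 5.0
    divergence_theta_deg: float = 60.0
    power_mW: float = 10.0

    def __post_init__(self) -> None:
        if self.D_mm <= 0 or self.R_mm <= 0:
            raise ValueError("lens aperture and curvature radius must be > 0")
        if self.n_lens <= 1:
            raise ValueError("lens index must be > 1")
        if self.l_mm < 0:
            raise ValueError("skin-to-focus distance must be >= 0")
        if self.power_mW < 0:
            raise ValueError("power must be >= 0")

    @property
    def spot_diameter_mm(self) -> float:
        return spot_diameter(self)

    @property
    def spot_area_mm2(self) -> float:
        return spot_area(self)


@dataclass(frozen=True)
class SafetySpec:
    """ICNIRP skin-irradiance limit for 400-1400 nm exposure.

    The base limit is 2.0e3 W/m^2 scaled by the wavelength-dependent factor
    C_A (>= 1; defaults conservatively to 1), with exposure time capped at
    8.33 h.
    """

    base_limit_W_m2: float = 2.0e3
    C_A: float = 1.0
    max_exposure_hours: float = 8.33

    def __post_init__(self) -> None:
        if self.base_limit_W_m2 <= 0:
            raise ValueError("base limit must be > 0")
        if self.C_A < 1:
            raise ValueError("C_A must be >= 1")

    @property
    def limit_W_m2(self) -> float:
        return self.base_limit_W_m2 * self.C_A


@dataclass(frozen=True)
class SourceSpec:
    """Complete source description: spectrum + geometry + safety limits."""

    spectrum: SpectrumModel = field(default_factory=SpectrumModel)
    geometry: SourceGeometry = field(default_factory=SourceGeometry)
    safety: SafetySpec = field(default_factory=SafetySpec)

    def to_dict(self) -> dict:
        return {
            "spectrum": {
                "a1": self.spectrum.a1,
                "b1_nm": self.spectrum.b1,
                "c1_nm": self.spectrum.c1,
                "wavelengths_nm": list(self.spectrum.discrete_wavelengths),
            },
            "lens": {
                "D_mm": self.geometry.D_mm,
                "R_mm": self.geometry.R_mm,
                "n": self.geometry.n_lens,
            },
            "l_mm": self.geometry.l_mm,
            "divergence_theta_deg": self.geometry.divergence_theta_deg,
            "power_mW": self.geometry.power_mW,
            "safety": {
                "base_limit_W_m2": self.safety.base_limit_W_m2,
                "C_A": self.safety.C_A,
                "max_hours": self.safety.max_exposure_hours,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SourceSpec":
        allowed = {"spectrum", "lens", "l_mm", "divergence_theta_deg", "power_mW", "safety"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"source config: unknown keys {sorted(unknown)}")
        spec_d = d.get("spectrum", {})
        unknown = set(spec_d) - {"a1", "b1_nm", "c1_nm", "wavelengths_nm"}
        if unknown:
            raise ValueError(f"source.spectrum: unknown keys {sorted(unknown)}")
        lens_d = d.get("lens", {})
        unknown = set(lens_d) - {"D_mm", "R_mm", "n"}
        if unknown:
            raise ValueError(f"source.lens: unknown keys {sorted(unknown)}")
        safety_d = d.get("safety", {})
        unknown = set(safety_d) - {"base_limit_W_m2", "C_A", "max_hours"}
        if unknown:
            raise ValueError(f"source.safety: unknown keys {sorted(unknown)}")
        defaults = cls()
        spectrum = SpectrumModel(
            a1=float(spec_d.get("a1", defaults.spectrum.a1)),
            b1=float(spec_d.get("b1_nm", defaults.spectrum.b1)),
            c1=float(spec_d.get("c1_nm", defaults.spectrum.c1)),
            discrete_wavelengths=tuple(
                float(w)
                for w in spec_d.get("wavelengths_nm", defaults.spectrum.discrete_wavelengths)
            ),
        )
        geometry = SourceGeometry(
            D_mm=float(lens_d.get("D_mm", defaults.geometry.D_mm)),
            R_mm=float(lens_d.get("R_mm", defaults.geometry.R_mm)),
            n_lens=float(lens_d.get("n", defaults.geometry.n_lens)),
            l_mm=float(d.get("l_mm", defaults.geometry.l_mm)),
            divergence_theta_deg=float(
                d.get("divergence_theta_deg", defaults.geometry.divergence_theta_deg)
            ),
            power_mW=float(d.get("power_mW", defaults.geometry.power_mW)),
        )
        safety = SafetySpec(
            base_limit_W_m2=float(
                safety_d.get("base_limit_W_m2", defaults.safety.base_limit_W_m2)
            ),
            C_A=float(safety_d.get("C_A", defaults.safety.C_A)),
            max_exposure_hours=float(safety_d.get("max_hours", defaults.safety.max_exposure_hours)),
        )
        return cls(spectrum=spectrum, geometry=geometry, safety=safety)


@dataclass(frozen=True)
class SafetyResult:
    passed: bool
    irradiance_W_m2: float
    limit_W_m2: float

    @property
    def margin_ratio(self) -> float:
        """Irradiance as a fraction of the limit; <= 1 passes."""
        return self.irradiance_W_m2 / self.limit_W_m2


def spectral_proportion(spec: SpectrumModel, wavelength_nm: float) -> float:
    """Gaussian spectral proportion a1 * exp(-((lambda - b1)/c1)^2)."""
    u = (wavelength_nm - spec.b1) / spec.c1
    return spec.a1 * math.exp(-u * u)


def discretize_spectrum(
    spec: SpectrumModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the spectrum on the discrete comb and normalise the weights.

    Returns ``(wavelengths, raw_weights, normalized_weights)``.  Raw weights
    are the Gaussian evaluated at each wavelength (the conventionally quoted
    proportions); normalised weights divide by their sum so that spectrally
    combined energies conserve the configured incident energy.
    """
    wavelengths = np.asarray(spec.discrete_wavelengths, dtype=float)
    raw = np.array([spectral_proportion(spec, wl) for wl in wavelengths])
    total = raw.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate spectrum: discrete weights sum to zero")
    return wavelengths, raw, raw / total


def spot_diameter(geom: SourceGeometry) -> float:
    """Spot diameter d = D*l / ((n - 1)*R) on the skin surface, mm."""
    return geom.D_mm * geom.l_mm / ((geom.n_lens - 1.0) * geom.R_mm)


def spot_area(geom_or_diameter: SourceGeometry | float) -> float:
    """Spot area pi*(d/2)^2 in mm^2, from a geometry or a bare diameter."""
    d = (
        spot_diameter(geom_or_diameter)
        if isinstance(geom_or_diameter, SourceGeometry)
        else float(geom_or_diameter)
    )
    return math.pi * (d / 2.0) ** 2


def power_density(power_mW: float, spot_diameter_mm: float) -> float:
    """Incident power density I = 4P / (pi d^2), mW/mm^2."""
    if spot_diameter_mm == 0:
        raise ZeroDivisionError(
            "spot diameter is zero (skin at the lens focus); move the skin "
            "surface away from the focus (l > 0) to obtain a finite spot"
        )
    return 4.0 * power_mW / (math.pi * spot_diameter_mm**2)


def check_safety(power_density_mW_mm2: float, safety: SafetySpec | None = None) -> SafetyResult:
    """Compare an incident irradiance with the ICNIRP skin limit.

    1 mW/mm^2 = 1000 W/m^2.  The bound is applied inclusively (irradiance
    exactly at the limit passes, with margin ratio 1.0).
    """
    safety = safety if safety is not None else SafetySpec()
    irradiance = power_density_mW_mm2 * 1000.0
    return SafetyResult(
        passed=irradiance <= safety.limit_W_m2,
        irradiance_W_m2=irradiance,
        limit_W_m2=safety.limit_W_m2,
    )


def default_source() -> SourceSpec:
    """Default wearable source: 850 nm LED, 20 mm spot (10 mm radius)."""
    return SourceSpec()
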