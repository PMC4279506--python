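"""Built-in physics validation suite (closed-form oracles vs the engine).

Each check compares a Monte Carlo estimate against an independent closed
form: Beer-Lambert attenuation for scattering-free slabs, the
normal-incidence Fresnel coefficient, the Henyey-Greenstein mean cosine,
exact energy-budget closure, and bit-identical seed determinism.  Failures
are returned as report entries, not raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mc import RunSettings, run_single_wavelength, scatter_hg, specular_reflect
from .tissue import Layer, OpticalProperties, TissueStack

__all__ = ["CheckResult", "run_validation_suite"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    expected: float
    measured: float
    tolerance: float
    passed: bool

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (
            f"[{status}] {self.name}: measured {self.measured:.6g}, "
            f"expected {self.expected:.6g} (tol {self.tolerance:.3g})"
        )


def absorbing_slab(mu_a_percm: float, thickness_mm: float, mu_s_percm: float = 0.0,
                   g: float = 0.0, n: float = 1.0, n_above: float = 1.0) -> TissueStack:
    """Single-layer stack with matched boundaries, for closed-form oracles."""
    layer = Layer(
        name="slab",
        thickness_mm=thickness_mm,
        properties_by_wavelength={850.0: OpticalProperties(mu_a_percm, mu_s_percm, g, n)},
        wavelength_independent=True,
    )
    return TissueStack(layers=(layer,), n_above=n_above, n_below=n)


def _beer_lambert_checks(n_photons: int, seed: int) -> list[CheckResult]:
    # (mu_a mm^-1, L mm) pairs spanning optical depths 0.5, 1, 2
    pairs = [(0.05, 10.0), (0.1, 10.0), (0.1, 20.0)]
    out = []
    for i, (mu_a_mm, length) in enumerate(pairs):
        stack = absorbing_slab(mu_a_percm=mu_a_mm * 10.0, thickness_mm=length)
        settings = RunSettings(
            n_photons=n_photons, seed=seed + i, beam_profile="pencil",
            beam_radius_mm=1.0, nr=50, nz=50, dz_mm=length / 50.0,
        )
        res = run_single_wavelength(stack, settings, 850.0)
        expected = math.exp(-mu_a_mm * length)
        se = res.mc_standard_error(expected)
        out.append(
            CheckResult(
                name=f"beer_lambert_mua{mu_a_mm}_L{length}",
                expected=expected,
                measured=res.transmittance,
                tolerance=3.0 * se,
                passed=abs(res.transmittance - expected) <= 3.0 * se,
            )
        )
    return out


def _fresnel_check() -> CheckResult:
    expected = ((1.0 - 1.34) / (1.0 + 1.34)) ** 2
    measured = specular_reflect(1.0, 1.34)
    return CheckResult(
        name="fresnel_normal_incidence_air_epidermis",
        expected=expected,
        measured=measured,
        tolerance=1e-12,
        passed=abs(measured - expected) <= 1e-12,
    )


def _hg_checks(n_draws: int, seed: int) -> list[CheckResult]:
    out = []
    for g in (0.0, 0.62, 0.85):
        rng = np.random.default_rng(seed)
        cosines = np.empty(n_draws)
        for i in range(n_draws):
            _, _, uz = scatter_hg(0.0, 0.0, 1.0, g, rng)
            cosines[i] = uz
        measured = float(cosines.mean())
        sigma = float(cosines.std(ddof=1)) / math.sqrt(n_draws)
        out.append(
            CheckResult(
                name=f"hg_mean_cosine_g{g}",
                expected=g,
                measured=measured,
                tolerance=3.0 * sigma,
                passed=abs(measured - g) <= 3.0 * sigma,
            )
        )
    return out


def _conservation_check(n_photons: int, seed: int) -> CheckResult:
    from .tissue import default_skin_stack

    settings = RunSettings(n_photons=n_photons, seed=seed, nr=200, nz=100)
    res = run_single_wavelength(default_skin_stack(), settings, 850.0)
    measured = res.budget_closure
    return CheckResult(
        name="energy_budget_closure",
        expected=1.0,
        measured=measured,
        tolerance=1e-9,
        passed=abs(measured - 1.0) <= 1e-9,
    )


def _determinism_check(n_photons: int, seed: int) -> CheckResult:
    from .tissue import default_skin_stack

    settings = RunSettings(n_photons=n_photons, seed=seed, nr=100, nz=50)
    a = run_single_wavelength(default_skin_stack(), settings, 850.0)
    b = run_single_wavelength(default_skin_stack(), settings, 850.0)
    identical = (
        np.array_equal(a.grid.absorption, b.grid.absorption)
        and np.array_equal(a.grid.crossing_energy, b.grid.crossing_energy)
        and a.grid.specular == b.grid.specular
        and np.array_equal(a.grid.per_layer_absorbed, b.grid.per_layer_absorbed)
    )
    return CheckResult(
        name="seed_determinism_bit_identical",
        expected=1.0,
        measured=1.0 if identical else 0.0,
        tolerance=0.0,
        passed=identical,
    )


def run_validation_suite(quick: bool = True, seed: int = 12345) -> list[CheckResult]:
    """Run all oracle checks; quick mode uses small ensembles (seconds)."""
    n_photons = 20_000 if quick else 200_000
    n_draws = 50_000 if quick else 1_000_000
    report: list[CheckResult] = []
    report.extend(_beer_lambert_checks(n_photons, seed))
    report.append(_fresnel_check())
    report.extend(_hg_checks(n_draws, seed + 7))
    report.append(_conservation_check(n_photons, seed + 11))
    report.append(_determinism_check(min(n_photons, 5000), seed + 13))
    return report
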