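"""Full-transport oracles: Beer-Lambert, budget closure, determinism, symmetry."""

from __future__ import annotations

import math

import numpy as np
import pytest

from lumiderm.mc import RunSettings, run_single_wavelength
from lumiderm.tissue import Layer, OpticalProperties, TissueStack
from lumiderm.validation import absorbing_slab


def _slab(mu_a_percm, mu_s_percm, g, n, thickness_mm, n_above=1.0, n_below=None):
    layer = Layer(
        "slab",
        thickness_mm,
        {850.0: OpticalProperties(mu_a_percm, mu_s_percm, g, n)},
        wavelength_independent=True,
    )
    return TissueStack(
        layers=(layer,), n_above=n_above, n_below=n if n_below is None else n_below
    )


class TestBeerLambertLimit:
    @pytest.mark.parametrize(
        "mu_a_mm,length_mm,seed", [(0.05, 10.0, 31), (0.1, 10.0, 32), (0.1, 20.0, 33)]
    )
    def test_scattering_free_transmittance(self, mu_a_mm, length_mm, seed):
        """With no scattering and matched indices, T = exp(-mu_a * L)."""
        stack = absorbing_slab(mu_a_percm=mu_a_mm * 10, thickness_mm=length_mm)
        settings = RunSettings(
            n_photons=30_000, seed=seed, beam_profile="pencil", nr=50, nz=50,
            dz_mm=length_mm / 50,
        )
        res = run_single_wavelength(stack, settings, 850.0)
        expected = math.exp(-mu_a_mm * length_mm)
        assert abs(res.transmittance - expected) < 3 * res.mc_standard_error(expected)
        assert res.specular_reflectance == 0.0
        assert res.diffuse_reflectance == 0.0


class TestEnergyBudget:
    def test_budget_closes_exactly_with_roulette_correction(self, small_run):
        assert abs(small_run.budget_closure - 1.0) < 1e-9
        assert abs(small_run.grid.budget_residual) < 1e-6 * small_run.n_photons

    def test_fraction_sum_near_one_without_correction(self, small_run):
        total = (
            small_run.specular_reflectance
            + small_run.diffuse_reflectance
            + small_run.transmittance
            + small_run.total_absorbed_fraction
        )
        # roulette noise only; generously bounded by 3 per-photon sigma
        assert abs(total - 1.0) < 3.0 / math.sqrt(small_run.n_photons)

    def test_all_fractions_in_unit_interval(self, small_run):
        fracs = [
            small_run.specular_reflectance,
            small_run.diffuse_reflectance,
            small_run.transmittance,
            *small_run.absorbed_fraction_by_layer,
        ]
        assert all(0.0 <= f <= 1.0 for f in fracs)

    def test_binned_and_exact_layer_tallies_agree_in_total(self, small_run):
        assert small_run.absorbed_fraction_by_layer_binned.sum() == pytest.approx(
            small_run.absorbed_fraction_by_layer.sum(), rel=1e-12
        )


class TestPureScattering:
    def test_deep_nonabsorbing_slab_reflects_nearly_everything(self):
        """mu_a = 0 with matched boundaries: diffuse reflectance -> 1."""
        # 200 transport mean free paths deep; the residue leaks out the bottom
        stack = _slab(0.0, 90.0, 0.0, 1.0, thickness_mm=200 / 9.0)
        settings = RunSettings(n_photons=5_000, seed=41, beam_profile="pencil", nr=40, nz=40)
        res = run_single_wavelength(stack, settings, 850.0)
        assert res.diffuse_reflectance + res.transmittance == pytest.approx(1.0, abs=1e-9)
        assert res.diffuse_reflectance > 0.97


class TestDeterminismAndSeeds:
    def test_identical_seed_bit_identical(self, stack):
        settings = RunSettings(n_photons=4_000, seed=55, nr=80, nz=60)
        a = run_single_wavelength(stack, settings, 850.0)
        b = run_single_wavelength(stack, settings, 850.0)
        assert np.array_equal(a.grid.absorption, b.grid.absorption)
        assert np.array_equal(a.grid.crossing_energy, b.grid.crossing_energy)
        assert np.array_equal(a.grid.reflectance_diffuse, b.grid.reflectance_diffuse)
        assert a.grid.specular == b.grid.specular
        assert a.grid.roulette_net == b.grid.roulette_net

    def test_different_seeds_agree_within_mc_error(self, stack):
        runs = [
            run_single_wavelength(
                stack, RunSettings(n_photons=20_000, seed=s, nr=80, nz=60), 850.0
            )
            for s in (101, 202)
        ]
        for attr in ("diffuse_reflectance", "total_absorbed_fraction"):
            a, b = (getattr(r, attr) for r in runs)
            se = math.sqrt(runs[0].mc_standard_error(a) ** 2 + runs[1].mc_standard_error(b) ** 2)
            assert abs(a - b) < 3 * se


class TestPlaneParallelInvariances:
    def test_layer_fractions_independent_of_beam_profile(self, stack):
        """Laterally infinite slabs: pencil and flat beams share depth physics."""
        pencil = run_single_wavelength(
            stack, RunSettings(n_photons=20_000, seed=61, beam_profile="pencil", nr=80, nz=60),
            850.0,
        )
        flat = run_single_wavelength(
            stack, RunSettings(n_photons=20_000, seed=62, nr=80, nz=60), 850.0
        )
        for fa, fb in zip(pencil.absorbed_fraction_by_layer, flat.absorbed_fraction_by_layer):
            se = math.sqrt(
                pencil.mc_standard_error(fa) ** 2 + flat.mc_standard_error(fb) ** 2
            )
            assert abs(fa - fb) < 3.5 * se

    def test_epidermis_fraction_flat_across_band(self, reference_spectral_run):
        """Epidermis properties are constant over 800-900 nm, so its absorbed
        fraction is nearly flat across the band.  A small residual dependence
        (~2%) remains because deeper layers absorb more at 900 nm, returning
        less backscattered light for second-pass epidermal absorption."""
        fractions = [
            r.absorbed_fraction_by_layer[0]
            for r in reference_spectral_run.per_wavelength
        ]
        spread = (max(fractions) - min(fractions)) / np.mean(fractions)
        assert spread < 0.03
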