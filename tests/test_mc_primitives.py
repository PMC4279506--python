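"""Single-photon primitives: launch, Fresnel, step, HG scattering, roulette."""

from __future__ import annotations

import math

import numpy as np
import pytest

from lumiderm.mc import (
    PhotonState,
    RunSettings,
    TallyGrid,
    boundary_interact,
    deposit,
    fresnel_reflectance,
    launch,
    roulette,
    sample_step,
    scatter_hg,
    specular_reflect,
)
from lumiderm.tissue import OpticalProperties


class TestLaunch:
    def test_pencil_starts_on_axis(self, rng):
        p = launch(RunSettings(beam_profile="pencil"), rng)
        assert (p.x, p.y, p.z) == (0.0, 0.0, 0.0)
        assert (p.ux, p.uy, p.uz) == (0.0, 0.0, 1.0)
        assert p.weight == 1.0

    def test_flat_disk_moments_and_support(self, rng):
        settings = RunSettings(beam_radius_mm=10.0)
        r2 = np.array([launch(settings, rng).r ** 2 for _ in range(20_000)])
        assert r2.max() <= 100.0
        # E[r^2] = R^2/2 for a uniform disk
        se = r2.std(ddof=1) / math.sqrt(r2.size)
        assert abs(r2.mean() - 50.0) < 3 * se


class TestFresnel:
    def test_air_epidermis_normal_incidence(self):
        assert specular_reflect(1.0, 1.34) == pytest.approx(0.02111, abs=1e-5)

    def test_matched_media_and_symmetry(self):
        assert specular_reflect(1.0, 1.0) == 0.0
        assert specular_reflect(1.34, 1.55) == specular_reflect(1.55, 1.34)

    def test_total_internal_reflection(self):
        # critical cosine for 1.5 -> 1.0 is sqrt(1 - (1/1.5)^2) ~ 0.745
        assert fresnel_reflectance(1.5, 1.0, 0.5) == 1.0

    @pytest.mark.parametrize("n1,n2", [(1.0, 1.34), (1.34, 1.55), (1.55, 1.45), (1.45, 1.37)])
    def test_matches_explicit_s_p_average(self, n1, n2):
        # independent oracle: average of the s- and p-polarised coefficients
        for ci in (0.95, 0.8, 0.6, 0.4, 0.2, 0.05):
            si = math.sqrt(1 - ci * ci)
            st = n1 / n2 * si
            if st >= 1:
                expected = 1.0
            else:
                ct = math.sqrt(1 - st * st)
                rs = ((n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)) ** 2
                rp = ((n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)) ** 2
                expected = 0.5 * (rs + rp)
            assert fresnel_reflectance(n1, n2, ci) == pytest.approx(expected, abs=1e-12)


class TestStepSampling:
    def test_exact_quantile(self):
        # xi = e^-1 gives a step of exactly one mean free path
        from lumiderm._kernel import step_from_xi

        assert step_from_xi(math.exp(-1.0), 2.0) == pytest.approx(0.5)

    def test_mean_free_path(self, rng):
        mu_t = 50.5  # epidermis mu_t in mm^-1: (55 + 450)/10
        draws = np.array([sample_step(mu_t, rng) for _ in range(100_000)])
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - 1.0 / mu_t) < 3 * se
        assert 1.0 / mu_t == pytest.approx(0.0198, abs=1e-4)

    def test_vacuum_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_step(0.0, rng)


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.62, 0.85])
    def test_mean_cosine_equals_g(self, g, rng):
        uz = np.array([scatter_hg(0.0, 0.0, 1.0, g, rng)[2] for _ in range(100_000)])
        se = uz.std(ddof=1) / math.sqrt(uz.size)
        assert abs(uz.mean() - g) < 3 * se

    def test_unit_norm_preserved(self, rng):
        d = np.array([0.3, -0.5, math.sqrt(1 - 0.34)])
        for _ in range(200):
            d = np.array(scatter_hg(*d, 0.8, rng))
            assert abs(np.dot(d, d) - 1.0) < 1e-9

    def test_azimuth_unbiased(self, rng):
        xy = np.array([scatter_hg(0.0, 0.0, 1.0, 0.8, rng)[:2] for _ in range(50_000)])
        se = xy.std(axis=0, ddof=1) / math.sqrt(len(xy))
        assert np.all(np.abs(xy.mean(axis=0)) < 3 * se)


class TestDeposit:
    def _grid(self):
        return TallyGrid(dr_mm=0.05, dz_mm=0.05, nr=10, nz=10, n_layers=4)

    def test_epidermis_share(self):
        grid = self._grid()
        photon = PhotonState(z=0.03, weight=1.0, layer=0)
        props = OpticalProperties(55.0, 450.0, 0.8, 1.34)
        deposit(photon, props, grid)
        assert grid.per_layer_absorbed[0] == pytest.approx(55.0 / 505.0)
        assert photon.weight == pytest.approx(1.0 - 55.0 / 505.0)
        assert grid.absorption.sum() == pytest.approx(55.0 / 505.0)

    def test_no_absorption_when_mu_a_zero(self):
        grid = self._grid()
        photon = PhotonState(weight=0.7, layer=1)
        deposit(photon, OpticalProperties(0.0, 10.0, 0.5, 1.4), grid)
        assert photon.weight == 0.7
        assert grid.absorption.sum() == 0.0

    def test_lifetime_deposition_bounded_by_initial_weight(self):
        grid = self._grid()
        photon = PhotonState(weight=1.0, layer=0)
        props = OpticalProperties(55.0, 450.0, 0.8, 1.34)
        for _ in range(500):
            deposit(photon, props, grid)
        assert grid.absorption.sum() <= 1.0 + 1e-12


class TestBoundaryInteract:
    def test_matched_indices_always_transmit(self, stack, rng):
        photon = PhotonState(z=13.315, uz=0.3, ux=math.sqrt(1 - 0.09), layer=3)
        # bottom of muscle is index-matched; force the photon to the bottom
        photon.z = stack.total_thickness_mm
        transmitted = boundary_interact(photon, stack, rng, 850.0)
        assert transmitted and not photon.alive

    def test_beyond_critical_angle_reflects(self, stack, rng):
        # dermis (1.55) -> fat (1.45) going down at grazing incidence
        photon = PhotonState(z=1.315, uz=0.1, ux=math.sqrt(1 - 0.01), layer=1)
        for _ in range(50):
            photon.uz = 0.1
            assert not boundary_interact(photon, stack, rng, 850.0)
            assert photon.uz == -0.1

    def test_refraction_updates_layer_and_direction(self, stack, rng):
        crossed = 0
        for _ in range(200):
            photon = PhotonState(z=0.065, uz=0.9, ux=math.sqrt(1 - 0.81), layer=0)
            if boundary_interact(photon, stack, rng, 850.0):
                crossed += 1
                assert photon.layer == 1
                norm = photon.ux**2 + photon.uy**2 + photon.uz**2
                assert norm == pytest.approx(1.0, abs=1e-9)
                # entering a denser medium bends toward the normal
                assert photon.uz > 0.9
        assert crossed > 150  # reflection probability is small here


class TestRoulette:
    def test_above_threshold_noop(self, rng):
        photon = PhotonState(weight=0.5)
        roulette(photon, RunSettings(), rng)
        assert photon.weight == 0.5 and photon.alive

    def test_survivor_boost(self):
        settings = RunSettings(roulette_threshold=1e-3, roulette_survival=0.1)

        class AlwaysSurvive:
            def random(self):
                return 0.05

        photon = PhotonState(weight=5e-4)
        roulette(photon, settings, AlwaysSurvive())
        assert photon.weight == pytest.approx(5e-3)

    def test_unbiased_in_expectation(self, rng):
        settings = RunSettings(roulette_threshold=1e-3, roulette_survival=0.1)
        w0, n = 5e-4, 200_000
        total = 0.0
        for _ in range(n):
            photon = PhotonState(weight=w0)
            roulette(photon, settings, rng)
            total += photon.weight
        # mean post-roulette weight equals the pre-roulette weight
        se = w0 * math.sqrt((1 - 0.1) / 0.1 / n)
        assert abs(total / n - w0) < 3 * se
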