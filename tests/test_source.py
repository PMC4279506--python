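"""LED source model: Gaussian spectrum, spot geometry, irradiance, safety."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumiderm.source import (
    SafetySpec,
    SourceGeometry,
    SpectrumModel,
    check_safety,
    discretize_spectrum,
    power_density,
    spectral_proportion,
    spot_area,
    spot_diameter,
)


class TestSpectrum:
    @pytest.mark.parametrize(
        "wl,expected",
        [(800, 0.0098), (825, 0.2010), (850, 0.5494), (875, 0.2010), (900, 0.0098)],
    )
    def test_discrete_proportions_to_4dp(self, wl, expected):
        assert round(spectral_proportion(SpectrumModel(), wl), 4) == expected

    def test_peak_equals_a1(self):
        spec = SpectrumModel()
        assert spectral_proportion(spec, spec.b1) == spec.a1

    def test_far_tail_negligible(self):
        spec = SpectrumModel()
        assert spectral_proportion(spec, spec.b1 + 10 * spec.c1) < 1e-40

    @given(delta=st.floats(min_value=0.0, max_value=500.0))
    @settings(derandomize=True, max_examples=50)
    def test_symmetry_about_center(self, delta):
        spec = SpectrumModel()
        left = spectral_proportion(spec, spec.b1 - delta)
        right = spectral_proportion(spec, spec.b1 + delta)
        assert left == pytest.approx(right, rel=1e-12)

    def test_discretize_raw_and_normalized(self):
        wls, raw, norm = discretize_spectrum(SpectrumModel())
        np.testing.assert_allclose(
            np.round(raw, 4), [0.0098, 0.2010, 0.5494, 0.2010, 0.0098]
        )
        assert norm.sum() == pytest.approx(1.0, abs=1e-12)
        # printed proportions deliberately do not sum to 1
        assert raw.sum() == pytest.approx(0.971, abs=5e-4)

    def test_normalized_weights_invariant_under_a1_rescale(self):
        _, _, norm1 = discretize_spectrum(SpectrumModel(a1=0.5494))
        _, _, norm2 = discretize_spectrum(SpectrumModel(a1=5.494))
        np.testing.assert_allclose(norm1, norm2, rtol=1e-12)

    def test_singleton_spectrum(self):
        _, _, norm = discretize_spectrum(SpectrumModel(discrete_wavelengths=(850.0,)))
        assert norm.tolist() == [1.0]

    def test_degenerate_spectrum_raises(self):
        spec = SpectrumModel(discrete_wavelengths=(850.0 + 1e6,))
        with pytest.raises(ValueError, match="degenerate"):
            discretize_spectrum(spec)


class TestSpotGeometry:
    def test_at_focus_spot_is_zero(self):
        geom = SourceGeometry(l_mm=0.0)
        assert spot_diameter(geom) == 0.0

    def test_direct_evaluation(self):
        geom = SourceGeometry(D_mm=25, l_mm=5, n_lens=1.5, R_mm=12.5)
        assert spot_diameter(geom) == pytest.approx(20.0)
        assert spot_area(geom) == pytest.approx(math.pi * 100.0)

    def test_spot_area_from_bare_diameter(self):
        assert spot_area(20.0) == pytest.approx(314.159, abs=1e-3)

    @given(
        scale=st.floats(min_value=0.1, max_value=10.0),
        l=st.floats(min_value=0.1, max_value=50.0),
    )
    @settings(derandomize=True, max_examples=40)
    def test_linearity_in_l_and_D(self, scale, l):
        base = SourceGeometry(D_mm=25, l_mm=l, n_lens=1.5, R_mm=12.5)
        assert spot_diameter(
            SourceGeometry(D_mm=25 * scale, l_mm=l, n_lens=1.5, R_mm=12.5)
        ) == pytest.approx(scale * spot_diameter(base), rel=1e-12)
        assert spot_diameter(
            SourceGeometry(D_mm=25, l_mm=l * scale, n_lens=1.5, R_mm=12.5)
        ) == pytest.approx(scale * spot_diameter(base), rel=1e-12)


class TestPowerDensity:
    def test_bench_measurement_arithmetic(self):
        # 332 mW on a 17.5 mm aperture -> 1.38 mW/mm^2
        assert round(power_density(332.0, 17.5), 2) == 1.38

    def test_zero_power(self):
        assert power_density(0.0, 17.5) == 0.0

    def test_zero_diameter_raises_with_guidance(self):
        with pytest.raises(ZeroDivisionError, match="focus"):
            power_density(100.0, 0.0)

    @given(
        p=st.floats(min_value=0.0, max_value=1e4),
        d=st.floats(min_value=0.1, max_value=100.0),
    )
    @settings(derandomize=True, max_examples=40)
    def test_inversion_identity(self, p, d):
        assert power_density(p, d) * spot_area(d) == pytest.approx(p, rel=1e-12, abs=1e-12)


class TestSafety:
    def test_bench_irradiance_passes(self):
        result = check_safety(1.38, SafetySpec())
        assert result.passed
        assert result.irradiance_W_m2 == pytest.approx(1380.0)

    def test_over_limit_fails(self):
        assert not check_safety(2.1, SafetySpec()).passed

    def test_exactly_at_limit_passes_with_unit_margin(self):
        result = check_safety(2.0, SafetySpec())
        assert result.passed
        assert result.margin_ratio == pytest.approx(1.0)

    def test_c_a_scales_limit(self):
        assert check_safety(2.1, SafetySpec(C_A=1.5)).passed
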