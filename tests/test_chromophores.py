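"""Closed-form chromophore spectra: worked values, limits and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skindrs import chromophores as chrom

from ._oracles import vessel_packing_quadrature


class TestReducedScattering:
    @pytest.mark.parametrize(
        "lam, alpha, beta, gamma, expected, rtol",
        [
            # at the 600 nm reference the model returns alpha exactly
            (600.0, 1.99, 0.82, 0.31, 1.99, 1e-12),
            # cohort-median parameters at the blue end of the band
            (475.0, 1.99, 0.82, 0.31, 3.2335, 1e-3),
            # beta = 4 collapses both terms onto the Rayleigh power law
            (700.0, 2.5, 4.0, 0.37, 2.5 * (700.0 / 600.0) ** -4, 1e-12),
        ],
    )
    def test_worked_values(self, lam, alpha, beta, gamma, expected, rtol):
        p = chrom.ScatteringParams(alpha, beta, gamma)
        assert chrom.reduced_scattering(lam, p) == pytest.approx(expected, rel=rtol)

    @given(
        alpha=st.floats(0.5, 5.0),
        beta=st.floats(0.0, 4.0),
        gamma=st.floats(0.0, 1.0),
        lam=st.floats(400.0, 1000.0),
        c=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_homogeneous_in_alpha(self, alpha, beta, gamma, lam, c):
        p1 = chrom.ScatteringParams(alpha, beta, gamma)
        p2 = chrom.ScatteringParams(c * alpha, beta, gamma)
        v1 = chrom.reduced_scattering(lam, p1)
        assert chrom.reduced_scattering(lam, p2) == pytest.approx(c * v1, rel=1e-12)
        assert v1 > 0

    def test_decreasing_in_wavelength_for_positive_beta(self):
        p = chrom.ScatteringParams(2.0, 1.1, 0.3)
        wl = np.linspace(450, 900, 50)
        vals = chrom.reduced_scattering(wl, p)
        assert np.all(np.diff(vals) < 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            chrom.ScatteringParams(-1.0, 0.8, 0.3)
        with pytest.raises(ValueError):
            chrom.reduced_scattering(-5.0, chrom.ScatteringParams(2.0, 0.8, 0.3))


class TestMelaninAbsorption:
    @pytest.mark.parametrize("beta_mel", [1.0, 2.5, 4.3, 7.9])
    def test_reference_constant_at_550(self, beta_mel):
        assert chrom.melanin_absorption(550.0, beta_mel) == pytest.approx(48.4)

    @pytest.mark.parametrize(
        "lam, beta_mel, expected",
        [(1100.0, 1.0, 24.2), (275.0, 2.0, 193.6)],
    )
    def test_power_law_values(self, lam, beta_mel, expected):
        assert chrom.melanin_absorption(lam, beta_mel) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            chrom.melanin_absorption(550.0, 0.0)
        with pytest.raises(ValueError):
            chrom.melanin_absorption(0.0, 2.0)


class TestBloodAbsorption:
    def test_saturation_endpoints(self, hb_table):
        lam = 560.0
        assert chrom.blood_absorption(lam, 1.0, hb_table) == pytest.approx(
            hb_table.oxy(lam)
        )
        assert chrom.blood_absorption(lam, 0.0, hb_table) == pytest.approx(
            hb_table.deoxy(lam)
        )

    def test_linear_in_saturation(self, hb_table):
        lam = 633.0
        v0 = chrom.blood_absorption(lam, 0.2, hb_table)
        v1 = chrom.blood_absorption(lam, 0.5, hb_table)
        v2 = chrom.blood_absorption(lam, 0.8, hb_table)
        assert v1 == pytest.approx(0.5 * (v0 + v2), rel=1e-12)

    def test_isosbestic_point_saturation_independent(self, hb_table):
        lam_iso = hb_table.isosbestic_wavelength()
        assert 780.0 < lam_iso < 815.0
        vals = [chrom.blood_absorption(lam_iso, s, hb_table) for s in (0.0, 0.5, 1.0)]
        assert max(vals) - min(vals) <= 0.02 * np.mean(vals)

    def test_out_of_range_wavelength_raises(self, hb_table):
        with pytest.raises(ValueError):
            chrom.blood_absorption(2000.0, 0.5, hb_table)


class TestVesselPacking:
    def test_zero_absorption_limit(self):
        assert chrom.vessel_packing_factor(0.0, 0.01) == pytest.approx(1.0)
        assert chrom.vessel_packing_factor(1e-12, 0.01) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_value(self):
        expected = (1.0 - np.exp(-0.4)) / 0.4
        assert chrom.vessel_packing_factor(20.0, 0.01) == pytest.approx(expected)

    def test_large_argument_asymptote(self):
        mu, r = 500.0, 0.05
        assert chrom.vessel_packing_factor(mu, r) == pytest.approx(
            1.0 / (2.0 * mu * r), rel=1e-6
        )

    @given(x=st.floats(1e-3, 5.0))
    @settings(max_examples=60, deadline=None)
    def test_matches_quadrature_oracle(self, x):
        """c_vp equals the uniform-traversal mean transmittance within 1 %."""
        radius = 0.005
        mu = x / (2.0 * radius)  # mu_a_blood * R = x / 2
        got = chrom.vessel_packing_factor(mu, radius)
        ref = vessel_packing_quadrature(mu, radius)
        assert got == pytest.approx(ref, rel=0.01)
        assert 0.0 < got <= 1.0

    def test_monotone_decreasing(self):
        mus = np.linspace(0.0, 100.0, 50)
        vals = chrom.vessel_packing_factor(mus, 0.005)
        assert np.all(np.diff(vals) < 0)


class TestDermisAbsorption:
    def test_zero_blood(self, hb_table):
        d = chrom.DermisLayerParams(0.0, 0.5)
        assert chrom.dermis_absorption(560.0, d, hb_table) == 0.0

    def test_tiny_vessel_limit(self, hb_table):
        d = chrom.DermisLayerParams(0.02, 0.7, vessel_radius=1e-7)
        expected = 0.02 * chrom.blood_absorption(560.0, 0.7, hb_table)
        assert chrom.dermis_absorption(560.0, d, hb_table) == pytest.approx(
            expected, rel=1e-4
        )

    def test_isosbestic_value(self, hb_table):
        lam_iso = hb_table.isosbestic_wavelength()
        d = chrom.DermisLayerParams(0.011, 0.5, vessel_radius=1e-7)
        expected = 0.011 * hb_table.oxy(lam_iso)
        assert chrom.dermis_absorption(lam_iso, d, hb_table) == pytest.approx(
            expected, rel=0.02
        )

    def test_monotone_in_blood_fraction(self, hb_table):
        vals = [
            chrom.dermis_absorption(
                575.0, chrom.DermisLayerParams(fb, 0.5), hb_table
            )
            for fb in (0.001, 0.005, 0.02, 0.08)
        ]
        assert np.all(np.diff(vals) > 0)


class TestHemoglobinTable:
    def test_coverage_and_spacing(self, hb_table):
        assert hb_table.wavelengths[0] <= 450.0
        assert hb_table.wavelengths[-1] >= 900.0
        assert np.max(np.diff(hb_table.wavelengths)) <= 1.0 + 1e-9
        assert np.all(hb_table.mu_a_oxy > 0)
        assert np.all(hb_table.mu_a_deoxy > 0)

    def test_oxyhemoglobin_shape(self, hb_table):
        # the green Q-band peaks dwarf the red window
        assert hb_table.oxy(575.0) > hb_table.oxy(650.0)
        assert hb_table.oxy(542.0) > hb_table.oxy(560.0)

    def test_conversion_is_wavelength_independent(self):
        """mu_a / extinction must be one global constant."""
        import pandas as pd
        from importlib import resources

        ref = resources.files("skindrs.data") / "hemoglobin_extinction_synthetic.tsv"
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", comment="#")
        table = chrom.compile_hemoglobin_table()
        conv = np.log(10.0) * chrom.WHOLE_BLOOD_HB_MOLARITY / 10.0
        sub = df[(df.wavelength_nm >= 450) & (df.wavelength_nm <= 900)]
        ratios = table.oxy(sub.wavelength_nm.to_numpy()) / sub.eps_hbo2_cm1_M.to_numpy()
        assert np.allclose(ratios, conv, rtol=1e-6)

    def test_whole_blood_concentration_constant(self):
        assert chrom.WHOLE_BLOOD_HB_MOLARITY * chrom.HB_MOLAR_MASS == pytest.approx(
            148.35
        )
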