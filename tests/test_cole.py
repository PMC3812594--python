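"""Forward Cole model: closed forms, frozen oracle values, and algebraic properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ebis.cole import (
    ColeParameters,
    FrequencyGrid,
    ImpedanceSpectrum,
    add_parallel_capacitance,
    admittance_to_impedance,
    cole_conductance,
    cole_impedance,
    impedance_to_admittance,
)
from ebis.errors import DegenerateInputError, ValidationError

# Frozen independent evaluations (40-digit complex arithmetic, computed once
# outside the package with mpmath).
ORACLE_Z_80_20 = 38.067923677574239 - 19.452427653004908j  # (80,20,0.8,50k) @ 100 kHz
ORACLE_G_80_20 = 0.020829874514264997
ORACLE_ZP_LOADED = 74.763279520319201 - 25.312552789605259j  # 75-25j @ 10kHz + 1 nF


def grid_of(*freqs):
    return FrequencyGrid(np.array(freqs, dtype=float))


valid_params = st.builds(
    lambda r_inf, delta, alpha, fc: ColeParameters(
        r0=r_inf + delta, r_inf=r_inf, alpha=alpha, fc=fc
    ),
    r_inf=st.floats(5.0, 200.0),
    delta=st.floats(1.0, 300.0),
    alpha=st.floats(0.2, 1.0),
    fc=st.floats(1e3, 5e5),
)


class TestColeParameters:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(r0=50.0, r_inf=50.0, alpha=0.8, fc=1e4),  # no dispersion
            dict(r0=40.0, r_inf=50.0, alpha=0.8, fc=1e4),  # inverted ordering
            dict(r0=100.0, r_inf=-5.0, alpha=0.8, fc=1e4),
            dict(r0=100.0, r_inf=50.0, alpha=0.0, fc=1e4),
            dict(r0=100.0, r_inf=50.0, alpha=1.2, fc=1e4),
            dict(r0=100.0, r_inf=50.0, alpha=0.8, fc=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ColeParameters(**kwargs)

    def test_conductance_limits_are_reciprocal_resistances(self):
        p = ColeParameters(100.0, 50.0, 0.8, 1e4)
        assert p.y0 == pytest.approx(0.01)
        assert p.y_inf == pytest.approx(0.02)


class TestFrequencyGrid:
    def test_default_grid_matches_measurement_protocol(self):
        g = FrequencyGrid.default()
        assert len(g) == 256
        assert g.f_min == pytest.approx(3.096e3)
        assert g.f_max == pytest.approx(1.000e6)
        assert np.all(np.diff(np.log(g.frequencies_hz)) > 0)
        # log-spaced: constant ratio between neighbours
        ratios = g.frequencies_hz[1:] / g.frequencies_hz[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_rejects_unsorted_or_nonpositive(self):
        with pytest.raises(ValidationError):
            FrequencyGrid(np.array([2.0, 1.0]))
        with pytest.raises(ValidationError):
            FrequencyGrid(np.array([0.0, 1.0]))


class TestColeImpedance:
    def test_zero_frequency_limit_approaches_r0(self):
        p = ColeParameters(100.0, 50.0, 1.0, 1e4)
        z = cole_impedance(p, grid_of(1e-6))[0]
        assert z == pytest.approx(100.0 + 0.0j, abs=1e-6)

    def test_closed_form_at_characteristic_frequency(self):
        # alpha=1 at f=fc: Z = R_inf + (R0-R_inf)/(1+j) = 75 - 25j
        p = ColeParameters(100.0, 50.0, 1.0, 1e4)
        z = cole_impedance(p, grid_of(1e4))[0]
        assert z == pytest.approx(75.0 - 25.0j, rel=1e-12)

    def test_matches_frozen_oracle(self):
        p = ColeParameters(80.0, 20.0, 0.8, 50e3)
        z = cole_impedance(p, grid_of(100e3))[0]
        assert z == pytest.approx(ORACLE_Z_80_20, rel=1e-12)

    @given(valid_params)
    def test_real_part_bounded_and_reactance_nonpositive(self, p):
        z = cole_impedance(p, FrequencyGrid.default())
        assert np.all(z.real > p.r_inf) and np.all(z.real < p.r0)
        assert np.all(z.imag <= 0.0)


class TestColeConductance:
    def test_low_frequency_limit_is_y0(self):
        p = ColeParameters(100.0, 50.0, 0.63, 1e4)
        g = cole_conductance(p, grid_of(1e-9))[0]
        assert g == pytest.approx(0.01, abs=1e-9)

    def test_value_at_fc_for_alpha_one(self):
        p = ColeParameters(100.0, 50.0, 1.0, 1e4)
        g = cole_conductance(p, grid_of(1e4))[0]
        assert g == pytest.approx(0.012, rel=1e-12)  # Re(1/(75-25j))

    def test_matches_frozen_oracle(self):
        p = ColeParameters(80.0, 20.0, 0.8, 50e3)
        g = cole_conductance(p, grid_of(100e3))[0]
        assert g == pytest.approx(ORACLE_G_80_20, rel=1e-12)

    @given(valid_params)
    def test_consistent_with_admittance_of_impedance_form(self, p):
        """The cos-expansion form equals Re(1/Z) of the principal-branch form."""
        grid = FrequencyGrid.default()
        g = cole_conductance(p, grid)
        g_ref = (1.0 / cole_impedance(p, grid)).real
        assert np.allclose(g, g_ref, rtol=1e-12, atol=0)

    @given(valid_params)
    def test_bounded_and_monotone_on_default_grid(self, p):
        g = cole_conductance(p, FrequencyGrid.default())
        assert np.all(g >= p.y0 - 1e-15) and np.all(g <= p.y_inf + 1e-15)
        assert np.all(np.diff(g) >= -1e-18)


class TestAdmittanceConversion:
    def test_known_point(self):
        s = ImpedanceSpectrum(grid_of(1e4), np.array([75.0]), np.array([-25.0]))
        a = impedance_to_admittance(s)
        assert a.conductance[0] == pytest.approx(0.012, rel=1e-12)
        assert a.susceptance[0] == pytest.approx(0.004, rel=1e-12)

    def test_purely_real_impedance(self):
        s = ImpedanceSpectrum(grid_of(1e4), np.array([50.0]), np.array([0.0]))
        a = impedance_to_admittance(s)
        assert a.conductance[0] == pytest.approx(0.02)
        assert a.susceptance[0] == 0.0

    def test_zero_magnitude_point_rejected(self):
        s = ImpedanceSpectrum(grid_of(1e4), np.array([0.0]), np.array([0.0]))
        with pytest.raises(DegenerateInputError):
            impedance_to_admittance(s)

    @given(valid_params)
    def test_round_trip_identity(self, p):
        grid = FrequencyGrid.default()
        z = cole_impedance(p, grid)
        s = ImpedanceSpectrum(grid, z.real, z.imag)
        back = admittance_to_impedance(impedance_to_admittance(s))
        assert np.allclose(back.resistance, s.resistance, rtol=1e-12)
        assert np.allclose(back.reactance, s.reactance, rtol=1e-12)


class TestParallelCapacitance:
    @pytest.fixture()
    def spectrum(self):
        p = ColeParameters(100.0, 50.0, 0.8, 3e4)
        grid = FrequencyGrid.default()
        z = cole_impedance(p, grid)
        return ImpedanceSpectrum(grid, z.real, z.imag)

    def test_zero_capacitance_is_identity(self, spectrum):
        assert add_parallel_capacitance(spectrum, 0.0) is spectrum

    def test_negative_capacitance_rejected(self, spectrum):
        with pytest.raises(ValidationError):
            add_parallel_capacitance(spectrum, -1e-12)

    @pytest.mark.parametrize("c_p", [1e-12, 1e-9, 1e-8])
    def test_conductance_unchanged_susceptance_shifted(self, spectrum, c_p):
        loaded = add_parallel_capacitance(spectrum, c_p)
        y_in = impedance_to_admittance(spectrum)
        y_out = impedance_to_admittance(loaded)
        assert np.allclose(y_out.conductance, y_in.conductance, rtol=1e-9)
        shift = 2 * np.pi * spectrum.grid.frequencies_hz * c_p
        assert np.allclose(y_out.susceptance - y_in.susceptance, shift, rtol=1e-9)

    def test_matches_frozen_oracle(self):
        s = ImpedanceSpectrum(grid_of(1e4), np.array([75.0]), np.array([-25.0]))
        loaded = add_parallel_capacitance(s, 1e-9)
        zp = loaded.resistance[0] + 1j * loaded.reactance[0]
        assert zp == pytest.approx(ORACLE_ZP_LOADED, rel=1e-12)
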