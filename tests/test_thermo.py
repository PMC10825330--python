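"""Arrhenius, Van't Hoff / Gibbs chain and transport estimators."""

import math

import numpy as np
import pytest

from uaextract.fixtures import KINETIC_PARAMS, KINETIC_TEMPERATURES_C, THERMO_TABLE
from uaextract.kinetics import KineticDataset, PSOFit, predict_ct
from uaextract.thermo import (
    R_GAS,
    arrhenius_fit,
    biot,
    celsius_to_kelvin,
    equilibrium_constant,
    estimate_transport,
    gibbs,
    gibbs_from_ke,
    vant_hoff_fit,
)

T_K = celsius_to_kelvin(np.array(KINETIC_TEMPERATURES_C))


def two_point_closed_form(t1, t2, v1, v2):
    """Exact two-point solution of ln v = a + b/T."""
    b = (math.log(v1) - math.log(v2)) / (1 / t1 - 1 / t2)
    a = math.log(v1) - b / t1
    return a, b


class TestArrhenius:
    def test_antioxidant_activation_energy(self):
        ks = [KINETIC_PARAMS["YA"][t][0] for t in KINETIC_TEMPERATURES_C]
        fit = arrhenius_fit(T_K, ks)
        assert fit.ea / 1000 == pytest.approx(25.407, abs=0.05)

    def test_identical_rate_constants_give_zero_ea(self):
        fit = arrhenius_fit(T_K, [0.005] * 4)
        assert fit.ea == pytest.approx(0.0, abs=1e-9)
        assert fit.k0 == pytest.approx(0.005)

    def test_two_point_matches_closed_form(self):
        t = [303.0, 333.0]
        k = [0.002, 0.006]
        fit = arrhenius_fit(t, k)
        a, b = two_point_closed_form(*t, *k)
        assert fit.ea == pytest.approx(-b * R_GAS, rel=1e-12)
        assert fit.k0 == pytest.approx(math.exp(a), rel=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="positive"):
            arrhenius_fit(T_K, [0.1, -0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="distinct"):
            arrhenius_fit([300.0, 300.0], [0.1, 0.2])


class TestEquilibrium:
    def test_half_saturation_gives_unity(self):
        assert equilibrium_constant(10.0, 20.0) == pytest.approx(1.0)

    def test_phenolics_saturation_value(self):
        # Cs at 30 degC over the maximum observed phenolic content
        assert equilibrium_constant(16.536, 24.619) == pytest.approx(2.0458, abs=1e-4)

    def test_monotone_in_cs_and_domain_error(self):
        ref = equilibrium_constant(19.0, 20.0)
        assert ref > equilibrium_constant(18.0, 20.0)
        with pytest.raises(ValueError):
            equilibrium_constant(21.0, 20.0)


class TestVantHoff:
    def test_recovers_published_enthalpy_entropy_from_gibbs(self):
        """Ke rebuilt from the printed Gibbs energies recovers dH, dS."""
        d = THERMO_TABLE["YP"]
        dg = np.array([d["dg"][t] for t in KINETIC_TEMPERATURES_C]) * 1000.0
        ke = np.exp(-dg / (R_GAS * T_K))
        fit = vant_hoff_fit(T_K, ke)
        assert fit.dh / 1000 == pytest.approx(51.975, rel=1e-3)
        assert fit.ds == pytest.approx(177.321, rel=1e-3)

    def test_flat_line_gives_zero_enthalpy_entropy_r(self):
        fit = vant_hoff_fit(T_K, [math.e] * 4)
        assert fit.dh == pytest.approx(0.0, abs=1e-9)
        assert fit.ds == pytest.approx(R_GAS, rel=1e-12)

    def test_two_points_interpolated_exactly(self):
        fit = vant_hoff_fit([303.0, 333.0], [2.0, 12.0])
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)
        assert fit.r2 == pytest.approx(1.0)


class TestGibbs:
    def test_published_phenolics_endpoints(self):
        assert gibbs(51975.0, 177.321, 303.0) == pytest.approx(-1753.0, abs=1.0)
        assert gibbs(51975.0, 177.321, 333.0) == pytest.approx(-7073.0, abs=1.0)

    def test_zero_parameters(self):
        assert gibbs(0.0, 0.0, 310.0) == 0.0

    def test_from_ke_identities(self):
        assert gibbs_from_ke(1.0, 300.0) == 0.0
        assert gibbs_from_ke(2.006, 303.0) == pytest.approx(-1753.0, abs=2.0)
        assert gibbs_from_ke(math.e, 1.0 / R_GAS) == pytest.approx(-1.0, rel=1e-12)

    def test_round_trip_through_ke(self):
        dh, ds, t = 51975.0, 177.321, 313.0
        g = gibbs(dh, ds, t)
        ke = math.exp(-g / (R_GAS * t))
        assert gibbs_from_ke(ke, t) == pytest.approx(g, rel=1e-9)


class TestBiot:
    def test_published_carotenoid_row(self):
        # De, Kt at 30 degC with the table-implied length reproduce Bi = 9.956
        assert biot(2.087e-6, 1.5203e-4, 3.187e-11) == pytest.approx(9.956, abs=0.01)

    def test_zero_length_and_linearity(self):
        assert biot(1e-6, 0.0, 1e-11) == 0.0
        assert biot(2e-6, 1e-4, 1e-11) == pytest.approx(2 * biot(1e-6, 1e-4, 1e-11))

    def test_zero_de_rejected(self):
        with pytest.raises(ValueError):
            biot(1e-6, 1e-4, 0.0)


class TestTransport:
    L = 1.5203e-4

    @staticmethod
    def slab_series(cs, de_m2_s, length, t_min, n_terms=10):
        """Multi-term Fourier slab solution used as generation truth."""
        de_min = de_m2_s * 60.0
        frac = np.zeros_like(t_min, dtype=float)
        for n in range(n_terms):
            m = 2 * n + 1
            frac += (8 / math.pi**2) / m**2 * np.exp(
                -(m**2) * math.pi**2 * de_min * t_min / (4 * length**2)
            )
        return cs * (1.0 - frac)

    def test_recovers_known_de_within_5pct(self):
        de_true = 3.0e-11
        cs = 50.0
        t = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        ct = self.slab_series(cs, de_true, self.L, t)
        data = KineticDataset("YB", 30.0, t, ct)
        fit = PSOFit(k=0.005, cs=cs)  # Cs known; k only feeds the Kt estimate
        rec = estimate_transport(data, fit, self.L, "slab")
        assert rec.de == pytest.approx(de_true, rel=0.05)

    def test_biot_identity_exact_on_record(self):
        t = np.array([2.5, 5.0, 10.0, 15.0, 20.0, 25.0])
        data = KineticDataset("YP", 30.0, t, predict_ct(0.00556, 16.536, t))
        fit = PSOFit(k=0.00556, cs=16.536)
        rec = estimate_transport(data, fit, self.L)
        assert rec.bi == pytest.approx(rec.kt * rec.length / rec.de, rel=1e-12)

    def test_de_increases_along_arrhenius_series(self):
        t = np.array([2.5, 5.0, 10.0, 15.0, 20.0, 25.0])
        des = []
        for i, k in enumerate([0.002, 0.003, 0.0045, 0.006]):
            cs = 50.0 + 2 * i
            data = KineticDataset("YA", 30.0 + 10 * i, t, predict_ct(k, cs, t))
            des.append(estimate_transport(data, PSOFit(k=k, cs=cs), self.L).de)
        assert np.all(np.diff(des) > 0)

    def test_unknown_geometry_rejected(self):
        t = np.array([2.5, 5.0, 10.0])
        data = KineticDataset("YP", 30.0, t, predict_ct(0.005, 20.0, t))
        with pytest.raises(ValueError, match="geometry"):
            estimate_transport(data, PSOFit(k=0.005, cs=20.0), self.L, "torus")
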