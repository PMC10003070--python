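"""Unit tests of the nine rate laws against hand-evaluated limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyrdyn import ExternalPools, default_parameters
from pyrdyn.model import (METABOLITES, outflows, rate_v1, rate_v2, rate_v3,
                          rate_v4, rate_v5, rate_v6, rate_v7, rate_v8,
                          rate_v9, rates)

EXT0 = ExternalPools(atp=0.0, imp=0.0)
P = default_parameters()


def state(**kw):
    x = np.zeros(9)
    for name, value in kw.items():
        x[METABOLITES.index(name)] = value
    return x


class TestV1:
    def test_uninhibited_limit_is_k1(self):
        assert rate_v1(state(), P, EXT0) == pytest.approx(P.k1)

    def test_half_at_ump_equal_K(self):
        x = state(ump=P.K_UMP1)
        assert rate_v1(x, P, EXT0) == pytest.approx(P.k1 / 2)

    def test_hill_2_at_twice_K_gives_fifth(self):
        p = P.replace(h_UMP1=2.0)
        x = state(ump=2 * p.K_UMP1)
        # denominator 1 + 2^2 = 5, evaluated by hand
        assert rate_v1(x, p, EXT0) == pytest.approx(p.k1 / 5)

    def test_imp_activates_and_inhibits(self):
        # numerator activation (1 + d*IMP/Ka) over denominator (1 + IMP/K)
        ext = ExternalPools(atp=0.0, imp=P.Ka_IMP1)
        expected = P.k1 * (1 + P.d_IMP) / (1 + P.Ka_IMP1 / P.K_IMP1)
        assert rate_v1(state(), P, ext) == pytest.approx(expected)

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_each_inhibitor(self, u, d, t):
        base = rate_v1(state(ump=u, udp=d, utp=t), P, EXT0)
        for chan in ("ump", "udp", "utp"):
            kw = {"ump": u, "udp": d, "utp": t}
            kw[chan] = kw[chan] + 0.5
            assert rate_v1(state(**kw), P, EXT0) <= base + 1e-15


class TestV2:
    def test_zero_substrate(self):
        assert rate_v2(state(), P, EXT0) == 0.0

    def test_saturation_limit_is_k2(self):
        assert rate_v2(state(cap=1e9), P, EXT0) == pytest.approx(P.k2, rel=1e-6)

    def test_half_substrate_half_ctp_inhibition(self):
        # substrate factor 1/2, regulatory factor (1+0)/(1+1) = 1/2 -> k2/4
        p = P.replace(h_CAP=1.0, d_CTP2=0.0)
        x = state(cap=p.Km_CAP2, ctp=p.K_CTP2)
        assert rate_v2(x, p, EXT0) == pytest.approx(p.k2 / 4)

    def test_regulatory_factor_unity_without_ligands(self):
        x = state(cap=P.Km_CAP2)
        assert rate_v2(x, P, EXT0) == pytest.approx(P.k2 / 2)


@pytest.mark.parametrize("rate,km,k,sub", [
    (rate_v3, "Km_CAASP3", "k3", "casp"),
    (rate_v6, "Km_OMP6", "k6", "omp"),
    (rate_v8, "Km_UDP8", "k8", "udp"),
])
class TestMichaelisMenten:
    def test_zero_substrate(self, rate, km, k, sub):
        assert rate(state(), P) == 0.0

    def test_half_saturation(self, rate, km, k, sub):
        x = state(**{sub: P[km]})
        assert rate(x, P) == pytest.approx(P[k] / 2)

    def test_three_km_gives_three_quarters(self, rate, km, k, sub):
        x = state(**{sub: 3 * P[km]})
        assert rate(x, P) == pytest.approx(0.75 * P[k])


class TestV4:
    def test_zero_at_origin(self):
        assert rate_v4(state(), P) == 0.0

    def test_pure_reverse_flux_is_negative(self):
        assert rate_v4(state(oro=0.5), P) < 0.0

    def test_null_at_equilibrium_ratio(self):
        oro = 0.7
        dho = (P.k4r / P.k4f) * (oro / P.Km_ORO4) * P.Km_DHO4
        assert rate_v4(state(dho=dho, oro=oro), P) == pytest.approx(0.0, abs=1e-15)

    @given(st.floats(0.0, 5.0, allow_subnormal=False),
           st.floats(0.0, 5.0, allow_subnormal=False))
    @settings(max_examples=50, deadline=None)
    def test_sign_matches_thermodynamic_drive(self, dho, oro):
        drive = P.k4f * dho / P.Km_DHO4 - P.k4r * oro / P.Km_ORO4
        assert np.sign(rate_v4(state(dho=dho, oro=oro), P)) == np.sign(drive)


class TestV5:
    def test_zero_substrate(self):
        assert rate_v5(state(), P) == 0.0

    def test_half_saturation_at_k5prpp(self):
        x = state(oro=P.k5prpp * P.Km_ORO5)
        assert rate_v5(x, P) == pytest.approx(P.k5 / 2)

    def test_printed_constants_value(self):
        # k5=3.9, k5prpp=7.5: at oro/Km = 22.5 the rate is 3.9*22.5/30
        x = state(oro=22.5 * P.Km_ORO5)
        assert rate_v5(x, P) == pytest.approx(2.925)


class TestV7:
    def test_plain_mm_without_utp(self):
        x = state(ump=P.Km_UMP7)
        assert rate_v7(x, P) == pytest.approx(P.k7 / 2)

    def test_noncompetitive_halves_vmax(self):
        p = P.replace(r=1.0, h_UTP7=1.0)
        x = state(ump=1e9, utp=p.K_UTP71)
        assert rate_v7(x, p) == pytest.approx(p.k7 / 2, rel=1e-6)

    def test_competitive_doubles_apparent_km(self):
        p = P.replace(r=0.0, h_UTP7=1.0)
        x = state(ump=2 * p.Km_UMP7, utp=p.K_UTP72)
        # Km_app = 2 Km, so ump = 2 Km sits at half saturation
        assert rate_v7(x, p) == pytest.approx(p.k7 / 2)

    def test_r_interpolates_between_coded_mechanisms(self, rng):
        """r=0 and r=1 reduce to independently coded textbook forms."""
        def competitive(ump, utp, p):
            return p.k7 * ump / (
                p.Km_UMP7 * (1 + (utp / p.K_UTP72) ** p.h_UTP7) + ump)

        def noncompetitive(ump, utp, p):
            return (p.k7 * ump / (p.Km_UMP7 + ump)
                    / (1 + (utp / p.K_UTP71) ** p.h_UTP7))

        for _ in range(100):
            ump, utp = rng.uniform(0, 5, 2)
            x = state(ump=ump, utp=utp)
            assert rate_v7(x, P.replace(r=0.0), ) == pytest.approx(
                competitive(ump, utp, P), rel=1e-12)
            assert rate_v7(x, P.replace(r=1.0)) == pytest.approx(
                noncompetitive(ump, utp, P), rel=1e-12)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_utp_inhibition_monotone_for_any_mechanism_mix(self, r, utp):
        p = P.replace(r=r)
        x0 = state(ump=0.2, utp=utp)
        x1 = state(ump=0.2, utp=utp + 0.5)
        assert rate_v7(x1, p) <= rate_v7(x0, p) + 1e-15


class TestV9:
    def test_zero_substrate(self):
        assert rate_v9(state(), P) == 0.0

    def test_half_at_km_without_ctp(self):
        x = state(utp=P.Km_UTP9)
        assert rate_v9(x, P) == pytest.approx(P.k9 / 2)

    def test_product_inhibition_third_at_km(self):
        x = state(utp=P.Km_UTP9, ctp=P.K_CTP9)
        # denominator Km^h * 2 + Km^h = 3 Km^h
        assert rate_v9(x, P) == pytest.approx(P.k9 / 3)

    @given(st.floats(0.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_ctp_inhibition_monotone(self, ctp):
        x0 = state(utp=1.0, ctp=ctp)
        x1 = state(utp=1.0, ctp=ctp + 0.5)
        assert rate_v9(x1, P) <= rate_v9(x0, P) + 1e-15


class TestOutflows:
    def test_zero_state(self):
        assert outflows(np.zeros(9), P) == (0.0, 0.0, 0.0, 0.0)

    def test_linearity(self):
        p = P.replace(k10=0.001)
        v10, v11, v12, v15 = outflows(state(utp=2.0), p)
        assert v10 == pytest.approx(0.002)
        x = state(udp=0.3, utp=1.0, ctp=0.7)
        one = outflows(x, P)
        two = outflows(2 * x, P)
        assert two == pytest.approx(tuple(2 * v for v in one))


def test_rates_rejects_non_finite():
    x = np.zeros(9)
    x[0] = np.nan
    with pytest.raises(ValueError):
        rates(x, P, EXT0)
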