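"""Integration and steady-state location."""

import numpy as np
import pytest

from pyrdyn import (ExternalPools, Trajectory, default_parameters,
                    find_steady_state, integrate, rhs)
from pyrdyn.model import METABOLITES
from pyrdyn.simulate import jacobian, is_stable


def outflow_only_params():
    """All enzymatic steps off; only the linear outflows act."""
    return default_parameters(
        k1=1e-300, k2=1e-300, k3=1e-300, k4f=1e-300, k4r=1e-300,
        k5=1e-300, k6=1e-300, k7=1e-300, k8=1e-300, k9=1e-300)


class TestIntegrate:
    def test_outflow_only_exponential_decay(self, ext):
        p = outflow_only_params()
        x0 = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        traj = integrate(p, ext, x0=x0, t_end=3000.0, report_step=30.0)
        t = traj.times
        # x1..x6 frozen, x7/x8/x9 decay at k22, k10, k11+k23
        for i in range(6):
            np.testing.assert_allclose(traj.states[:, i], x0[i], rtol=1e-7)
        np.testing.assert_allclose(traj.channel("udp"),
                                   x0[6] * np.exp(-p.k22 * t), rtol=1e-6)
        np.testing.assert_allclose(traj.channel("utp"),
                                   x0[7] * np.exp(-p.k10 * t), rtol=1e-6)
        np.testing.assert_allclose(traj.channel("ctp"),
                                   x0[8] * np.exp(-(p.k11 + p.k23) * t),
                                   rtol=1e-6)

    def test_initial_linear_growth_of_cap(self, p_default):
        ext0 = ExternalPools(atp=0.0, imp=0.0)
        # horizon well below the x1 turnover time (~1.6 s), so consumption
        # by V2 is still negligible and growth is first-order
        traj = integrate(p_default, ext0, t_end=0.1, report_step=0.05)
        assert traj.channel("cap")[-1] == pytest.approx(p_default.k1 * 0.1,
                                                        rel=5e-2)

    def test_reporting_grid(self, p_default, ext):
        traj = integrate(p_default, ext, t_end=900.0, report_step=30.0)
        assert traj.report_step == 30.0
        assert traj.times[0] == 0.0 and traj.times[-1] == 900.0
        assert traj.states.shape == (31, 9)

    def test_tolerance_convergence(self, p_default, ext):
        """Halving solver tolerances moves the terminal state by < 1e-6 rel."""
        kw = dict(t_end=5e4, report_step=1e3)
        a = integrate(p_default, ext, rtol=1e-8, atol=1e-12, **kw)
        b = integrate(p_default, ext, rtol=5e-9, atol=5e-13, **kw)
        rel = np.abs(a.states[-1] - b.states[-1]) / (np.abs(b.states[-1]) + 1e-15)
        assert np.max(rel) < 1e-6

    @pytest.mark.parametrize("bad", [
        {"t_end": -1.0},
        {"x0": np.full(9, -1.0)},
        {"x0": np.full(8, 0.0)},
    ])
    def test_input_validation(self, p_default, ext, bad):
        with pytest.raises(ValueError):
            integrate(p_default, ext, **bad)


class TestSteadyState:
    def test_outflow_only_origin_fixed_point(self, ext):
        p = outflow_only_params().replace(k1=1e-300)
        # from the default empty start; the origin is non-hyperbolic
        # (x1..x6 inert), so the linear-stability requirement is waived
        xs = find_steady_state(p, ext, t_max=2e5, require_stable=False)
        assert xs is not None
        np.testing.assert_allclose(xs, 0.0, atol=1e-9)

    def test_residual_below_tolerance(self, p_default, ext, steady_state):
        d = rhs(0.0, steady_state, p_default, ext)
        assert np.max(np.abs(d)) < 1e-10

    def test_reproducible_from_two_starts(self, p_default, ext, steady_state):
        alt = find_steady_state(p_default, ext, x0=np.full(9, 0.2))
        assert alt is not None
        np.testing.assert_allclose(alt, steady_state, rtol=1e-8, atol=1e-12)

    def test_near_linear_regime_matches_closed_form(self, ext):
        """With huge Km everywhere, stage levels follow the linear chain.

        In the linear regime each stage obeys c_j * x_j = F with
        c_j = k_j / Km_j and F pinned by the (tiny) feedback-free V1, so the
        fixed point has the closed form x_j = F / c_j, solved here with
        plain algebra as an independent oracle.
        """
        big = 100.0
        p = default_parameters(
            k1=1e-4,
            Km_CAP2=big, Km_CAASP3=big, Km_DHO4=big, Km_ORO4=big,
            Ki_ORO4=big, Km_ORO5=big, Km_OMP6=big, Km_UMP7=big,
            Km_UDP8=big, K_UMP1=big, K_UDP1=big, K_UTP1=big,
            K_UTP71=big, K_UTP72=big, Km_UTP9=big, K_CTP9=big,
            K_CTP2=big, K_UTP2=big, h_CAP=1.0)
        ext0 = ExternalPools(atp=0.0, imp=0.0)
        xs = find_steady_state(p, ext0, t_max=4e5)
        assert xs is not None
        F = p.k1                                   # uninhibited inflow
        # reversible step 4: k4f/ (k4 KmDHO4) x3 - k4r/(k4 KmORO4) x4 = F
        x4 = F / (p.k5 / (p.k5prpp * p.Km_ORO5))
        x3 = (F + p.k4r / (p.k4 * p.Km_ORO4) * x4) * p.k4 * p.Km_DHO4 / p.k4f
        expected = {
            "cap": F / (p.k2 / p.Km_CAP2),
            "casp": F / (p.k3 / p.Km_CAASP3),
            "dho": x3,
            "oro": x4,
            "omp": F / (p.k6 / p.Km_OMP6),
            "ump": F / (p.k7 / p.Km_UMP7),
            "udp": F / (p.k8 / p.Km_UDP8 + p.k22),
        }
        for name, val in expected.items():
            assert xs[METABOLITES.index(name)] == pytest.approx(val, rel=5e-3), name
        # utp balance: inflow V8, outflow k10*utp + V9 (V9 negligible at huge Km)
        F8 = F - p.k22 * expected["udp"]
        assert xs[7] == pytest.approx(F8 / p.k10, rel=5e-3)

    def test_limit_cycle_returns_none(self, ext):
        from pyrdyn import synth
        assert find_steady_state(synth.make_oscillatory_base(), ext) is None

    def test_jacobian_stability_at_steady_state(self, p_default, ext,
                                                steady_state):
        J = jacobian(p_default, ext, steady_state)
        assert J.shape == (9, 9)
        assert is_stable(p_default, ext, steady_state)


class TestTrajectoryIO:
    def test_wide_and_tidy_round_trip(self, tmp_path, p_default, ext):
        traj = integrate(p_default, ext, t_end=600.0, report_step=30.0)
        for tidy in (False, True):
            path = tmp_path / f"t_{tidy}.csv"
            traj.write_csv(path, tidy=tidy)
            back = Trajectory.read_csv(path)
            np.testing.assert_allclose(back.times, traj.times)
            back_states = np.column_stack(
                [back.channel(m) for m in traj.names])
            np.testing.assert_allclose(back_states, traj.states, rtol=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            Trajectory(times=[0.0, 1.0], states=np.zeros((3, 9)))
        with pytest.raises(ValueError):
            Trajectory(times=[1.0, 0.0], states=np.zeros((2, 9)))
        with pytest.raises(ValueError):
            Trajectory(times=[0.0, 1.0], states=np.full((2, 9), np.nan))
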