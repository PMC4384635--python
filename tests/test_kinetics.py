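"""Unit and property tests for the trans-autophosphorylation kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from btkact.kinetics import (
    ProgressCurve,
    RateParameters,
    TimeToHalfNotReached,
    dimer_kd,
    equilibrium_dimer_fraction,
    make_rate_parameters,
    phospho_fraction,
    simulate_progress,
    time_to_half,
)

from helpers_oracles import euler_trajectory

T_GRID = np.linspace(0.0, 1e4, 201)


class TestRateParameters:
    @pytest.mark.parametrize(
        "scenario, k1", [("no_IP6", 1e4), ("with_IP6", 1e5)]
    )
    def test_scenario_defaults(self, scenario, k1):
        p = make_rate_parameters(scenario)
        assert p.k1 == p.k3 == k1
        assert p.k_minus1 == p.k_minus3 == 20.0
        assert p.k2 == 0.1 and p.k4 == 1.0
        assert p.label == scenario

    def test_overrides_apply_only_named_rates(self):
        p = make_rate_parameters("no_IP6", k2=0.0, k4=0.0)
        assert p.k2 == 0.0 and p.k4 == 0.0
        assert p.k1 == 1e4 and p.k_minus1 == 20.0

    @pytest.mark.parametrize(
        "call",
        [
            lambda: make_rate_parameters("IP7"),
            lambda: make_rate_parameters("no_IP6", k2=-1.0),
            lambda: make_rate_parameters("no_IP6", k9=1.0),
            lambda: RateParameters(1e4, -20.0, 0.1, 1e4, 20.0, 1.0),
        ],
    )
    def test_invalid_inputs_rejected(self, call):
        with pytest.raises(ValueError):
            call()


class TestDimerEquilibrium:
    def test_dimer_kd_reproduces_scenario_constants(self):
        assert dimer_kd(make_rate_parameters("no_IP6")) == pytest.approx(2e-3)
        assert dimer_kd(make_rate_parameters("with_IP6")) == pytest.approx(2e-4)

    def test_kd_inversely_proportional_to_on_rate(self):
        base = make_rate_parameters("no_IP6")
        faster = make_rate_parameters("no_IP6", k1=base.k1 * 10)
        assert dimer_kd(faster) == pytest.approx(dimer_kd(base) / 10)

    def test_dimer_kd_requires_positive_on_rate(self):
        with pytest.raises(ValueError):
            dimer_kd(make_rate_parameters("no_IP6", k1=0.0))

    def test_weak_binding_limit_vanishes(self):
        assert equilibrium_dimer_fraction(1e-6, 1e3) < 1e-8

    def test_closed_form_against_root_finding(self):
        # independent oracle: solve 2 M^2/Kd + M - total0 = 0 numerically
        total0, kd = 1e-6, 2e-3
        m = brentq(
            lambda m_: 2 * m_**2 / kd + m_ - total0, 0, total0, xtol=1e-18, rtol=1e-15
        )
        expected = 1 - m / total0
        assert expected == pytest.approx(1e-3, rel=0.01)  # trace dimer at 1 uM / 2 mM
        assert equilibrium_dimer_fraction(total0, kd) == pytest.approx(expected, rel=1e-8)

    def test_kd_eight_times_total(self):
        # closed form gives M = total0 * (sqrt(128) - 8) / 4
        assert equilibrium_dimer_fraction(1.0, 8.0) == pytest.approx(0.17157, abs=1e-4)


class TestSimulateProgress:
    def test_no_reactions_stays_at_initial_state(self):
        p = RateParameters(0, 0, 0, 0, 0, 0)
        c = simulate_progress(p, 1e-6, T_GRID)
        assert np.allclose(c.M, 1e-6, rtol=1e-9)
        assert np.all(c.P == 0) and np.all(c.MM == 0) and np.all(c.PM == 0)
        assert np.all(phospho_fraction(c) == 0)
        with pytest.raises(TimeToHalfNotReached):
            time_to_half(c)

    @pytest.mark.parametrize("scenario", ["no_IP6", "with_IP6"])
    def test_matches_fixed_step_euler_oracle(self, scenario):
        p = make_rate_parameters(scenario)
        t = np.linspace(0.0, 1e4, 101)
        c = simulate_progress(p, 1e-6, t)
        ref = euler_trajectory(p, 1e-6, t, dt=1e-3)
        sol = np.stack([c.M, c.P, c.MM, c.PM], axis=1)
        scale = np.abs(ref).max(axis=0)
        assert np.max(np.abs(sol - ref) / scale) < 1e-3

    @pytest.mark.parametrize("scenario", ["no_IP6", "with_IP6"])
    def test_conservation_and_nonnegativity(self, scenario):
        c = simulate_progress(make_rate_parameters(scenario), 1e-6, T_GRID)
        assert np.max(np.abs(c.conservation_error())) < 1e-6
        for s in (c.M, c.P, c.MM, c.PM):
            assert np.all(s >= 0)

    def test_phospho_fraction_saturates_with_ip6(self):
        t = np.linspace(0.0, 5e3, 200)
        c = simulate_progress(make_rate_parameters("with_IP6"), 1e-6, t)
        f = phospho_fraction(c)
        assert np.all((f >= 0) & (f <= 1 + 1e-9))
        assert f[-1] > 0.99  # no dephosphorylation: tends to complete activation

    def test_ip6_accelerates_activation_over_fivefold(self):
        t50 = {
            sc: time_to_half(simulate_progress(make_rate_parameters(sc), 1e-6, T_GRID))
            for sc in ("no_IP6", "with_IP6")
        }
        assert t50["with_IP6"] < 0.2 * t50["no_IP6"]

    @staticmethod
    def _phospho_rate(c):
        # exact instantaneous d(phospho-fraction)/dt from the mass balance
        p = c.params
        return (p.k2 * c.MM + p.k4 * c.PM) / c.total0

    def test_autocatalysis_makes_progress_sigmoidal(self):
        # k4 > k2: the phospho-rate peaks well after t = 0
        t = np.linspace(0.0, 1e4, 2001)
        c = simulate_progress(make_rate_parameters("no_IP6"), 1e-6, t)
        rate = self._phospho_rate(c)
        assert t[np.argmax(rate)] > 500.0

    def test_no_feedback_puts_rate_maximum_at_origin(self):
        # k4 = k2 with k3 = k1 removes the feedback: after the fast
        # complex-equilibration transient the rate only decays
        p = make_rate_parameters("no_IP6", k4=0.1)
        t = np.linspace(0.0, 1e4, 2001)
        c = simulate_progress(p, 1e-6, t)
        rate = self._phospho_rate(c)
        assert t[np.argmax(rate)] <= 50.0
        interior = rate[t >= 50.0]
        assert np.all(np.diff(interior) <= 1e-12)

    def test_catalysis_off_recovers_dimer_equilibrium(self):
        p = make_rate_parameters("no_IP6", k2=0.0, k4=0.0)
        t = np.linspace(0.0, 10.0, 50)  # equilibration time ~1/k_minus1
        c = simulate_progress(p, 1e-6, t)
        expected = equilibrium_dimer_fraction(1e-6, dimer_kd(p))
        assert 2 * c.MM[-1] / c.total0 == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize(
        "bad_grid", [np.array([1.0, 2.0]), np.array([0.0, 2.0, 1.0]), np.array([0.0])]
    )
    def test_bad_time_grids_rejected(self, bad_grid):
        with pytest.raises(ValueError):
            simulate_progress(make_rate_parameters("no_IP6"), 1e-6, bad_grid)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            simulate_progress(make_rate_parameters("no_IP6"), 0.0, T_GRID)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        k1=st.floats(1e2, 1e6),
        km1=st.floats(0.1, 100.0),
        k2=st.floats(0.0, 5.0),
        k3=st.floats(1e2, 1e6),
        km3=st.floats(0.1, 100.0),
        k4=st.floats(0.0, 5.0),
        total0=st.floats(1e-7, 1e-5),
    )
    def test_conservation_and_monotonicity_for_random_rates(
        self, k1, km1, k2, k3, km3, k4, total0
    ):
        p = RateParameters(k1, km1, k2, k3, km3, k4)
        c = simulate_progress(p, total0, np.linspace(0.0, 2e3, 60))
        assert np.max(np.abs(c.conservation_error())) < 1e-6
        f = phospho_fraction(c)
        assert np.all(np.diff(f) >= -1e-9)  # no dephosphorylation step
        for s in (c.M, c.P, c.MM, c.PM):
            assert np.all(s >= 0)


class TestTimeToHalf:
    def test_interpolates_linearly_between_bracketing_points(self):
        p = RateParameters(0, 0, 0, 0, 0, 0)
        c = ProgressCurve(
            t=np.array([0.0, 10.0]),
            M=np.array([1e-6, 0.0]),
            P=np.array([0.0, 1e-6]),
            MM=np.zeros(2),
            PM=np.zeros(2),
            total0=1e-6,
            params=p,
        )
        assert time_to_half(c) == pytest.approx(5.0)

    def test_exact_hit_returns_grid_time(self):
        p = RateParameters(0, 0, 0, 0, 0, 0)
        c = ProgressCurve(
            t=np.array([0.0, 4.0, 8.0]),
            M=np.array([1e-6, 0.5e-6, 0.0]),
            P=np.array([0.0, 0.5e-6, 1e-6]),
            MM=np.zeros(3),
            PM=np.zeros(3),
            total0=1e-6,
            params=p,
        )
        assert time_to_half(c) == pytest.approx(4.0)


def test_progress_curve_csv_round_trip(tmp_path):
    import pandas as pd

    c = simulate_progress(make_rate_parameters("with_IP6"), 1e-6, np.linspace(0, 100, 11))
    path = tmp_path / "curve.csv"
    c.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == [
        "time_s", "M_uM", "P_uM", "MM_uM", "PM_uM", "phospho_fraction"
    ]
    assert np.allclose(df["M_uM"], c.M * 1e6)
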