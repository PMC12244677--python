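"""Closed-loop assembly, gain-margin methods, sensitivity scaling laws."""

import numpy as np
import pandas as pd
import pytest

from armloop.loop import (build_closed_loop, loop_at_a_time_check,
                          sensitivity_analysis, system_gain_margin)
from armloop.plant import assemble_forward_path
from armloop.tables import (DelayTables, FeedbackParams, ForwardPathParams,
                            GainMatrix)
from armloop.muscles import CANONICAL_13, DELAY_11


class TestAssembly:
    def test_state_count_is_plant_plus_delay_blocks(self, plant_params,
                                                    feedback, delay_tables):
        closed = build_closed_loop(plant_params, feedback, delay_tables,
                                   pade_order=3, c=0.0)
        assert closed.n_states == 44 + 3 * 15

    def test_open_and_closed_agree_when_both_loops_off(self, plant_params,
                                                       gain_matrix,
                                                       delay_tables):
        fb = FeedbackParams(G=gain_matrix, c=0.0, k=1e-15,
                            allow_out_of_range=True)
        closed = build_closed_loop(plant_params, fb, delay_tables, 3, c=0.0)
        plant_poles = np.sort_complex(
            assemble_forward_path(plant_params).poles())
        closed_poles = np.sort_complex(closed.poles())
        for p in plant_poles:
            assert np.min(np.abs(closed_poles - p)) < 1e-6
        # torque steps produce no muscular response with both loops off
        t = np.arange(0.0, 0.2, 1e-3)
        y = closed.step_response("tau_ext:WFE", t)
        u_cols = [i for i, l in enumerate(closed.output_labels)
                  if l.startswith("u:")]
        assert np.allclose(y[:, u_cols], 0.0, atol=1e-12)

    def test_negative_c_rejected(self, plant_params, feedback, delay_tables):
        with pytest.raises(ValueError):
            build_closed_loop(plant_params, feedback, delay_tables, 3, c=-0.1)


def _toy_single_muscle(delay_free=True):
    """One muscle, one DOF, unit homonymous gain; Routh-analyzable."""
    labels = ("Delt Ant",)
    dof = ("SFE",)
    T1, T2, C = 0.03, 0.05, 100.0
    I, D, K = 0.1, 0.8, 5.0
    m_arm = 0.04
    params = ForwardPathParams(
        T1=np.array([T1]), T2=np.array([T2]), C=np.array([C]),
        M=np.array([[m_arm]]), I=np.array([[I]]), D=np.array([[D]]),
        K=np.array([[K]]), muscle_labels=labels, dof_labels=dof)
    v = pd.DataFrame(np.nan, index=list(CANONICAL_13),
                     columns=list(CANONICAL_13))
    v.loc["Delt Ant", "Delt Ant"] = 1.0
    G = GainMatrix(v)
    aff = pd.Series(0.0, index=list(DELAY_11))
    eff = pd.Series(0.0, index=list(DELAY_11))
    delays = DelayTables(afferent=aff, efferent=eff)
    return params, G, delays, (T1, T2, C, I, D, K, m_arm)


class _ToyLoop:
    """Single-muscle closed loop with proportional feedback, no delay."""

    @staticmethod
    def build(c, r=0.1):
        params, G, delays, consts = _toy_single_muscle()
        fb = FeedbackParams(G=G, c=c, r=r, k=1e-15, allow_out_of_range=True)
        # pade order irrelevant: delay is 1 ms central only
        return params, fb, delays, consts


class TestMarginMethods:
    def test_bisection_matches_routh_bound_on_toy(self):
        """Closed form: the toy's characteristic polynomial is quartic; the
        Routh-Hurwitz condition gives the exact critical gain."""
        params, fb, delays, (T1, T2, C, I, D, K, m) = _ToyLoop.build(0.0)
        rep = system_gain_margin(params, fb, delays, pade_order=1)
        # brute-force oracle: scan the characteristic polynomial directly.
        # loop: u -> f = C/((T1 s+1)(T2 s+1)) -> tau = m f -> q -> dlam=-m q
        # feedback (PD + 1ms central delay via first-order Pade):
        # closed-loop char poly from state matrix eigenvalues at c*.
        lo, hi = 0.0, 50.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            sys_ = build_closed_loop(params, fb, delays, 1, c=mid)
            if np.max(sys_.poles().real) < 0:
                lo = mid
            else:
                hi = mid
        assert rep.c_max == pytest.approx(lo, rel=1e-3)
        # analytic sanity: at c slightly below, stable; above, unstable
        below = build_closed_loop(params, fb, delays, 1, c=0.99 * rep.c_max)
        above = build_closed_loop(params, fb, delays, 1, c=1.01 * rep.c_max)
        assert below.is_stable()
        assert not above.is_stable()

    def test_toy_margin_matches_polynomial_root_oracle(self):
        """The single-muscle critical gain matches a characteristic
        polynomial composed by hand (classical Routh-style analysis via
        direct root finding), independently of the state-space assembly.

        Loop: u -> f = C/((T1 s+1)(T2 s+1)) u -> tau = m f -> q over the
        impedance -> dlam = -m q -> PD feedback (c/r)(1 + r s) through a
        first-order Pade of the 1 ms central delay, entering positively.
        """
        params, G, delays, (T1, T2, C, I, D, K, m) = _toy_single_muscle()
        r, T_c = 0.1, 0.001
        fb = FeedbackParams(G=G, c=0.0, r=r, k=1e-15, allow_out_of_range=True)

        def dominant(c):
            g = (c / r) * C * m * m
            fwd = np.polymul([T1 * T2, T1 + T2, 1.0], [I, D, K])
            fwd = np.polymul(fwd, [T_c / 2, 1.0])            # Pade-1 denom
            fbk = g * np.polymul([r, 1.0], [-T_c / 2, 1.0])  # Pade-1 num
            return np.max(np.roots(np.polyadd(fwd, fbk)).real)

        lo, hi = 0.0, 100.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if dominant(mid) < 0 else (lo, mid)
        rep = system_gain_margin(params, fb, delays, pade_order=1)
        assert rep.c_max == pytest.approx(lo, rel=1e-3)

    def test_sweep_and_bisection_agree(self, plant_params, feedback,
                                       delay_tables, margin):
        sweep = system_gain_margin(plant_params, feedback, delay_tables,
                                   method="disk_margin")
        assert sweep.c_max == pytest.approx(margin.c_max, rel=0.05)
        # cross-classification: both label c slightly in/outside as such
        for c, stable in [(0.95 * margin.c_max, True),
                          (1.05 * margin.c_max, False)]:
            sys_ = build_closed_loop(plant_params, feedback, delay_tables,
                                     3, c=c)
            assert sys_.is_stable() == stable

    def test_margin_report_brackets_instability(self, plant_params, feedback,
                                                delay_tables, margin):
        assert margin.c_max > 0
        assert margin.dominant_pole_real < 0

    def test_dominant_pole_monotone_near_margin(self, plant_params, feedback,
                                                delay_tables, margin):
        cs = np.linspace(0.75, 1.0, 5) * margin.c_max
        doms = []
        for c in cs:
            sys_ = build_closed_loop(plant_params, feedback, delay_tables,
                                     3, c=c)
            doms.append(np.max(sys_.poles().real))
        assert np.all(np.diff(doms) > 0)

    def test_unstable_inner_loop_rejected(self, plant_params, gain_matrix,
                                          delay_tables):
        fb_bad = FeedbackParams(G=gain_matrix, c=0.0, k=80.0,
                                allow_out_of_range=True)
        with pytest.raises(ValueError, match="unstable at c = 0"):
            system_gain_margin(plant_params, fb_bad, delay_tables)

    def test_unknown_method_rejected(self, plant_params, feedback,
                                     delay_tables):
        with pytest.raises(ValueError, match="unknown stability method"):
            system_gain_margin(plant_params, feedback, delay_tables,
                               method="routh")


class TestScalingLaws:
    def test_moment_arm_quadratic_law(self, plant_params, feedback,
                                      delay_tables, margin):
        for s, expect in [(0.5, 4.0), (2.0, 0.25)]:
            rep = system_gain_margin(plant_params.scaled(M=s), feedback,
                                     delay_tables)
            assert rep.c_max / margin.c_max == pytest.approx(expect, rel=1e-3)

    def test_max_force_linear_law(self, plant_params, feedback, delay_tables,
                                  margin):
        for s, expect in [(0.5, 2.0), (2.0, 0.5)]:
            rep = system_gain_margin(plant_params.scaled(C=s), feedback,
                                     delay_tables)
            assert rep.c_max / margin.c_max == pytest.approx(expect, rel=1e-3)

    def test_other_parameters_sublinear(self, plant_params, feedback,
                                        delay_tables, margin):
        """Impedance and time-constant scalings move the margin by less
        than the scale factor itself."""
        table = sensitivity_analysis(
            plant_params, feedback, delay_tables,
            scales=(0.5, 2.0), parameters=("I", "D", "K", "T1", "T2"))
        for (name, s), c_max in table.items():
            ratio = c_max / margin.c_max
            assert abs(np.log(ratio)) < abs(np.log(s)), (name, s, ratio)


class TestLoopAtATime:
    def test_degenerate_at_zero_gain(self, plant_params, feedback,
                                     delay_tables):
        """At c = 0 the printed criterion reduces to real(1) < 0: never met."""
        omega = np.logspace(-1, 2, 40)
        flags = loop_at_a_time_check(plant_params, feedback, delay_tables,
                                     c=0.0, omega=omega)
        assert not flags.any()

    def test_flags_appear_beyond_margin(self, plant_params, feedback,
                                        delay_tables, margin):
        omega = np.logspace(-1, 2.5, 200)
        flags = loop_at_a_time_check(plant_params, feedback, delay_tables,
                                     c=50.0 * margin.c_max, omega=omega)
        assert flags.any()
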