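"""Step/frequency response grids, pole summaries, stretch classification."""

import numpy as np
import pytest

from armloop.loop import build_closed_loop
from armloop.plant import assemble_forward_path, build_muscle_dynamics
from armloop.responses import (classify_stretch_response,
                               frequency_response_grid, pole_summary,
                               random_gain_experiment, resonance_peak,
                               step_response_grid)
from armloop.statespace import pade_delay
from armloop.muscles import DOF_7, MUSCLES


@pytest.fixture(scope="module")
def closed_75(plant_params, feedback, delay_tables, margin):
    return build_closed_loop(plant_params, feedback, delay_tables, 3,
                             c=0.75 * margin.c_max)


class TestPoleSummary:
    def test_matches_direct_eigenvalues(self, plant_params):
        sys_ = assemble_forward_path(plant_params)
        summ = pole_summary(sys_)
        assert np.allclose(np.sort_complex(summ.poles),
                           np.sort_complex(np.linalg.eigvals(sys_.A)))
        assert summ.n_real == 30 and summ.n_complex == 14

    def test_two_lag_siso_all_real(self):
        sys_ = build_muscle_dynamics(np.array([0.03]), np.array([0.05]),
                                     np.array([1.0]), labels=("m",))
        summ = pole_summary(sys_)
        assert summ.n_real == 2 and summ.n_complex == 0
        assert np.isnan(summ.stats.loc["mean", "natural_freq_hz"])

    def test_summary_statistics_conventions(self, plant_params):
        """Real poles are excluded from natural-frequency/damping stats."""
        sys_ = assemble_forward_path(plant_params)
        summ = pole_summary(sys_)
        cpx = summ.poles[np.abs(summ.poles.imag) > 1e-9]
        wn = np.abs(cpx) / (2 * np.pi)
        assert summ.stats.loc["mean", "natural_freq_hz"] == pytest.approx(
            wn.mean())
        zeta = -cpx.real / np.abs(cpx)
        assert summ.stats.loc["max", "damping_ratio"] == pytest.approx(
            zeta.max())

    def test_closed_loop_census_structure(self, closed_75):
        summ = pole_summary(closed_75)
        assert summ.is_stable
        assert summ.n_real + summ.n_complex == 89
        assert summ.n_complex % 2 == 0  # conjugate pairs


class TestStepGrid:
    def test_linearity_in_magnitude(self, closed_75):
        g1 = step_response_grid(closed_75, "tau_ext", "q", duration=0.4,
                                magnitude=1.0)
        g2 = step_response_grid(closed_75, "tau_ext", "q", duration=0.4,
                                magnitude=2.0)
        for key in g1.responses:
            assert np.allclose(2 * g1.responses[key], g2.responses[key],
                               rtol=1e-9, atol=1e-12)

    def test_grid_covers_all_channel_pairs(self, closed_75):
        grid = step_response_grid(closed_75, "uCNS", "q", duration=0.05)
        assert len(grid.responses) == 15 * 7

    def test_steady_state_matches_dc_gain(self, plant_params, feedback,
                                          delay_tables, margin):
        """Final-value check on a stable closed loop at half the margin."""
        sys_ = build_closed_loop(plant_params, feedback, delay_tables, 3,
                                 c=0.5 * margin.c_max)
        t = np.arange(0.0, 40.0, 2e-3)
        y = sys_.step_response("tau_ext:EFE", t, 1.0)
        dc = sys_.dc_gain()[:, sys_.input_index("tau_ext:EFE")]
        q_row = sys_.output_index("q:EFE")
        assert y[-1, q_row] == pytest.approx(dc[q_row], rel=1e-3)

    def test_unstable_configuration_refused(self, plant_params, feedback,
                                            delay_tables, margin):
        sys_ = build_closed_loop(plant_params, feedback, delay_tables, 3,
                                 c=1.2 * margin.c_max)
        with pytest.raises(ValueError, match="unstable"):
            step_response_grid(sys_, "uCNS", "q", duration=0.1)

    def test_diagonal_pairs_dominate_drive_to_displacement(self, closed_75,
                                                           plant_params):
        """The largest |q| response to a muscle's drive lies on a DOF the
        muscle actually spans (rank test, not exact values)."""
        grid = step_response_grid(closed_75, "uCNS", "q", duration=1.5)
        hits = 0
        for j, muscle in enumerate(MUSCLES.plant_15):
            peaks = {dof: np.abs(grid.responses[(muscle, dof)]).max()
                     for dof in DOF_7}
            best = max(peaks, key=peaks.get)
            spanned = {DOF_7[i] for i in
                       np.nonzero(plant_params.M[:, j])[0]}
            hits += best in spanned
        assert hits >= 12  # impedance coupling may divert a few


class TestFrequencyGrid:
    def test_pade_block_is_all_pass(self):
        sys_ = pade_delay(0.012, 3)
        H = sys_.frequency_response(2 * np.pi * np.linspace(0.1, 20, 50))
        assert np.allclose(np.abs(H[:, 0, 0]), 1.0, atol=1e-9)

    def test_dc_sample_matches_dc_gain(self, closed_75):
        freq, mag, _, dc = frequency_response_grid(closed_75, "tau_ext", "q",
                                                   n_freq=30)
        assert freq[0] == 0.0
        assert np.allclose(mag[0], dc, rtol=1e-8)

    def test_feedback_reduces_dc_gain_on_diagonal(self, plant_params,
                                                  feedback, delay_tables,
                                                  margin, closed_75):
        open_sys = build_closed_loop(plant_params, feedback, delay_tables, 3,
                                     c=0.0)
        _, _, _, dc_open = frequency_response_grid(open_sys, "tau_ext", "q",
                                                   n_freq=2)
        _, _, _, dc_closed = frequency_response_grid(closed_75, "tau_ext",
                                                     "q", n_freq=2)
        diag_open = np.diag(dc_open)
        diag_closed = np.diag(dc_closed)
        assert np.mean(diag_closed <= diag_open + 1e-12) > 0.5

    def test_resonance_peak_finder_on_second_order(self):
        w, zeta = 2 * np.pi * 4.0, 0.2
        from armloop.plant import build_impedance
        sys_ = build_impedance(np.eye(1), np.array([[2 * zeta * w]]),
                               np.array([[w ** 2]]), labels=("J",))
        freq = np.linspace(0.1, 12, 500)
        H = sys_.frequency_response(2 * np.pi * freq)[:, 0, 0]
        peak = resonance_peak(freq, np.abs(H))
        expected = 4.0 * np.sqrt(1 - 2 * zeta ** 2)
        assert peak is not None
        assert peak[0] == pytest.approx(expected, abs=0.1)


class TestStretchClassification:
    def test_zero_feedback_means_silent_muscles(self, plant_params, feedback,
                                                delay_tables):
        sys_ = build_closed_loop(plant_params, feedback, delay_tables, 3,
                                 c=0.0)
        fb_off = dict(G=feedback.G, c=0.0, k=1e-15, allow_out_of_range=True)
        from armloop.tables import FeedbackParams
        sys_off = build_closed_loop(plant_params, FeedbackParams(**fb_off),
                                    delay_tables, 3, c=0.0)
        labels, summary = classify_stretch_response(sys_off, delay_tables,
                                                    n_boot=0)
        assert labels["silent"].all()
        assert summary["n_cases"] == 0

    def test_classification_summary_and_reproducibility(self, closed_75,
                                                        delay_tables):
        _, s1 = classify_stretch_response(
            closed_75, delay_tables, rng=np.random.default_rng(3),
            n_boot=500)
        _, s2 = classify_stretch_response(
            closed_75, delay_tables, rng=np.random.default_rng(3),
            n_boot=500)
        assert s1["concordance_ci95"] == s2["concordance_ci95"]
        assert 0.0 <= s1["fraction_concordant"] <= 1.0
        assert s1["concordance_ci95"][0] <= s1["fraction_concordant"] \
            <= s1["concordance_ci95"][1]

    def test_muscle_without_afferents_stays_silent(self, closed_75,
                                                   delay_tables):
        """Bra receives no measured spindle feedback: no reflex response."""
        labels, _ = classify_stretch_response(closed_75, delay_tables,
                                              n_boot=0)
        assert labels.loc[labels["muscle"] == "Bra", "silent"].all()


class TestRandomGains:
    def test_seeded_reproducibility_and_empty_report(self, plant_params,
                                                     feedback, delay_tables):
        empty = random_gain_experiment(plant_params, feedback, delay_tables,
                                       mode="preserve_sign", n_draws=0,
                                       seed=5)
        assert empty["draws"] == []
        r1 = random_gain_experiment(plant_params, feedback, delay_tables,
                                    mode="preserve_sign", n_draws=2, seed=5,
                                    n_boot=0)
        r2 = random_gain_experiment(plant_params, feedback, delay_tables,
                                    mode="preserve_sign", n_draws=2, seed=5,
                                    n_boot=0)
        assert r1["draws"] == r2["draws"]

    def test_sign_preservation_keeps_majority_concordance(self, plant_params,
                                                          feedback,
                                                          delay_tables):
        rep = random_gain_experiment(plant_params, feedback, delay_tables,
                                     mode="preserve_sign", n_draws=3, seed=11,
                                     n_boot=0)
        assert rep["reference_concordance"] > 0.5
        assert rep["mean_concordance"] > 0.5

    def test_unknown_mode_rejected(self, plant_params, feedback,
                                   delay_tables):
        with pytest.raises(ValueError, match="unknown mode"):
            random_gain_experiment(plant_params, feedback, delay_tables,
                                   mode="scramble", n_draws=1, seed=0)
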