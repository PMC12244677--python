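"""Step/frequency responses, pole statistics and reflex-behaviour analyses.

The closed-loop model supports three families of input-output mappings:
descending neural drive to joint displacement (15 x 7), external joint
torque to muscle activity (7 x 15), and external joint torque to joint
displacement (7 x 7).  This module computes those response grids at a
ladder of feedback levels (fractions of the system-wide gain margin),
summarizes pole locations, classifies the short-latency stretch response
(does a lengthened muscle get excited?), and runs the pseudo-random
gain-matrix control experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .muscles import DOF_7, MUSCLES
from .statespace import LinearSystem
from .tables import DelayTables, FeedbackParams, ForwardPathParams, expand_to_plant
from .loop import DEFAULT_PADE_ORDER, build_closed_loop, system_gain_margin

__all__ = [
    "ResponseGrid", "PoleSummary", "step_response_grid", "pole_summary",
    "classify_stretch_response", "random_gain_experiment",
    "frequency_response_grid",
]


@dataclass(frozen=True)
class ResponseGrid:
    """Sampled step responses for one input kind / output kind pairing."""

    input_kind: str                 # "uCNS" or "tau_ext"
    output_kind: str                # "q", "u" or "dlam"
    feedback_level: float           # fraction of c_max used
    time: np.ndarray
    responses: dict                 # (input_channel, output_channel) -> array
    magnitude: float = 1.0


def _channels(kind: str):
    if kind in ("uCNS", "u", "f", "dlam", "dlamdot"):
        return list(MUSCLES.plant_15)
    if kind in ("tau_ext", "q"):
        return list(DOF_7)
    raise ValueError(f"unknown channel kind {kind!r}")


def step_response_grid(system: LinearSystem, input_kind: str,
                       output_kind: str, duration: float = 3.0,
                       dt: float = 1e-3, magnitude: float | None = None,
                       feedback_level: float = 0.0) -> ResponseGrid:
    """Step responses for every (input, output) channel pair.

    Default magnitudes: 1 MVC for neural-drive steps, 1 N m for external
    torque steps.  Refuses unstable systems.
    """
    if not system.is_stable():
        raise ValueError("system is unstable; refusing to simulate step "
                         "responses (dominant pole in right half plane)")
    if magnitude is None:
        magnitude = 1.0
    t = np.arange(0.0, duration, dt)
    in_ch = _channels(input_kind)
    out_ch = _channels(output_kind)
    out_rows = [system.output_index(f"{output_kind}:{c}") for c in out_ch]
    responses = {}
    for ic in in_ch:
        y = system.step_response(f"{input_kind}:{ic}", t, magnitude)
        for oc, row in zip(out_ch, out_rows):
            responses[(ic, oc)] = y[:, row]
    return ResponseGrid(input_kind=input_kind, output_kind=output_kind,
                        feedback_level=feedback_level, time=t,
                        responses=responses, magnitude=magnitude)


@dataclass(frozen=True)
class PoleSummary:
    """Pole locations plus descriptive statistics in printed-table form.

    Real/imaginary parts are reported in Hz (rad/s divided by 2 pi);
    imaginary statistics use absolute values; natural-frequency and
    damping-ratio statistics exclude real poles; time constants are
    -1/Re(pole) in seconds.
    """

    poles: np.ndarray
    n_real: int
    n_complex: int
    stats: pd.DataFrame

    @property
    def is_stable(self) -> bool:
        return bool(np.max(self.poles.real) < 0)


def pole_summary(system: LinearSystem, imag_tol: float = 1e-9) -> PoleSummary:
    poles = np.sort_complex(system.poles())
    is_real = np.abs(poles.imag) <= imag_tol * np.maximum(1.0, np.abs(poles))
    n_real = int(is_real.sum())
    n_complex = len(poles) - n_real
    two_pi = 2 * np.pi
    real_hz = poles.real / two_pi
    imag_hz = np.abs(poles.imag) / two_pi
    tau = np.where(poles.real < 0, -1.0 / poles.real, np.inf)
    cpx = poles[~is_real]
    wn = np.abs(cpx) / two_pi
    zeta = -cpx.real / np.abs(cpx)

    def describe(v):
        v = np.asarray(v, dtype=float)
        if len(v) == 0:
            return [np.nan] * 4
        return [v.mean(), v.std(ddof=1) if len(v) > 1 else 0.0, v.min(), v.max()]

    stats = pd.DataFrame(
        {"real_hz": describe(real_hz), "imag_hz": describe(imag_hz),
         "time_constant_s": describe(tau[np.isfinite(tau)]),
         "natural_freq_hz": describe(wn), "damping_ratio": describe(zeta)},
        index=["mean", "sd", "min", "max"])
    return PoleSummary(poles=poles, n_real=n_real, n_complex=n_complex,
                       stats=stats)


def _window_sign(trace: np.ndarray, atol: float) -> int:
    """+1 / -1 for a consistent sign inside the window, 0 for ambiguous."""
    active = trace[np.abs(trace) > atol]
    if len(active) == 0:
        return 0
    signs = np.sign(active)
    if np.all(signs > 0):
        return 1
    if np.all(signs < 0):
        return -1
    return 0


def classify_stretch_response(system: LinearSystem, delays: DelayTables,
                              window_s: float = 0.025, dt: float = 2e-4,
                              magnitude: float = 1.0, atol_frac: float = 1e-6,
                              rng: np.random.Generator | None = None,
                              n_boot: int = 10_000):
    """Short-latency stretch-response classification over all (DOF, muscle).

    For a step in external torque on each DOF, each muscle's elongation
    and activity signals are inspected over a 25 ms window starting at
    that muscle's own lumped round-trip delay (the signals before the
    delay are reflex-free).  Labels: lengthened/shortened/ambiguous from
    the elongation sign, excited/inhibited/ambiguous/silent from the
    activity sign.  Returns a DataFrame of labels plus a dict with the
    concordance fraction (lengthened->excited, shortened->inhibited) among
    unambiguous cases, the unambiguous fraction, and a seeded bootstrap
    95% confidence interval for the concordance.
    """
    rt_ms = expand_to_plant(delays.roundtrip_per_canonical(), mode="replicate")
    t_end = float(rt_ms.max()) / 1000.0 + window_s + 5 * dt
    t = np.arange(0.0, t_end, dt)
    rows = []
    for dof in DOF_7:
        y = system.simulate(
            _step_input(system, f"tau_ext:{dof}", t, magnitude), t)
        for m in MUSCLES.plant_15:
            delay_s = rt_ms[m] / 1000.0
            i0 = int(np.ceil(delay_s / dt))
            i1 = i0 + int(round(window_s / dt))
            lam = y[i0:i1, system.output_index(f"dlam:{m}")]
            act = y[i0:i1, system.output_index(f"u:{m}")]
            lam_scale = np.abs(y[:, system.output_index(f"dlam:{m}")]).max()
            act_scale = np.abs(y[:, system.output_index(f"u:{m}")]).max()
            s_lam = _window_sign(lam, atol_frac * max(lam_scale, 1e-300))
            s_act = (0 if act_scale == 0
                     else _window_sign(act, atol_frac * act_scale))
            rows.append({"dof": dof, "muscle": m,
                         "length": {1: "lengthened", -1: "shortened",
                                    0: "ambiguous"}[s_lam],
                         "activity": ("silent" if act_scale == 0 else
                                      {1: "excited", -1: "inhibited",
                                       0: "ambiguous"}[s_act]),
                         "s_lam": s_lam, "s_act": s_act,
                         "silent": act_scale == 0})
    labels = pd.DataFrame(rows)
    active = labels[~labels["silent"]]
    unamb = active[(active["s_lam"] != 0) & (active["s_act"] != 0)]
    n_cases = len(active)
    frac_unamb = len(unamb) / n_cases if n_cases else float("nan")
    concordant = (unamb["s_lam"] == unamb["s_act"]).to_numpy()
    frac_conc = concordant.mean() if len(unamb) else float("nan")
    ci = (float("nan"), float("nan"))
    if len(unamb) and n_boot:
        rng = rng or np.random.default_rng(0)
        boot = rng.choice(concordant.astype(float),
                          size=(n_boot, len(concordant)), replace=True).mean(axis=1)
        ci = tuple(np.percentile(boot, [2.5, 97.5]))
    summary = {"n_cases": n_cases, "n_unambiguous": len(unamb),
               "fraction_unambiguous": frac_unamb,
               "fraction_concordant": frac_conc,
               "concordance_ci95": ci}
    return labels, summary


def _step_input(system: LinearSystem, label: str, t: np.ndarray,
                magnitude: float) -> np.ndarray:
    u = np.zeros((len(t), system.n_inputs))
    u[:, system.input_index(label)] = magnitude
    return u


def frequency_response_grid(system: LinearSystem, input_kind: str,
                            output_kind: str, f_max_hz: float = 20.0,
                            n_freq: int = 400):
    """Magnitude/phase over 0..f_max Hz for every channel pair.

    Returns (freq_hz, magnitude, phase, dc_gain) with arrays of shape
    (n_freq, n_out, n_in); includes a DC sample at 0 Hz.
    """
    freq = np.linspace(0.0, f_max_hz, n_freq)
    in_ch = [f"{input_kind}:{c}" for c in _channels(input_kind)]
    out_ch = [f"{output_kind}:{c}" for c in _channels(output_kind)]
    sub = system.subsystem(inputs=in_ch, outputs=out_ch)
    H = sub.frequency_response(2 * np.pi * freq)
    return freq, np.abs(H), np.angle(H), np.abs(sub.dc_gain())


def resonance_peak(freq_hz: np.ndarray, magnitude: np.ndarray):
    """Largest interior magnitude peak: (frequency_hz, magnitude) or None."""
    m = np.asarray(magnitude)
    interior = (m[1:-1] > m[:-2]) & (m[1:-1] > m[2:])
    if not interior.any():
        return None
    idx = np.argmax(np.where(interior, m[1:-1], -np.inf)) + 1
    return float(freq_hz[idx]), float(m[idx])


def random_gain_experiment(params: ForwardPathParams, fb: FeedbackParams,
                           delays: DelayTables, mode: str,
                           n_draws: int, seed: int,
                           feedback_level: float = 0.75,
                           pade_order: int = DEFAULT_PADE_ORDER,
                           max_retries_per_draw: int = 50,
                           n_boot: int = 200):
    """Stretch-response experiment with pseudo-random spindle gain matrices.

    Every present element of the proportional gain matrix is redrawn from
    a uniform distribution bounded by the largest absolute estimated
    element; ``preserve_sign`` keeps each element's estimated sign (zeros
    stay zero), ``shuffle_all`` draws sign and value freely.  The
    derivative matrix follows proportionally (V = rL).  Unstable draws
    are rejected.  Returns a report with the per-draw concordance
    fractions plus the estimated-gain reference value.
    """
    if mode not in ("preserve_sign", "shuffle_all"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    report = {"mode": mode, "n_draws": n_draws, "draws": []}
    if n_draws == 0:
        return report

    margin = system_gain_margin(params, fb, delays, pade_order=pade_order)
    c_use = feedback_level * margin.c_max
    base = dc_replace(fb, c=c_use)
    ref_system = build_closed_loop(params, base, delays, pade_order, c=c_use)
    _, ref_summary = classify_stretch_response(
        ref_system, delays, rng=np.random.default_rng(seed), n_boot=n_boot)
    report["reference_concordance"] = ref_summary["fraction_concordant"]

    G0 = fb.G.fill_delt_lat().filled(0.0).values
    bound = float(np.abs(G0.to_numpy()).max())  # relative scale; L = (c/r) G
    for _ in range(n_draws):
        for _attempt in range(max_retries_per_draw):
            g = G0.to_numpy().copy()
            present = g != 0
            if mode == "preserve_sign":
                g[present] = np.sign(g[present]) * rng.uniform(
                    0, bound, size=present.sum())
            else:
                g[:, :] = rng.uniform(-bound, bound, size=g.shape)
            Gr = fb.G.values.copy()
            Gr.loc[:, :] = g
            from .tables import GainMatrix
            fb_r = dc_replace(base, G=GainMatrix(Gr))
            system = build_closed_loop(params, fb_r, delays, pade_order,
                                       c=c_use)
            if system.is_stable():
                break
        else:
            raise RuntimeError("no stable random gain matrix found within "
                               f"{max_retries_per_draw} retries")
        _, summary = classify_stretch_response(
            system, delays, rng=np.random.default_rng(seed + 1), n_boot=0)
        report["draws"].append(
            {"fraction_concordant": summary["fraction_concordant"],
             "fraction_unambiguous": summary["fraction_unambiguous"]})
    vals = [d["fraction_concordant"] for d in report["draws"]]
    report["mean_concordance"] = float(np.mean(vals))
    return report
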