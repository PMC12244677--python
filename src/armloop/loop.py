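"""Closed-loop interconnection and multiloop stability analysis.

The feedback path adds, per muscle, the spindle signal (a
proportional-derivative function of all muscles' elongations through the
gain matrices L = (c/r)G and V = cG, entering the summing junction as
positive feedback) and the GTO signal (-k/C_i times the muscle's own
force).  Both ride through one lumped round-trip transport delay per
muscle (afferent + 1 ms central + efferent), approximated by a single
Padé block per channel, so a Padé order of 3 adds 45 states to the
44-state plant.

The scale factor c that turns the relative gain matrix G into absolute
gains is bounded by stability: the *system-wide gain margin* is the
largest c for which every closed-loop pole stays in the open left half
plane, with the GTO loop closed and delays included.  Two methods are
provided: a bisection on the dominant pole (authoritative) and a
frequency-sweep multiloop margin that finds where an eigenvalue locus of
the broken-loop transfer matrix crosses the positive real axis
(det(I - c L(jw)) = 0).  The per-loop criterion real(1 - c S_i P_k) < 0
is exposed as a diagnostic only: it describes the instability boundary of
one loop at a time and is vacuous at c = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .muscles import MUSCLES
from .statespace import LinearSystem, pade_bank
from .tables import DelayTables, FeedbackParams, ForwardPathParams, expand_gain_to_plant
from .plant import assemble_forward_path

__all__ = [
    "StabilityReport", "build_closed_loop", "system_gain_margin",
    "loop_at_a_time_check", "sensitivity_analysis", "DEFAULT_PADE_ORDER",
]

DEFAULT_PADE_ORDER = 3


@dataclass(frozen=True)
class StabilityReport:
    method: str
    c_max: float
    dominant_pole_real: float
    iterations: tuple = ()

    def __post_init__(self) -> None:
        if self.c_max < 0:
            raise ValueError("gain margin must be nonnegative")


@dataclass(frozen=True)
class _LoopPieces:
    """Precomputed blocks of the closed-loop state matrix, affine in c."""

    A0: np.ndarray          # closed loop with c = 0 (GTO + delays active)
    A1: np.ndarray          # dA/dc (spindle loop contribution)
    plant: LinearSystem
    bank: LinearSystem
    Wsp: np.ndarray         # plant state -> spindle feedback signal (c=1)
    Wgto: np.ndarray        # plant state -> GTO feedback signal
    delays_s: np.ndarray


def _row_block(sys: LinearSystem, prefix: str) -> np.ndarray:
    rows = [i for i, l in enumerate(sys.output_labels) if l.startswith(prefix)]
    return sys.C[rows, :]


def _plant_gain_matrix(fb: FeedbackParams, muscle_labels,
                       expansion_mode: str) -> np.ndarray:
    """Filled gain matrix on the plant's muscle set (storage orientation)."""
    if set(fb.G.labels) == set(muscle_labels):
        return (fb.G.filled(0.0).values
                .loc[list(muscle_labels), list(muscle_labels)].to_numpy())
    filled = fb.G.fill_delt_lat().filled(0.0)
    if tuple(muscle_labels) == tuple(MUSCLES.plant_15):
        return expand_gain_to_plant(filled, mode=expansion_mode)
    # reduced plant drawn from canonical muscles
    sub = filled.values.loc[list(muscle_labels), list(muscle_labels)]
    return sub.to_numpy()


def _lumped_delays_s(delays: DelayTables, muscle_labels) -> np.ndarray:
    """Per-channel round-trip delay a + 1 ms + e (s) on the plant labels."""
    rt13 = delays.roundtrip_per_canonical()
    out = []
    for label in muscle_labels:
        canon = (MUSCLES.canonical_of_head(label)
                 if label in MUSCLES.plant_15 else label)
        out.append(rt13[canon])
    return np.asarray(out) / 1000.0


def _loop_pieces(params: ForwardPathParams, fb: FeedbackParams,
                 delays: DelayTables, pade_order: int,
                 expansion_mode: str = "replicate") -> _LoopPieces:
    plant = assemble_forward_path(params)
    n_m = len(params.muscle_labels)

    Gm = _plant_gain_matrix(fb, params.muscle_labels, expansion_mode)
    # formula orientation: row = target, column = source
    Gf = Gm.T
    L_over_c = Gf / fb.r          # L = (c/r) G
    V_over_c = Gf                 # V = c G
    C_dlam = _row_block(plant, "dlam:")
    C_dlamdot = _row_block(plant, "dlamdot:")
    Wsp = L_over_c @ C_dlam + V_over_c @ C_dlamdot

    gto = fb.gto_gains(params.C)
    Wgto = -np.diag(gto) @ _row_block(plant, "f:")

    delays_s = _lumped_delays_s(delays, params.muscle_labels)
    bank = pade_bank(delays_s, order=pade_order,
                     labels=[f"d:{m}" for m in params.muscle_labels])

    Bu = plant.B[:, :n_m]
    n_p, n_d = plant.n_states, bank.n_states
    Dd, Cd, Bd, Ad = bank.D, bank.C, bank.B, bank.A

    def asm(W):
        A = np.zeros((n_p + n_d, n_p + n_d))
        A[:n_p, :n_p] = Bu @ Dd @ W
        A[:n_p, n_p:] = Bu @ Cd
        A[n_p:, :n_p] = Bd @ W
        A[n_p:, n_p:] = Ad
        return A

    A0 = asm(Wgto)
    A0[:n_p, :n_p] += plant.A
    A1 = asm(Wsp)
    A1[:n_p, n_p:] = 0.0
    A1[n_p:, n_p:] = 0.0
    return _LoopPieces(A0=A0, A1=A1, plant=plant, bank=bank, Wsp=Wsp,
                       Wgto=Wgto, delays_s=delays_s)


def build_closed_loop(params: ForwardPathParams, fb: FeedbackParams,
                      delays: DelayTables, pade_order: int = DEFAULT_PADE_ORDER,
                      c: float | None = None,
                      expansion_mode: str = "replicate") -> LinearSystem:
    """Assemble the closed-loop system (inputs uCNS, tau_ext).

    ``c`` defaults to ``fb.c``.  Missing spindle gains are filled with
    zero and the Delt Lat homonymous gain with the mean of the other two
    heads before expansion to the 15-muscle plant.  State count is
    44 + pade_order * 15.
    """
    if c is None:
        c = fb.c
    if c < 0:
        raise ValueError("c must be nonnegative")
    pieces = _loop_pieces(params, fb, delays, pade_order, expansion_mode)
    plant, bank = pieces.plant, pieces.bank
    n_m = len(params.muscle_labels)
    n_p, n_d = plant.n_states, bank.n_states
    W = c * pieces.Wsp + pieces.Wgto

    A = pieces.A0 + c * pieces.A1
    B = np.zeros((n_p + n_d, plant.n_inputs))
    B[:n_p, :] = plant.B

    # outputs: as the plant, but u = uCNS + delayed feedback
    C = np.zeros((plant.n_outputs, n_p + n_d))
    C[:, :n_p] = plant.C
    D = plant.D.copy()
    u_rows = [i for i, l in enumerate(plant.output_labels)
              if l.startswith("u:")]
    C[u_rows, :n_p] += bank.D @ W
    C[u_rows, n_p:] += bank.C
    return LinearSystem(A, B, C, D, plant.input_labels, plant.output_labels)


def _max_real(A: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(A).real))


def _bisect_margin(pieces: _LoopPieces, tol: float) -> StabilityReport:
    if _max_real(pieces.A0) >= 0:
        raise ValueError("plant with GTO loop is unstable at c = 0; "
                         "no spindle gain margin exists")
    lo, hi = 0.0, 0.5
    log = []
    while _max_real(pieces.A0 + hi * pieces.A1) < 0:
        lo, hi = hi, hi * 2
        log.append((hi, "expanding"))
        if hi > 1e6:
            raise ValueError("no finite gain margin found below c = 1e6")
    while hi - lo > tol * hi:  # relative tolerance on the margin
        mid = 0.5 * (lo + hi)
        alpha = _max_real(pieces.A0 + mid * pieces.A1)
        log.append((mid, alpha))
        if alpha < 0:
            lo = mid
        else:
            hi = mid
    return StabilityReport(
        method="bisection", c_max=lo,
        dominant_pole_real=_max_real(pieces.A0 + lo * pieces.A1),
        iterations=tuple(log))


def _broken_loop_tf(pieces: _LoopPieces, omega: np.ndarray) -> np.ndarray:
    """Eigen-sweep transfer: spindle loop broken before the delay bank."""
    plant, bank = pieces.plant, pieces.bank
    n_m = pieces.Wsp.shape[0]
    n_p, n_d = plant.n_states, bank.n_states
    A = pieces.A0
    B = np.zeros((n_p + n_d, n_m))
    Bu = plant.B[:, :n_m]
    B[:n_p, :] = Bu @ bank.D
    B[n_p:, :] = bank.B
    C = np.zeros((n_m, n_p + n_d))
    C[:, :n_p] = pieces.Wsp
    sys = LinearSystem(A, B, C, np.zeros((n_m, n_m)))
    return sys.frequency_response(omega)


def _sweep_margin(pieces: _LoopPieces, n_freq: int = 1200,
                  omega_max: float = 2000.0) -> StabilityReport:
    """Frequency-sweep multiloop margin from broken-loop eigenvalue loci.

    Instability onset satisfies det(I - c L(jw)) = 0, i.e. 1/c is a real
    positive eigenvalue of the broken-loop transfer L(jw).  Eigenvalue
    branches are tracked across a dense frequency grid; real-axis
    crossings with positive real part yield candidate margins 1/Re.
    """
    omega = np.concatenate([[0.0], np.logspace(-2, np.log10(omega_max),
                                               n_freq - 1)])
    H = _broken_loop_tf(pieces, omega)
    n = H.shape[1]
    candidates = []
    prev = np.linalg.eigvals(H[0])
    # DC: eigenvalues are exactly real
    for lam in prev:
        if abs(lam.imag) < 1e-9 and lam.real > 0:
            candidates.append((1.0 / lam.real, 0.0))
    for idx in range(1, len(omega)):
        cur_raw = np.linalg.eigvals(H[idx])
        # greedy nearest-neighbour branch matching
        cur = np.empty_like(prev)
        used = np.zeros(n, dtype=bool)
        for i, p in enumerate(prev):
            dists = np.where(used, np.inf, np.abs(cur_raw - p))
            j = int(np.argmin(dists))
            used[j] = True
            cur[i] = cur_raw[j]
        for i in range(n):
            im0, im1 = prev[i].imag, cur[i].imag
            if im0 == 0.0 and prev[i].real > 0:
                candidates.append((1.0 / prev[i].real, omega[idx - 1]))
            elif im0 * im1 < 0:
                frac = abs(im0) / (abs(im0) + abs(im1))
                re_cross = prev[i].real + frac * (cur[i].real - prev[i].real)
                if re_cross > 0:
                    candidates.append(
                        (1.0 / re_cross,
                         omega[idx - 1] + frac * (omega[idx] - omega[idx - 1])))
        prev = cur
    if not candidates:
        raise ValueError("no real-axis crossing found; increase omega_max")
    c_max, w_star = min(candidates)
    alpha = _max_real(pieces.A0 + c_max * pieces.A1)
    return StabilityReport(method="disk_margin", c_max=float(c_max),
                           dominant_pole_real=alpha,
                           iterations=((w_star, len(candidates)),))


def system_gain_margin(params: ForwardPathParams, fb: FeedbackParams,
                       delays: DelayTables,
                       pade_order: int = DEFAULT_PADE_ORDER,
                       method: str = "bisection", tol: float = 1e-4,
                       expansion_mode: str = "replicate") -> StabilityReport:
    """System-wide gain margin: the largest stable spindle scale factor c.

    The search runs on the full interconnection — GTO loop closed at
    ``fb.k`` and per-channel Padé delays included.  ``method`` selects
    ``bisection`` (dominant closed-loop pole, authoritative) or
    ``disk_margin`` (frequency-sweep multiloop bound).
    """
    pieces = _loop_pieces(params, fb, delays, pade_order, expansion_mode)
    if method == "bisection":
        return _bisect_margin(pieces, tol)
    if method == "disk_margin":
        return _sweep_margin(pieces)
    raise ValueError(f"unknown stability method {method!r}")


def loop_at_a_time_check(params: ForwardPathParams, fb: FeedbackParams,
                         delays: DelayTables, c: float,
                         omega: np.ndarray,
                         pade_order: int = DEFAULT_PADE_ORDER) -> np.ndarray:
    """Per-loop diagnostic real(1 - c S_i P_k) < 0 over a frequency grid.

    Returns a boolean (target, input) matrix that is True where the
    criterion is met at some grid frequency — the single-loop instability
    boundary condition.  At c = 0 the expression is real(1) < 0, never
    true; the multiloop margin, not this diagnostic, is authoritative.
    """
    pieces = _loop_pieces(params, fb, delays, pade_order)
    plant, bank = pieces.plant, pieces.bank
    n_m = pieces.Wsp.shape[0]
    n_p, n_d = plant.n_states, bank.n_states
    # open both loops: uCNS -> delayed spindle signal
    A = np.zeros((n_p + n_d, n_p + n_d))
    A[:n_p, :n_p] = plant.A
    A[n_p:, :n_p] = bank.B @ pieces.Wsp
    A[n_p:, n_p:] = bank.A
    B = np.zeros((n_p + n_d, n_m))
    B[:n_p, :] = plant.B[:, :n_m]
    C = np.zeros((n_m, n_p + n_d))
    C[:, :n_p] = bank.D @ pieces.Wsp
    C[:, n_p:] = bank.C
    H = LinearSystem(A, B, C, np.zeros((n_m, n_m))).frequency_response(omega)
    return np.any((1.0 - c * H).real < 0, axis=0)


def sensitivity_analysis(params: ForwardPathParams, fb: FeedbackParams,
                         delays: DelayTables,
                         scales=(0.5, 1.0, 2.0),
                         parameters=("T1", "T2", "C", "M", "I", "D", "K"),
                         pade_order: int = DEFAULT_PADE_ORDER,
                         tol: float = 1e-4):
    """Gain margin c_max after scaling each forward-path parameter.

    Every element of one parameter at a time is multiplied by each scale;
    returns a dict {(parameter, scale): c_max}.  Exact laws hold for the
    purely multiplicative parameters: scaling M by s divides c_max by s^2
    (M sits in both the torque path and the elongation path) and scaling C
    by s divides it by s (C sits in the forward path only; the GTO loop is
    invariant because k/C cancels it).
    """
    out = {}
    for name in parameters:
        for s in scales:
            p = params if s == 1.0 else params.scaled(**{name: s})
            rep = system_gain_margin(p, fb, delays, pade_order=pade_order,
                                     method="bisection", tol=tol)
            out[(name, s)] = rep.c_max
    return out
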