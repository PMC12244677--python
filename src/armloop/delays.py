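"""Decomposition of round-trip reflex delays into afferent/efferent delays.

A short-loop reflex from source muscle i to target muscle j takes
``T_ij = a_i + c_ij + e_j``: afferent conduction to the cord, a central
(synaptic) delay, and efferent conduction back out.  Homonymous central
delays are 1 ms (one synapse); measured *excess* central delay (ECD) adds
to that for heteronymous paths.  Given measured round-trip delays and
central delays, each measured pair contributes one linear equation
``a_i + e_j = T_ij - c_ij``; the stacked system ``A x = b`` is solved by
least squares.

The design matrix always annihilates the direction "+1 on every afferent
unknown, -1 on every efferent unknown" (each equation contains exactly one
of each), so the decomposition is determined only up to a common shift;
the minimum-norm pseudo-inverse solution is reported, along with whether
further (unexpected) rank deficiency is present.  An optional anchor pins
one afferent delay for synthetic-recovery work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .muscles import DELAY_11
from .tables import GainMatrix

__all__ = [
    "DelayLinearSystem", "impute_central_delays", "assemble_system",
    "solve_delays", "regress_vs_innervation_length",
    "extrapolate_missing_muscle", "ECD_THRESHOLD_MS",
]

#: excitatory/inhibitory classification threshold on excess central delay
ECD_THRESHOLD_MS = 0.5

HOMONYMOUS_CENTRAL_MS = 1.0


@dataclass(frozen=True)
class DelayLinearSystem:
    """The stacked per-pair equations a_i + e_j = T_ij - c_ij.

    ``A`` has one row per measured pair with exactly two ones (the source's
    afferent column and the target's efferent column); columns are labeled
    by ``unknowns`` as ``("a", muscle)`` / ``("e", muscle)``.
    """

    A: np.ndarray
    rhs: np.ndarray
    unknowns: tuple[tuple[str, str], ...]
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.A.shape != (len(self.pairs), len(self.unknowns)):
            raise ValueError("design matrix shape inconsistent with labels")
        if not np.all(self.A.sum(axis=1) == 2):
            raise ValueError("each equation must couple one afferent and one efferent")


def _sign_matrix(G: GainMatrix | None) -> pd.DataFrame | None:
    if G is None:
        return None
    from .spindle import collapse_deltoid
    collapsed = collapse_deltoid(G) if set(G.labels) != set(DELAY_11) else G
    return collapsed.values


def impute_central_delays(
    ecd: pd.DataFrame,
    G: GainMatrix | None = None,
    pairs=None,
    threshold: float = ECD_THRESHOLD_MS,
) -> pd.DataFrame:
    """Central-delay matrix c_ij (ms) with sign-based imputation.

    Measured cells: c = ecd + 1 ms.  Homonymous cells: exactly 1 ms.  For
    each requested unmeasured heteronymous pair, the central delay is the
    mean of measured central delays over excitatory pairs if the pair's
    feedback is excitatory (gain > 0, or missing gain with no fallback),
    or over inhibitory pairs if inhibitory.  Pairs lacking both an ECD
    value and a gain sign stay NaN (the caller excludes them from the
    linear system).

    ``pairs`` restricts imputation to the given (source, target) list;
    by default every cell with an available sign is imputed.
    """
    labels = list(ecd.index)
    central = ecd + HOMONYMOUS_CENTRAL_MS
    for m in labels:
        central.loc[m, m] = HOMONYMOUS_CENTRAL_MS

    signs = _sign_matrix(G)

    def classify(src, tgt):
        """+1 excitatory, -1 inhibitory, None unknown (zero gains too)."""
        if signs is not None and not np.isnan(signs.loc[src, tgt]):
            g = signs.loc[src, tgt]
            if g > 0:
                return 1
            if g < 0:
                return -1
            return None
        e = ecd.loc[src, tgt]
        if not np.isnan(e):  # threshold fallback
            return 1 if e < threshold else -1
        return None

    exc, inh = [], []
    for src in labels:
        for tgt in labels:
            if src == tgt:
                continue
            e = ecd.loc[src, tgt]
            if np.isnan(e):
                continue
            cls = classify(src, tgt)
            if cls == 1:
                exc.append(e + HOMONYMOUS_CENTRAL_MS)
            elif cls == -1:
                inh.append(e + HOMONYMOUS_CENTRAL_MS)
    exc_mean = float(np.mean(exc)) if exc else np.nan
    inh_mean = float(np.mean(inh)) if inh else np.nan

    wanted = pairs if pairs is not None else [
        (s, t) for s in labels for t in labels if s != t]
    for src, tgt in wanted:
        if not np.isnan(central.loc[src, tgt]):
            continue
        cls = classify(src, tgt)
        if cls == 1:
            central.loc[src, tgt] = exc_mean
        elif cls == -1:
            central.loc[src, tgt] = inh_mean
    return central


def assemble_system(roundtrip: pd.DataFrame,
                    central: pd.DataFrame) -> DelayLinearSystem:
    """Build the least-squares system from measured round-trip delays.

    Pairs whose central delay is unavailable are excluded (flagged by
    omission from ``pairs``).  A muscle appearing in no measurement as a
    source (resp. target) receives no afferent (resp. efferent) column.
    """
    measured = [(s, t) for s in roundtrip.index for t in roundtrip.columns
                if not np.isnan(roundtrip.loc[s, t])
                and not np.isnan(central.loc[s, t])]
    if not measured:
        raise ValueError("no measured round-trip delays with known central delay")
    sources = sorted({s for s, _ in measured}, key=list(roundtrip.index).index)
    targets = sorted({t for _, t in measured}, key=list(roundtrip.index).index)
    unknowns = tuple([("a", m) for m in sources] + [("e", m) for m in targets])
    col = {u: i for i, u in enumerate(unknowns)}
    A = np.zeros((len(measured), len(unknowns)))
    rhs = np.zeros(len(measured))
    for row, (s, t) in enumerate(measured):
        A[row, col[("a", s)]] = 1.0
        A[row, col[("e", t)]] = 1.0
        rhs[row] = roundtrip.loc[s, t] - central.loc[s, t]
    return DelayLinearSystem(A=A, rhs=rhs, unknowns=unknowns,
                             pairs=tuple(measured))


@dataclass(frozen=True)
class DelaySolution:
    afferent: pd.Series
    efferent: pd.Series
    residuals: np.ndarray
    rank: int
    shift_indeterminate: bool
    null_space: np.ndarray | None


def solve_delays(system: DelayLinearSystem,
                 anchor: tuple[str, float] | None = None) -> DelaySolution:
    """Minimum-norm least-squares decomposition of the delay system.

    ``anchor`` optionally fixes one muscle's afferent delay (``(muscle,
    value_ms)``), removing the common-shift indeterminacy; used for
    synthetic parameter-recovery validation.  The solution reports the
    residual vector, the numerical rank, whether the shift direction is in
    the null space (it always is, structurally), and the null-space basis
    when rank deficiency goes beyond that known direction.
    """
    A, rhs = system.A, system.rhs
    if anchor is not None:
        muscle, value = anchor
        idx = system.unknowns.index(("a", muscle))
        # eliminate the anchored unknown
        rhs = rhs - A[:, idx] * value
        keep = [i for i in range(A.shape[1]) if i != idx]
        x_rest, *_ = np.linalg.lstsq(A[:, keep], rhs, rcond=None)
        x = np.zeros(A.shape[1])
        x[idx] = value
        x[keep] = x_rest
        rank = np.linalg.matrix_rank(A[:, keep]) + 1
    else:
        x, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)

    residuals = system.A @ x - system.rhs
    shift = np.array([1.0 if kind == "a" else -1.0
                      for kind, _ in system.unknowns])
    shift_in_null = bool(np.allclose(system.A @ shift, 0))
    n_null = A.shape[1] - np.linalg.matrix_rank(A)
    null_basis = None
    if n_null > (1 if shift_in_null else 0):
        _, s, vt = np.linalg.svd(A)
        null_basis = vt[np.sum(s > s.max() * 1e-10):].T
    aff = {m: x[i] for i, (kind, m) in enumerate(system.unknowns) if kind == "a"}
    eff = {m: x[i] for i, (kind, m) in enumerate(system.unknowns) if kind == "e"}
    return DelaySolution(
        afferent=pd.Series(aff), efferent=pd.Series(eff),
        residuals=residuals, rank=int(rank),
        shift_indeterminate=shift_in_null, null_space=null_basis)


def regress_vs_innervation_length(delays: pd.Series, lengths: pd.Series):
    """Line fit of per-muscle delay (ms) against innervation length (m).

    Returns (slope_ms_per_m, intercept_ms, R, velocity_m_per_s) where the
    conduction velocity is the reciprocal of the slope after ms -> s
    conversion.  Requires at least 3 muscles with both values and
    non-degenerate lengths.
    """
    common = delays.index.intersection(lengths.index)
    d = delays.loc[common].to_numpy(dtype=float)
    ln = lengths.loc[common].to_numpy(dtype=float)
    ok = ~(np.isnan(d) | np.isnan(ln))
    d, ln = d[ok], ln[ok]
    if len(d) < 3:
        raise ValueError("need at least 3 muscles with delay and length")
    if np.ptp(ln) == 0:
        raise ValueError("innervation lengths are degenerate (constant)")
    slope, intercept = np.polyfit(ln, d, 1)
    R = float(np.corrcoef(ln, d)[0, 1])
    velocity = 1.0 / (slope / 1000.0)  # ms/m -> s/m, then invert
    return float(slope), float(intercept), R, float(velocity)


def extrapolate_missing_muscle(
    afferent_fit: tuple[float, float],
    efferent_fit: tuple[float, float],
    length_m: float,
    central_means: tuple[float, float] | None = None,
    excitatory: bool | None = None,
):
    """Delays for a muscle absent from every measurement, from its nerve length.

    ``afferent_fit``/``efferent_fit`` are (slope_ms_per_m, intercept_ms)
    regression lines; the central delay, if requested, is the excitatory or
    inhibitory mean supplied in ``central_means``.
    Returns (afferent_ms, efferent_ms, central_ms).
    """
    a = afferent_fit[0] * length_m + afferent_fit[1]
    e = efferent_fit[0] * length_m + efferent_fit[1]
    c = np.nan
    if central_means is not None and excitatory is not None:
        c = central_means[0] if excitatory else central_means[1]
    return float(a), float(e), float(c)
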