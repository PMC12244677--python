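"""Minimal labeled MIMO state-space toolkit.

A thin wrapper around (A, B, C, D) numpy matrices with named input/output
channels, plus the handful of operations the model needs: time response to
piecewise-constant inputs (exact zero-order-hold discretization), frequency
response, pole extraction, and Padé approximation of transport delays.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy import linalg, signal

__all__ = ["LinearSystem", "pade_delay"]


@dataclass(frozen=True)
class LinearSystem:
    """Continuous-time LTI system ``xdot = Ax + Bu, y = Cx + Du``."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    input_labels: tuple[str, ...] = ()
    output_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.B.shape[0] != n or self.C.shape[1] != n:
            raise ValueError("B/C dimensions inconsistent with A")
        if self.D.shape != (self.C.shape[0], self.B.shape[1]):
            raise ValueError("D dimensions inconsistent with B/C")
        object.__setattr__(self, "input_labels",
                           tuple(self.input_labels) or tuple(
                               f"u{i}" for i in range(self.B.shape[1])))
        object.__setattr__(self, "output_labels",
                           tuple(self.output_labels) or tuple(
                               f"y{i}" for i in range(self.C.shape[0])))
        if len(self.input_labels) != self.B.shape[1]:
            raise ValueError("input label count mismatch")
        if len(self.output_labels) != self.C.shape[0]:
            raise ValueError("output label count mismatch")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    def poles(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    def is_stable(self, margin: float = 0.0) -> bool:
        if self.n_states == 0:
            return True
        return bool(np.max(self.poles().real) < -margin)

    def input_index(self, label: str) -> int:
        return self.input_labels.index(label)

    def output_index(self, label: str) -> int:
        return self.output_labels.index(label)

    def subsystem(self, inputs=None, outputs=None) -> "LinearSystem":
        """Select input/output channels by label."""
        in_idx = ([self.input_index(l) for l in inputs]
                  if inputs is not None else list(range(self.n_inputs)))
        out_idx = ([self.output_index(l) for l in outputs]
                   if outputs is not None else list(range(self.n_outputs)))
        return LinearSystem(
            self.A, self.B[:, in_idx], self.C[out_idx, :],
            self.D[np.ix_(out_idx, in_idx)],
            tuple(self.input_labels[i] for i in in_idx),
            tuple(self.output_labels[i] for i in out_idx))

    def dc_gain(self) -> np.ndarray:
        """Steady-state gain -C A^{-1} B + D (requires invertible A)."""
        if self.n_states == 0:
            return self.D.copy()
        return self.D - self.C @ np.linalg.solve(self.A, self.B)

    def frequency_response(self, omega: np.ndarray) -> np.ndarray:
        """Transfer matrix H(jw), shape (len(omega), n_outputs, n_inputs)."""
        out = np.empty((len(omega), self.n_outputs, self.n_inputs),
                       dtype=complex)
        eye = np.eye(self.n_states)
        for i, w in enumerate(np.asarray(omega, dtype=float)):
            sol = np.linalg.solve(1j * w * eye - self.A, self.B)
            out[i] = self.C @ sol + self.D
        return out

    def step_response(self, input_label: str, t: np.ndarray,
                      magnitude: float = 1.0) -> np.ndarray:
        """Response of all outputs to a step on one input channel."""
        u = np.zeros((len(t), self.n_inputs))
        u[:, self.input_index(input_label)] = magnitude
        return self.simulate(u, t)

    def simulate(self, u: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Response to a piecewise-constant input sampled on ``t``.

        Uses exact zero-order-hold discretization, so step inputs are
        integrated without truncation error at the sample points.
        """
        t = np.asarray(t, dtype=float)
        dt = t[1] - t[0]
        if not np.allclose(np.diff(t), dt):
            raise ValueError("time grid must be uniform")
        Ad, Bd, *_ = signal.cont2discrete(
            (self.A, self.B, self.C, self.D), dt, method="zoh")
        x = np.zeros(self.n_states)
        y = np.empty((len(t), self.n_outputs))
        for i in range(len(t)):
            y[i] = self.C @ x + self.D @ u[i]
            x = Ad @ x + Bd @ u[i]
        return y


def _block_diag_systems(systems) -> LinearSystem:
    A = linalg.block_diag(*[s.A for s in systems])
    B = linalg.block_diag(*[s.B for s in systems])
    C = linalg.block_diag(*[s.C for s in systems])
    D = linalg.block_diag(*[s.D for s in systems])
    ins = tuple(l for s in systems for l in s.input_labels)
    outs = tuple(l for s in systems for l in s.output_labels)
    return LinearSystem(A, B, C, D, ins, outs)


def pade_delay(delay: float, order: int = 3, label: str = "w") -> LinearSystem:
    """SISO Padé [order/order] approximation of a transport delay (s).

    The approximation is all-pass (|H(jw)| = 1 everywhere) with exact
    unity DC gain, adding ``order`` states.  Zero delay returns a
    zero-state identity.
    """
    if delay < 0:
        raise ValueError("delay must be nonnegative")
    if order < 1:
        raise ValueError("order must be >= 1")
    if delay == 0:
        return LinearSystem(np.zeros((0, 0)), np.zeros((0, 1)),
                            np.zeros((1, 0)), np.eye(1),
                            (label + ":in",), (label + ":out",))
    n = order
    # e^{-sT} ~ num(s)/den(s), den_k = (2n-k)! n! / ((2n)! k! (n-k)!) T^k s^k
    coef = [factorial(2 * n - k) * factorial(n)
            / (factorial(2 * n) * factorial(k) * factorial(n - k))
            for k in range(n + 1)]
    den = np.array([c * delay**k for k, c in enumerate(coef)])[::-1]
    num = np.array([c * (-delay)**k for k, c in enumerate(coef)])[::-1]
    A, B, C, D = signal.tf2ss(num, den)
    return LinearSystem(A, B, C, D, (label + ":in",), (label + ":out",))


def pade_bank(delays, order: int = 3, labels=None) -> LinearSystem:
    """Diagonal bank of independent Padé delay blocks, one per channel."""
    labels = labels or [f"ch{i}" for i in range(len(delays))]
    return _block_diag_systems(
        [pade_delay(d, order, label=l) for d, l in zip(delays, labels)])
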