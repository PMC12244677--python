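"""Open-loop forward path: neural drive -> force -> torque -> motion.

Three cascaded linear submodels over 15 muscles and 7 DOF:

* excitation-contraction dynamics — per muscle, two first-order lags with
  time constants T1 (excitation) and T2 (contraction) and unity DC gain,
  scaled by the maximum contractile force C_i, so a sustained drive of
  1 MVC produces the force C_i at steady state (2 states per muscle);
* musculoskeletal geometry — joint torque tau = M f, with M the 7x15
  moment-arm matrix (transpose of the muscle-to-joint Jacobian);
* joint impedance — I qddot + D qdot + K q = tau + tau_ext, with coupled
  symmetric inertia, damping and stiffness matrices (2 states per DOF).

Muscle elongation follows the geometry in reverse: dlambda = -M^T q, so a
rotation in the direction of a muscle's moment arm shortens that muscle.
The open-loop system therefore has 44 states; its poles are the 30 real
muscle-lag poles and the 14 eigenmodes of the impedance pencil (the joint
block does not feed back into the muscle block without reflexes).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .muscles import DOF_7, MUSCLES
from .statespace import LinearSystem
from .tables import ForwardPathParams

__all__ = ["build_muscle_dynamics", "build_impedance", "assemble_forward_path"]


def build_muscle_dynamics(T1: np.ndarray, T2: np.ndarray, C: np.ndarray,
                          labels=MUSCLES.plant_15) -> LinearSystem:
    """Per-muscle activation/contraction dynamics, u (MVC) -> f (N).

    f_i(s)/u_i(s) = C_i / ((T1_i s + 1)(T2_i s + 1)); all poles real.
    """
    T1, T2, C = (np.asarray(v, dtype=float) for v in (T1, T2, C))
    if (T1 <= 0).any() or (T2 <= 0).any() or (C <= 0).any():
        raise ValueError("T1, T2, C must be strictly positive")
    n = len(T1)
    A = np.zeros((2 * n, 2 * n))
    B = np.zeros((2 * n, n))
    Cmat = np.zeros((n, 2 * n))
    for i in range(n):
        x1, x2 = 2 * i, 2 * i + 1
        A[x1, x1] = -1.0 / T1[i]
        A[x2, x1] = 1.0 / T2[i]
        A[x2, x2] = -1.0 / T2[i]
        B[x1, i] = 1.0 / T1[i]
        Cmat[i, x2] = C[i]
    return LinearSystem(A, B, Cmat, np.zeros((n, n)),
                        tuple(f"u:{m}" for m in labels),
                        tuple(f"f:{m}" for m in labels))


def build_impedance(I: np.ndarray, D: np.ndarray, K: np.ndarray,
                    labels=DOF_7) -> LinearSystem:
    """Joint impedance dynamics, total torque (N m) -> joint angles (rad).

    Realizes I qddot + D qdot + K q = tau with states (q, qdot); outputs
    are q and qdot.
    """
    m = I.shape[0]
    if np.linalg.matrix_rank(I) < m:
        raise ValueError("inertia matrix is singular")
    Iinv = np.linalg.inv(I)
    A = np.block([[np.zeros((m, m)), np.eye(m)],
                  [-Iinv @ K, -Iinv @ D]])
    B = np.vstack([np.zeros((m, m)), Iinv])
    Cmat = np.eye(2 * m)
    return LinearSystem(A, B, Cmat, np.zeros((2 * m, m)),
                        tuple(f"tau:{d}" for d in labels),
                        tuple(f"q:{d}" for d in labels)
                        + tuple(f"qdot:{d}" for d in labels))


def assemble_forward_path(params: ForwardPathParams) -> LinearSystem:
    """The 44-state open-loop plant.

    Inputs: ``uCNS:<muscle>`` (15, MVC) and ``tau_ext:<DOF>`` (7, N m).
    Outputs: ``q:<DOF>`` (rad), ``f:<muscle>`` (N), ``u:<muscle>`` (MVC,
    the activity entering the muscle dynamics — equal to uCNS in open
    loop), ``dlam:<muscle>`` and ``dlamdot:<muscle>`` (muscle elongation,
    m, and its rate).
    """
    muscles = build_muscle_dynamics(params.T1, params.T2, params.C,
                                    params.muscle_labels)
    joints = build_impedance(params.I, params.D, params.K, params.dof_labels)
    n_m, n_d = len(params.muscle_labels), len(params.dof_labels)
    nm_states, nd_states = muscles.n_states, joints.n_states

    # states [muscle; joint]; joint block driven by tau = M f + tau_ext
    A = linalg.block_diag(muscles.A, joints.A)
    A[nm_states:, :nm_states] = joints.B @ params.M @ muscles.C
    B = np.zeros((nm_states + nd_states, n_m + n_d))
    B[:nm_states, :n_m] = muscles.B
    B[nm_states:, n_m:] = joints.B

    q_rows = joints.C[:n_d, :]       # q part of joint outputs
    qdot_rows = joints.C[n_d:, :]
    C = np.zeros((n_d + 4 * n_m, nm_states + nd_states))
    D = np.zeros((n_d + 4 * n_m, n_m + n_d))
    C[:n_d, nm_states:] = q_rows                       # q
    C[n_d:n_d + n_m, :nm_states] = muscles.C           # f
    D[n_d + n_m:n_d + 2 * n_m, :n_m] = np.eye(n_m)     # u = uCNS (open loop)
    C[n_d + 2 * n_m:n_d + 3 * n_m, nm_states:] = -params.M.T @ q_rows     # dlam
    C[n_d + 3 * n_m:, nm_states:] = -params.M.T @ qdot_rows               # dlamdot

    inputs = tuple(f"uCNS:{m}" for m in params.muscle_labels) + tuple(
        f"tau_ext:{d}" for d in params.dof_labels)
    outputs = (tuple(f"q:{d}" for d in params.dof_labels)
               + tuple(f"f:{m}" for m in params.muscle_labels)
               + tuple(f"u:{m}" for m in params.muscle_labels)
               + tuple(f"dlam:{m}" for m in params.muscle_labels)
               + tuple(f"dlamdot:{m}" for m in params.muscle_labels))
    return LinearSystem(A, B, C, D, inputs, outputs)
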