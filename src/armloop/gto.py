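"""Homonymous Golgi-tendon-organ (GTO) force feedback.

The ensemble activity of a muscle's GTOs is modeled as linear negative
force feedback with gain k / C_i, inversely proportional to the muscle's
maximum contractile force C_i.  Consequently the transformation from
neural drive to GTO output is independent of C (the forward path carries a
factor C_i that the feedback gain cancels), consistent with GTOs being
activated by a similar number of muscle fibers in every muscle.  Stability
of the muscle/GTO loop bounds k to (0, 2.7); the default k = 1.27 trades
bandwidth against resonance oscillation.

Only homonymous force feedback is modeled — there are no reliable
heteronymous GTO gain measurements for the human upper limb — so the GTO
loop operator is diagonal.
"""

from __future__ import annotations

import numpy as np

from .tables import K_RANGE

__all__ = ["K_DEFAULT", "compute_gto_gains", "gto_loop_block"]

K_DEFAULT = 1.27


def compute_gto_gains(C: np.ndarray, k: float = K_DEFAULT, *,
                      allow_out_of_range: bool = False) -> np.ndarray:
    """Per-muscle GTO gains k / C_i (MVC/N).

    ``C`` is the vector of maximum muscle forces in newtons.  ``k`` must
    lie in the stable open interval (0, 2.7) unless explicitly overridden
    (k = 0 switches force feedback off and is always allowed).
    """
    C = np.asarray(C, dtype=float)
    if (C <= 0).any():
        raise ValueError("maximum muscle forces must be strictly positive")
    if k != 0 and not allow_out_of_range and not (K_RANGE[0] < k < K_RANGE[1]):
        raise ValueError(f"k={k} outside stable range {K_RANGE}; "
                         "pass allow_out_of_range=True to override")
    return k / C


def gto_loop_block(gains: np.ndarray) -> np.ndarray:
    """Diagonal feedback operator mapping muscle force f to activation.

    The returned matrix applies at the summing junction with negative sign
    (force feedback opposes drive); off-diagonal (heteronymous) coupling is
    structurally zero.
    """
    gains = np.asarray(gains, dtype=float)
    if gains.ndim != 1:
        raise ValueError("gains must be a per-muscle vector")
    return np.diag(gains)
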