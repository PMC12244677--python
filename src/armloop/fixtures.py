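"""Deterministic synthetic parameter and data generators.

Three kinds of stand-ins live here, each labelled synthetic:

* :func:`generate_fixture` — forward-path parameters (moment arms and
  joint impedance with anatomically plausible structure and magnitudes,
  muscle time constants) for the 15-muscle / 7-DOF plant.  The published
  model's numeric forward-path tables are supplementary material not
  packaged here; the fixture reproduces their *structure* (coupled
  symmetric positive-definite impedance, proximal-distal moment-arm
  blocks, all impedance modes underdamped) so structural and scaling
  properties of the closed loop can be exercised.  Maximum muscle forces
  are the packaged published values.
* :func:`reconstruct_precursor_observations` — a per-study reflex
  observation set (PSTH counts, EMG-averaging terms, proximal
  nerve-stimulation rows, within-method repeats, seven method groups with
  a two-stage scaling chain) constructed so that the estimation pipeline
  reproduces the packaged gain matrix exactly.
* :func:`synthetic_roundtrip_table` / :func:`synthetic_conduction_limb` —
  round-trip delay matrices consistent with the packaged per-muscle
  delays, and an idealized limb whose delays follow exact conduction
  velocities, for solver validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .muscles import CANONICAL_13, DELAY_11, DOF_7, MUSCLES
from .tables import DelayTables, ForwardPathParams, GainMatrix, expand_to_plant

__all__ = [
    "FixtureSpec", "generate_fixture", "reconstruct_precursor_observations",
    "synthetic_roundtrip_table", "synthetic_conduction_limb",
    "synthetic_gain_matrix", "synthetic_delay_tables",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Configuration of the synthetic plant-parameter generator."""

    seed: int = 0
    jitter: float = 0.05          # relative spread applied to nominal values
    damping_ratio: float = 0.3    # uniform modal damping of the impedance
    gain_density: float = 0.45    # fraction of non-missing heteronymous gains

    def __post_init__(self) -> None:
        if not 0 < self.damping_ratio < 1:
            raise ValueError("damping_ratio must lie in (0, 1) for "
                             "underdamped impedance modes")
        if not 0 <= self.gain_density <= 1:
            raise ValueError("gain_density must lie in [0, 1]")


# nominal moment arms (m): muscle -> {DOF: arm}; signs follow the convention
# that positive rotation in a DOF shortens muscles with positive arms there
_MOMENT_ARMS: dict[str, dict[str, float]] = {
    "Delt Ant": {"SFE": 0.05, "SAA": 0.02, "SIER": 0.01},
    "Delt Lat": {"SAA": 0.05},
    "Delt Post": {"SFE": -0.05, "SAA": 0.02, "SIER": -0.01},
    "Pec": {"SFE": 0.04, "SAA": -0.05, "SIER": 0.02},
    "Bi Long": {"SFE": 0.02, "EFE": 0.035, "FPS": -0.01},
    "Bi Short": {"EFE": 0.035, "FPS": -0.01},
    "Tri Long": {"SFE": -0.02, "EFE": -0.025},
    "Tri Lat": {"EFE": -0.025},
    "Bra": {"EFE": 0.03},
    "Brd": {"EFE": 0.05, "FPS": -0.005},
    "PT": {"EFE": 0.01, "FPS": 0.02},
    "ECR": {"WFE": -0.015, "WRUD": 0.01},
    "ECU": {"WFE": -0.02, "WRUD": -0.015},
    "FCR": {"WFE": 0.015, "WRUD": 0.008},
    "FCU": {"WFE": 0.02, "WRUD": -0.012},
}

# nominal principal impedance values, proximal -> distal
_I_DIAG = np.array([0.35, 0.35, 0.02, 0.08, 0.004, 0.004, 0.001])   # kg m^2
_K_DIAG = np.array([12.0, 12.0, 6.0, 4.0, 2.5, 1.8, 1.4])           # N m/rad


def _coupled_spd(diag: np.ndarray, rng: np.random.Generator,
                 coupling: float) -> np.ndarray:
    """SPD matrix with the given principal values and random coupling."""
    n = len(diag)
    skew = rng.uniform(-coupling, coupling, size=(n, n))
    skew = skew - skew.T
    rot = linalg.expm(skew)
    return rot @ np.diag(diag) @ rot.T


def generate_fixture(spec: FixtureSpec = FixtureSpec(),
                     max_forces: pd.Series | None = None) -> ForwardPathParams:
    """Deterministic synthetic forward-path parameters.

    ``max_forces`` (canonical 13-muscle index, N) defaults to the packaged
    published values; grouped muscles split their force equally between
    heads.  The impedance matrices are coupled SPD with uniform modal
    damping ratio, so every joint mode is underdamped (14 complex poles)
    and the open-loop system is stable by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(MUSCLES.plant_15)

    if max_forces is None:
        from .datasets import muscle_parameters
        max_forces = muscle_parameters()["max_force_N"]
    C = expand_to_plant(max_forces, mode="split").to_numpy(dtype=float)

    def jit(nominal):
        return nominal * (1.0 + spec.jitter * rng.uniform(-1, 1, size=np.shape(nominal)))

    T1 = jit(np.full(n, 0.030))
    T2 = jit(np.full(n, 0.045))
    M = np.zeros((len(DOF_7), n))
    for j, muscle in enumerate(MUSCLES.plant_15):
        for dof, arm in _MOMENT_ARMS[muscle].items():
            M[DOF_7.index(dof), j] = jit(arm)

    I = _coupled_spd(jit(_I_DIAG), rng, coupling=0.1)
    K = _coupled_spd(jit(_K_DIAG), rng, coupling=0.1)
    # uniform modal damping: D = 2 zeta I^{1/2} (I^{-1/2} K I^{-1/2})^{1/2} I^{1/2}
    I_half = linalg.sqrtm(I).real
    I_half_inv = np.linalg.inv(I_half)
    S = linalg.sqrtm(I_half_inv @ K @ I_half_inv).real
    D = 2.0 * spec.damping_ratio * I_half @ S @ I_half
    D = (D + D.T) / 2
    return ForwardPathParams(T1=T1, T2=T2, C=C, M=M, I=I, D=D, K=K)


_PROXIMAL = ("Delt Ant", "Delt Lat", "Delt Post", "Pec")
_DISTAL_TARGETS = ("Brd", "PT", "ECR", "ECU", "FCR", "FCU")


def synthetic_gain_matrix(spec: FixtureSpec = FixtureSpec()) -> GainMatrix:
    """Synthetic relative gain matrix with the published qualitative structure.

    Homonymous gains dominate their row, magnitudes grow proximal to
    distal, and the proximal-source to distal-target block is empty (no
    trans-joint proximal-distal connections).
    """
    rng = np.random.default_rng(spec.seed + 1)
    labels = list(CANONICAL_13)
    values = pd.DataFrame(np.nan, index=labels, columns=labels)
    scale = np.linspace(0.3, 2.0, len(labels))   # proximal -> distal growth
    for i, src in enumerate(labels):
        values.loc[src, src] = scale[i] * rng.uniform(0.8, 1.2)
        for j, tgt in enumerate(labels):
            if src == tgt:
                continue
            if src in _PROXIMAL and tgt in _DISTAL_TARGETS:
                continue  # structurally empty block
            if rng.uniform() < spec.gain_density:
                mag = 0.5 * min(scale[i], scale[j]) * rng.uniform(0.1, 0.9)
                values.loc[src, tgt] = mag * rng.choice([-1.0, 1.0])
    return GainMatrix(values)


def synthetic_delay_tables(spec: FixtureSpec = FixtureSpec()) -> DelayTables:
    """Synthetic per-muscle delays growing proximal to distal (ms)."""
    rng = np.random.default_rng(spec.seed + 2)
    base = np.linspace(0.0, 1.0, len(DELAY_11))
    aff = pd.Series(4.0 + 11.0 * base + rng.uniform(-0.5, 0.5, len(DELAY_11)),
                    index=list(DELAY_11))
    eff = pd.Series(4.0 + 15.0 * base + rng.uniform(-0.5, 0.5, len(DELAY_11)),
                    index=list(DELAY_11))
    return DelayTables(afferent=aff, efferent=eff)


def synthetic_roundtrip_table(delays: DelayTables,
                              central: pd.DataFrame,
                              pairs) -> pd.DataFrame:
    """Round-trip delays T_ij = a_i + c_ij + e_j over a measurement pattern.

    Synthetic: reconstructs the matrix of measured round-trip delays from
    solved per-muscle delays and a central-delay matrix, over the given
    (source, target) pairs.
    """
    out = pd.DataFrame(np.nan, index=list(DELAY_11), columns=list(DELAY_11))
    for s, t in pairs:
        c = central.loc[s, t]
        if np.isnan(c):
            raise ValueError(f"central delay unavailable for ({s}, {t})")
        out.loc[s, t] = delays.afferent[s] + c + delays.efferent[t]
    return out


def default_measurement_pattern(ecd: pd.DataFrame, G: GainMatrix,
                                homonymous=("Bi", "Tri", "ECR", "ECU",
                                            "FCR", "FCU")) -> list:
    """Measured-pair pattern for the synthetic round-trip table.

    All pairs with a measured excess central delay, a subset of homonymous
    pairs, and every heteronymous pair whose central delay can be imputed
    from a nonzero gain sign.  Bra never appears (no measurements exist
    with Bra as source or target).
    """
    from .spindle import collapse_deltoid
    Gc = collapse_deltoid(G)
    pairs = [(s, t) for s in DELAY_11 for t in DELAY_11
             if not np.isnan(ecd.loc[s, t])]
    pairs += [(m, m) for m in homonymous]
    for s in DELAY_11:
        for t in DELAY_11:
            if s == t or (s, t) in pairs or s == "Bra" or t == "Bra":
                continue
            if Gc.is_present(s, t) and Gc.gain(s, t) != 0:
                pairs.append((s, t))
    return pairs


def synthetic_conduction_limb(lengths: pd.Series | None = None,
                              afferent_velocity: float = 56.8,
                              efferent_velocity: float = 29.1):
    """Idealized limb whose delays follow exact conduction velocities.

    Returns (lengths_m, afferent_ms, efferent_ms) with delay = length /
    velocity exactly, for validating the delay-versus-length regression
    (the afferent/efferent velocity ratio is 56.8/29.1 = 1.95 by
    construction).
    """
    if lengths is None:
        lengths = pd.Series(np.linspace(0.15, 0.95, len(DELAY_11)),
                            index=list(DELAY_11))
    aff = 1000.0 * lengths / afferent_velocity
    eff = 1000.0 * lengths / efferent_velocity
    return lengths, aff, eff


def synthetic_innervation_lengths(delays: DelayTables,
                                  afferent_velocity: float = 56.8,
                                  efferent_velocity: float = 29.1) -> pd.Series:
    """One length per muscle jointly consistent with both delay vectors.

    Least-squares compromise: minimizes the squared mismatch of the
    packaged afferent and efferent delays against length/velocity for the
    two stated conduction velocities.
    """
    va, ve = afferent_velocity, efferent_velocity
    a = delays.afferent / 1000.0   # s
    e = delays.efferent / 1000.0
    L = (a / va + e / ve) / (1.0 / va**2 + 1.0 / ve**2)
    return L.rename("length_m")


# ---------------------------------------------------------------------------
# precursor observation reconstruction

_PSTH_METHODS = {"psth_nerve": (1.0, 1000), "psth_tap": (2.0, 2000),
                 "psth_muscle": (1.25, 10000)}
_EMG_METHODS = {"emga_nerve": 0.5, "emga_tap": 4.0, "emga_muscle": 0.2,
                "emga_vib": 2.5}
#: method -> the table it shares cells with (reference scaling chain)
_CHAIN_PARENT = {"psth_tap": "psth_nerve", "psth_muscle": "psth_tap",
                 "emga_nerve": "psth_nerve", "emga_tap": "psth_tap",
                 "emga_muscle": "psth_nerve", "emga_vib": "psth_tap"}
_EMG_B, _EMG_S = 0.05, 0.9

# cells reconstructed through proximal radial / musculocutaneous nerve rows
_NERVE_SPLIT_EQUAL = [("ECR+ECU", t) for t in ("Delt Post", "Bi", "Tri")]
_NERVE_SPLIT_KNOWN = [("Bi+Bra", "Tri"), ("Bi+Bra", "Bi")]
_NERVE_COVERED = {("ECR", "Delt Post"), ("ECU", "Delt Post"),
                  ("ECR", "Bi"), ("ECU", "Bi"), ("ECR", "Tri"),
                  ("ECU", "Tri"), ("Bra", "Tri"), ("Bra", "Bi")}
_NERVE_KNOWN_SINGLES = {("Bi", "Tri"), ("Bi", "Bi")}
#: cells observed twice in the reference method (exercise within-method averaging)
_DUPLICATED = {("Tri", "Delt Ant"), ("FCR", "Bi")}


def _psth_row(method, source, target, value, n_tot):
    d = round(value * n_tot)
    if abs(d - value * n_tot) > 1e-9:
        raise ValueError(f"cannot represent {value} with n_tot={n_tot}")
    n_plus, n_minus = (d, 0) if d >= 0 else (0, -d)
    return dict(method=method, source=source, target=target,
                n_plus=n_plus, n_minus=n_minus, n_tot=n_tot,
                p=np.nan, b=np.nan, s=np.nan)


def _emg_row(method, source, target, value):
    p = value * _EMG_S / _EMG_B
    return dict(method=method, source=source, target=target,
                n_plus=np.nan, n_minus=np.nan, n_tot=np.nan,
                p=p, b=_EMG_B, s=_EMG_S)


def reconstruct_precursor_observations(G: GainMatrix) -> pd.DataFrame:
    """Synthetic observation set that compiles exactly back to ``G``.

    Cells are dealt across seven method groups (three PSTH-family with
    bounded strengths and integer motor-unit counts, four EMG-A-family
    with p/b/s terms), each group carrying its own arbitrary unit scale.
    Shared cells implement the two-stage scaling chain (everything reaches
    the ``psth_nerve`` reference, possibly via ``psth_tap``); duplicated
    and nerve-stimulation rows exercise within-method averaging and
    stimulus splitting.
    """
    rows: list[dict] = []
    methods = list(_PSTH_METHODS) + list(_EMG_METHODS)

    def emit(method, source, target, red_value, duplicate=False):
        if method in _PSTH_METHODS:
            slope, n_tot = _PSTH_METHODS[method]
            value = red_value / slope
            if abs(value) > 1:
                raise ValueError(
                    f"PSTH strength {value} out of range for {source}->{target}")
            if duplicate:
                rows.append(_psth_row(method, source, target, value + 0.01, n_tot))
                rows.append(_psth_row(method, source, target, value - 0.01, n_tot))
            else:
                rows.append(_psth_row(method, source, target, value, n_tot))
        else:
            value = red_value / _EMG_METHODS[method]
            rows.append(_emg_row(method, source, target, value))

    present = [(s, t) for s in G.labels for t in G.labels if G.is_present(s, t)]

    # nerve-stimulation rows in the reference method
    Gv = G.values
    for nerve, tgt in _NERVE_SPLIT_EQUAL:
        muscles = nerve.split("+")
        total = float(sum(Gv.loc[m, tgt] for m in muscles))
        rows.append(_psth_row("psth_nerve", nerve, tgt, total, 1000))
    for nerve, tgt in _NERVE_SPLIT_KNOWN:
        muscles = nerve.split("+")
        total = float(sum(Gv.loc[m, tgt] for m in muscles))
        rows.append(_psth_row("psth_nerve", nerve, tgt, total, 1000))
    for src, tgt in sorted(_NERVE_KNOWN_SINGLES):
        emit("psth_nerve", src, tgt, float(Gv.loc[src, tgt]))

    # deal the remaining cells across methods, respecting PSTH bounds
    k = 0
    assignment: dict[str, list] = {m: [] for m in methods}
    for src, tgt in present:
        if (src, tgt) in _NERVE_COVERED or (src, tgt) in _NERVE_KNOWN_SINGLES:
            continue
        red_value = float(Gv.loc[src, tgt])
        for offset in range(len(methods)):
            method = methods[(k + offset) % len(methods)]
            if method in _PSTH_METHODS:
                slope = _PSTH_METHODS[method][0]
                if abs(red_value / slope) > 1:
                    continue
            assignment[method].append((src, tgt, red_value))
            break
        k += 1

    for method in methods:
        for src, tgt, red_value in assignment[method]:
            emit(method, src, tgt, red_value,
                 duplicate=(method == "psth_nerve" and (src, tgt) in _DUPLICATED))

    # shared cells: replicate each method's first cells into its chain parent
    for method, parent in _CHAIN_PARENT.items():
        own = assignment[method]
        parent_cells = {(s, t) for s, t, _ in assignment[parent]}
        shared = 0
        for src, tgt, red_value in own:
            if shared >= 3:
                break
            if (src, tgt) in parent_cells or (src, tgt) in _NERVE_COVERED:
                shared += 1
                continue
            if parent in _PSTH_METHODS:
                slope = _PSTH_METHODS[parent][0]
                if abs(red_value / slope) > 1:
                    continue
            emit(parent, src, tgt, red_value)
            shared += 1
        if shared == 0:
            raise ValueError(f"method {method} could not share any cell "
                             f"with {parent}")
    return pd.DataFrame(rows)
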