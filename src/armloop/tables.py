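"""Typed parameter tables with explicit missing-value masks, and their I/O.

The central storage convention for gain-like matrices is *rows = source
muscle, columns = target muscle*.  Control-theory formulas index the other
way round (the entry in row i, column j of the feedback matrices acts from
source j on target i); :meth:`GainMatrix.formula_matrix` performs that
transpose in exactly one place so the convention cannot silently drift.

Missing values are first class: a blank cell in a CSV becomes a masked
entry, never a zero.  Filling missing gains with zero for simulation is an
explicit, named step (:meth:`GainMatrix.filled`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .muscles import CANONICAL_13, DELAY_11, DOF_7, MUSCLES

__all__ = [
    "SchemaError", "GainMatrix", "ForwardPathParams", "FeedbackParams",
    "DelayTables", "SignalFrame", "load_gain_matrix", "load_delay_matrix",
    "load_muscle_table", "write_report", "expand_to_plant", "R_RANGE",
    "K_RANGE",
]

#: admissible range for the derivative-to-proportional time ratio r (s)
R_RANGE = (0.06, 0.14)
#: admissible open interval for the GTO proportionality constant k (unitless)
K_RANGE = (0.0, 2.7)


class SchemaError(ValueError):
    """A tabular input does not match its declared schema."""


def _read_labeled_csv(path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str)
    if df.columns[0] != index_name:
        raise SchemaError(
            f"{path}: first column must be {index_name!r}, got {df.columns[0]!r}")
    df = df.set_index(index_name)
    return df


def _to_float(df: pd.DataFrame, path) -> pd.DataFrame:
    def conv(val, row, col):
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            return np.nan
        try:
            return float(val)
        except ValueError:
            raise SchemaError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: {val!r}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for row in df.index:
        for col in df.columns:
            out.loc[row, col] = conv(df.loc[row, col], row, col)
    return out


def _check_labels(found, expected, what: str, path) -> None:
    unknown = [m for m in found if m not in expected]
    if unknown:
        raise SchemaError(f"{path}: unknown {what} label(s) {unknown}")
    missing = [m for m in expected if m not in list(found)]
    if missing:
        raise SchemaError(f"{path}: missing {what} label(s) {missing}")


@dataclass(frozen=True)
class GainMatrix:
    """Square relative-gain matrix over a muscle vocabulary, with mask.

    ``values`` is a float DataFrame (rows = source, columns = target) in
    which missing entries are NaN; ``mask`` is the boolean presence matrix.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if list(v.index) != list(v.columns):
            raise SchemaError("gain matrix must have identical row/column labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is present."""
        return self.values.notna()

    @property
    def n_present(self) -> int:
        return int(self.mask.to_numpy().sum())

    @property
    def n_missing(self) -> int:
        return self.values.size - self.n_present

    def gain(self, source: str, target: str) -> float:
        """The relative gain from ``source`` to ``target``.

        Raises ``KeyError`` for unknown muscles and ``ValueError`` for a
        masked (missing) entry — missing is never reported as zero.
        """
        if source not in self.values.index:
            raise KeyError(f"unknown source muscle {source!r}")
        if target not in self.values.columns:
            raise KeyError(f"unknown target muscle {target!r}")
        val = self.values.loc[source, target]
        if np.isnan(val):
            raise ValueError(f"gain {source!r} -> {target!r} is missing")
        return float(val)

    def is_present(self, source: str, target: str) -> bool:
        return bool(self.mask.loc[source, target])

    def filled(self, fill_value: float = 0.0) -> "GainMatrix":
        """Explicitly fill missing entries (e.g., with zero for simulation)."""
        return GainMatrix(self.values.fillna(fill_value))

    def fill_delt_lat(self) -> "GainMatrix":
        """Fill the unidentified Delt Lat homonymous gain.

        The lateral-deltoid homonymous gain was never measured; it is taken
        as the mean of the identified homonymous gains of the other two
        deltoid heads.
        """
        v = self.values.copy()
        if np.isnan(v.loc["Delt Lat", "Delt Lat"]):
            others = [v.loc["Delt Ant", "Delt Ant"], v.loc["Delt Post", "Delt Post"]]
            v.loc["Delt Lat", "Delt Lat"] = float(np.nanmean(others))
        return GainMatrix(v)

    def formula_matrix(self) -> np.ndarray:
        """Matrix with entry (i, j) = gain from source j to target i.

        This is the orientation used in the feedback-law formulas
        (a transpose of the storage layout); missing entries are NaN.
        """
        return self.values.to_numpy().T.copy()

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.values.to_csv(buf, index_label="source", float_format="%.17g")
        return buf.getvalue()

    def equals(self, other: "GainMatrix") -> bool:
        a, b = self.values.to_numpy(), other.values.to_numpy()
        return (list(self.labels) == list(other.labels)
                and np.array_equal(np.isnan(a), np.isnan(b))
                and np.array_equal(a[~np.isnan(a)], b[~np.isnan(b)]))


def load_gain_matrix(path, labels=CANONICAL_13) -> GainMatrix:
    """Load a labeled square gain matrix CSV (blank cell = missing)."""
    df = _read_labeled_csv(path, "source")
    _check_labels(df.index, labels, "muscle", path)
    _check_labels(df.columns, labels, "muscle", path)
    df = _to_float(df, path).loc[list(labels), list(labels)]
    return GainMatrix(df)


def load_delay_matrix(path, labels=DELAY_11) -> pd.DataFrame:
    """Load a labeled square delay matrix CSV (ms, blank = not measured)."""
    df = _read_labeled_csv(path, "source")
    _check_labels(df.index, labels, "muscle", path)
    _check_labels(df.columns, labels, "muscle", path)
    return _to_float(df, path).loc[list(labels), list(labels)]


def load_muscle_table(path) -> pd.DataFrame:
    """Load the per-muscle parameter table (indexed by canonical muscle)."""
    df = _read_labeled_csv(path, "muscle")
    _check_labels(df.index, CANONICAL_13, "muscle", path)
    num = [c for c in df.columns if c != "name"]
    out = df.loc[list(CANONICAL_13)].copy()
    out[num] = _to_float(df[num], path).loc[list(CANONICAL_13)]
    if (out["max_force_N"] <= 0).any():
        bad = out.index[out["max_force_N"] <= 0].tolist()
        raise SchemaError(f"{path}: nonpositive max force for {bad}")
    return out


def _check_spd(mat: np.ndarray, name: str, *, strict: bool, atol=1e-9) -> None:
    if not np.allclose(mat, mat.T, atol=atol):
        raise SchemaError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh((mat + mat.T) / 2)
    if strict and eig.min() <= 0:
        raise SchemaError(f"{name} must be positive definite")
    if not strict and eig.min() < -atol:
        raise SchemaError(f"{name} must be positive semidefinite")


@dataclass(frozen=True)
class ForwardPathParams:
    """Parameters of the open-loop forward path (15 muscles, 7 DOF).

    T1, T2 (s) and C (N) are per-plant-muscle vectors; M (m) is the 7x15
    moment-arm matrix (transpose of the muscle-to-joint Jacobian); I, D, K
    are the 7x7 joint inertia (kg m^2), damping (N m s/rad) and stiffness
    (N m/rad) matrices.
    """

    T1: np.ndarray
    T2: np.ndarray
    C: np.ndarray
    M: np.ndarray
    I: np.ndarray
    D: np.ndarray
    K: np.ndarray
    muscle_labels: tuple[str, ...] = MUSCLES.plant_15
    dof_labels: tuple[str, ...] = DOF_7

    def __post_init__(self) -> None:
        n, m = len(self.muscle_labels), len(self.dof_labels)
        for name in ("T1", "T2", "C"):
            vec = getattr(self, name)
            if vec.shape != (n,):
                raise SchemaError(f"{name} must have shape ({n},)")
            if (vec <= 0).any():
                raise SchemaError(f"{name} must be strictly positive")
        if self.M.shape != (m, n):
            raise SchemaError(f"M must have shape ({m}, {n})")
        _check_spd(self.I, "I", strict=True)
        _check_spd(self.D, "D", strict=False)
        _check_spd(self.K, "K", strict=False)
        for name in ("D", "K"):
            if (np.diag(getattr(self, name)) <= 0).any():
                raise SchemaError(f"{name} must have positive diagonal")

    def scaled(self, **factors: float) -> "ForwardPathParams":
        """Return a copy with named parameters multiplied elementwise."""
        changes = {}
        for name, fac in factors.items():
            if name not in ("T1", "T2", "C", "M", "I", "D", "K"):
                raise KeyError(f"unknown forward-path parameter {name!r}")
            changes[name] = getattr(self, name) * fac
        return replace(self, **changes)


@dataclass(frozen=True)
class FeedbackParams:
    """Spindle and GTO feedback parameters.

    The derivative gains are V = c G and the proportional gains
    L = (c/r) G, elementwise on the present entries of the relative gain
    matrix G.  GTO gains are k / C_i per muscle.  Units: c in MVC s/m,
    r in s, k unitless, GTO gains in MVC/N.
    """

    G: GainMatrix
    c: float
    r: float = 0.1
    k: float = 1.27
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("spindle scaling constant c must be >= 0")
        if not self.allow_out_of_range:
            if not (R_RANGE[0] <= self.r <= R_RANGE[1]):
                raise ValueError(
                    f"r={self.r} outside plausible range {R_RANGE}; "
                    "pass allow_out_of_range=True to override")
            if not (K_RANGE[0] < self.k < K_RANGE[1]):
                raise ValueError(
                    f"k={self.k} outside stable range {K_RANGE}; "
                    "pass allow_out_of_range=True to override")
        if self.r <= 0:
            raise ValueError("r must be positive")

    @property
    def V(self) -> pd.DataFrame:
        """Derivative gain matrix cG (storage orientation, NaN preserved)."""
        return self.c * self.G.values

    @property
    def L(self) -> pd.DataFrame:
        """Proportional gain matrix (c/r)G (storage orientation)."""
        return (self.c / self.r) * self.G.values

    def gto_gains(self, C: np.ndarray) -> np.ndarray:
        """Per-muscle GTO force-feedback gains k / C_i (MVC/N)."""
        from .gto import compute_gto_gains
        return compute_gto_gains(C, self.k,
                                 allow_out_of_range=self.allow_out_of_range)


@dataclass(frozen=True)
class DelayTables:
    """Reflex-delay tables over the 11-muscle (deltoid-collapsed) vocabulary.

    ``roundtrip`` holds measured round-trip delays T_ij; ``ecd`` the measured
    excess-of-central-delay matrix; ``central`` = ecd + 1 ms where measured;
    ``afferent``/``efferent`` the solved per-muscle delays.  All in ms.
    """

    roundtrip: pd.DataFrame | None = None
    ecd: pd.DataFrame | None = None
    afferent: pd.Series | None = None
    efferent: pd.Series | None = None

    def __post_init__(self) -> None:
        for name in ("roundtrip", "ecd"):
            df = getattr(self, name)
            if df is None:
                continue
            if list(df.index) != list(DELAY_11) or list(df.columns) != list(DELAY_11):
                raise SchemaError(f"{name} must be indexed by the 11 delay muscles")
        if self.roundtrip is not None and (self.roundtrip.to_numpy() < 0).any():
            raise SchemaError("round-trip delays must be nonnegative")
        if self.ecd is not None:
            homonymous = np.diag(self.ecd.to_numpy())
            if np.any(homonymous[~np.isnan(homonymous)] != 0):
                raise SchemaError("homonymous excess central delay must be 0 (or blank)")

    @property
    def central(self) -> pd.DataFrame | None:
        """Measured central delays: ecd + 1 ms where ecd is present."""
        if self.ecd is None:
            return None
        return self.ecd + 1.0

    def roundtrip_per_canonical(self) -> pd.Series:
        """Lumped round-trip delay a_i + 1 ms + e_i per canonical muscle (ms).

        The single deltoid delay is assigned to all three heads.
        """
        if self.afferent is None or self.efferent is None:
            raise ValueError("afferent/efferent delays not available")
        out = {}
        for m in CANONICAL_13:
            d = MUSCLES.delay_map[m]
            out[m] = float(self.afferent[d] + 1.0 + self.efferent[d])
        return pd.Series(out)


@dataclass
class SignalFrame:
    """Time-indexed simulation signals on the plant vocabularies.

    Every muscle-indexed signal has one column per plant muscle (15) and
    every joint-indexed signal one column per DOF (7), on a shared time
    grid in seconds.
    """

    time: np.ndarray
    signals: dict[str, np.ndarray] = field(default_factory=dict)

    _WIDTH = {"uCNS": 15, "u": 15, "uMS": 15, "uGTO": 15, "f": 15,
              "dlambda": 15, "ddlambda": 15, "tau": 7, "tau_ext": 7, "q": 7}

    def __post_init__(self) -> None:
        nt = len(self.time)
        for name, arr in self.signals.items():
            width = self._WIDTH.get(name)
            if arr.shape[0] != nt or (width is not None and arr.shape[1] != width):
                raise ValueError(f"signal {name!r} has shape {arr.shape}, "
                                 f"expected ({nt}, {width})")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.signals[name]


def expand_to_plant(values13: pd.Series, mode: str = "replicate") -> pd.Series:
    """Expand a canonical-13 per-muscle vector to the 15-muscle plant.

    ``replicate`` copies a grouped muscle's value to both heads (right for
    intensive quantities such as delays or per-muscle gains); ``split``
    divides the value equally between heads (right for source-role
    contributions whose grouped total must be conserved).
    """
    if mode not in ("replicate", "split"):
        raise ValueError(f"unknown expansion mode {mode!r}")
    out = {}
    for m in CANONICAL_13:
        heads = MUSCLES.heads(m)
        val = values13[m]
        if mode == "split":
            val = val / len(heads)
        for h in heads:
            out[h] = val
    return pd.Series(out).loc[list(MUSCLES.plant_15)]


def expand_gain_to_plant(G: GainMatrix, mode: str = "replicate") -> np.ndarray:
    """Expand a filled 13x13 gain matrix to 15x15 (storage orientation).

    Target-role values are replicated to both heads (each head receives the
    grouped feedback signal).  Source-role values are replicated or split
    according to ``mode``; ``split`` halves each head's contribution so the
    summed feedback from both heads equals the grouped value.
    """
    vals = G.values.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("fill missing gains explicitly before expansion")
    n15 = len(MUSCLES.plant_15)
    out = np.zeros((n15, n15))
    for i, src in enumerate(CANONICAL_13):
        src_heads = MUSCLES.heads(src)
        share = 1.0 / len(src_heads) if mode == "split" else 1.0
        if mode not in ("replicate", "split"):
            raise ValueError(f"unknown expansion mode {mode!r}")
        for j, tgt in enumerate(CANONICAL_13):
            for sh in src_heads:
                for th in MUSCLES.heads(tgt):
                    out[MUSCLES.plant_15.index(sh),
                        MUSCLES.plant_15.index(th)] = vals[i, j] * share
    return out


def write_report(obj, path) -> None:
    """Serialize a domain object to delimited text; round-trips losslessly."""
    path = Path(path)
    if isinstance(obj, GainMatrix):
        path.write_text(obj.to_csv())
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index_label="source", float_format="%.17g")
    elif isinstance(obj, pd.Series):
        obj.to_frame("value").to_csv(path, index_label="muscle",
                                     float_format="%.17g")
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
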