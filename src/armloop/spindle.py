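"""Estimation of relative muscle-spindle feedback gains from reflex studies.

The pipeline turns heterogeneous per-study observations into one unified
relative gain matrix in three steps:

1. *Extraction* — each observation yields a relative connection strength:
   post-stimulus time histogram (PSTH) studies report motor-unit counts and
   give (n+ - n-)/n_tot, bounded in [-1, 1]; EMG-averaging (EMG-A) studies
   report the fractional activity increase p over background b at stimulus
   intensity s and give p*b/s, unbounded.  Stimuli delivered to a nerve
   proximal to several muscles are split between the innervated muscles.
2. *Within-method averaging* — repeated measurements of the same
   source-target cell within one method group are averaged.
3. *Cross-method scaling* — method groups measure in different (arbitrary)
   units; through-origin regressions over shared cells chain every group
   onto a common reference scale, after which cells are averaged across
   methods.

Also provided: the symmetry statistics of the compiled matrix and the
sign-versus-excess-central-delay validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .muscles import CANONICAL_13, MUSCLES
from .tables import GainMatrix

__all__ = [
    "PrecursorObservation", "MethodScale", "psth_gain", "emg_gain",
    "split_nerve_stimulus", "average_within_method", "fit_method_scale",
    "estimate_method_table", "compile_gain_matrix", "symmetry_stats",
    "sign_vs_ecd_validation",
]


@dataclass(frozen=True)
class PrecursorObservation:
    """One reported reflex measurement.

    ``source`` is a muscle, or several muscles joined with ``+`` when a
    nerve innervating them was stimulated proximally.  Exactly one of
    ``psth_counts`` (n_plus, n_minus, n_tot) and ``emg_terms`` (p, b, s)
    must be given, matching the method family.
    """

    method: str
    source: str
    target: str
    psth_counts: tuple[int, int, int] | None = None
    emg_terms: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if (self.psth_counts is None) == (self.emg_terms is None):
            raise ValueError("exactly one of psth_counts / emg_terms required")
        if self.psth_counts is not None:
            n_plus, n_minus, n_tot = self.psth_counts
            if n_tot < 1:
                raise ValueError("n_tot must be >= 1")
            if not 0 <= n_plus + n_minus <= n_tot:
                raise ValueError("need 0 <= n_plus + n_minus <= n_tot")
        else:
            _, b, s = self.emg_terms
            if b <= 0 or s <= 0:
                raise ValueError("background b and stimulus s must be positive")

    @property
    def source_muscles(self) -> tuple[str, ...]:
        return tuple(m.strip() for m in self.source.split("+"))

    def gain(self) -> float:
        if self.psth_counts is not None:
            return psth_gain(self.psth_counts)
        return emg_gain(self.emg_terms)


@dataclass(frozen=True)
class MethodScale:
    """Through-origin regression putting one method on a reference scale."""

    method: str
    reference: str
    slope: float
    n_shared: int
    R: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope):
            raise ValueError("regression slope must be finite")
        if self.n_shared < 1:
            raise ValueError("at least one shared cell required")


def observations_from_frame(df: pd.DataFrame) -> list[PrecursorObservation]:
    """Build observations from a long-format table.

    Expected columns: method, source, target, and either integer
    n_plus/n_minus/n_tot (PSTH family) or float p/b/s (EMG-A family);
    the unused family's columns are blank per row.
    """
    obs = []
    for row in df.itertuples():
        if not pd.isna(row.n_tot):
            obs.append(PrecursorObservation(
                method=row.method, source=row.source, target=row.target,
                psth_counts=(int(row.n_plus), int(row.n_minus), int(row.n_tot))))
        else:
            obs.append(PrecursorObservation(
                method=row.method, source=row.source, target=row.target,
                emg_terms=(float(row.p), float(row.b), float(row.s))))
    return obs


def psth_gain(counts: tuple[int, int, int]) -> float:
    """Relative PSTH connection strength (n+ - n-)/n_tot, in [-1, 1]."""
    n_plus, n_minus, n_tot = counts
    if n_tot == 0:
        raise ZeroDivisionError("n_tot must be nonzero")
    return (n_plus - n_minus) / n_tot


def emg_gain(terms: tuple[float, float, float]) -> float:
    """Relative EMG-A connection strength p*b/s (unbounded)."""
    p, b, s = terms
    if s == 0:
        raise ZeroDivisionError("stimulus intensity s must be nonzero")
    return p * b / s


def split_nerve_stimulus(
    total_gain: float,
    known_components: list[tuple[str, float | None]],
) -> dict[str, float]:
    """Distribute a proximal nerve-stimulation gain among source muscles.

    The observed strength is the sum of the per-muscle connection
    strengths.  Components known from elsewhere are subtracted; the
    remainder is split equally among the unknown components.
    """
    known = {m: g for m, g in known_components if g is not None}
    unknown = [m for m, g in known_components if g is None]
    if len(unknown) > 2:
        import warnings
        warnings.warn(
            f"{len(unknown)} unresolved muscles share one nerve observation; "
            "splitting equally", stacklevel=2)
    remainder = total_gain - sum(known.values())
    out = dict(known)
    if unknown:
        share = remainder / len(unknown)
        for m in unknown:
            out[m] = share
    return out


def average_within_method(observations) -> pd.DataFrame:
    """Mean relative gain per (source, target) cell for one method group.

    Nerve-stimulation observations (multi-muscle sources) are resolved
    first: single-source cell means act as the known components.  Returns a
    long-format frame with columns source, target, gain.
    """
    methods = {o.method for o in observations}
    if len(methods) > 1:
        raise ValueError(f"observations span several methods: {sorted(methods)}")
    singles: dict[tuple[str, str], list[float]] = {}
    for obs in observations:
        if len(obs.source_muscles) == 1:
            singles.setdefault((obs.source, obs.target), []).append(obs.gain())
    single_means = {cell: float(np.mean(g)) for cell, g in singles.items()}

    cells: dict[tuple[str, str], list[float]] = {
        cell: [mean] for cell, mean in single_means.items()}
    for obs in observations:
        muscles = obs.source_muscles
        if len(muscles) == 1:
            continue
        components = [(m, single_means.get((m, obs.target))) for m in muscles]
        for m, g in split_nerve_stimulus(obs.gain(), components).items():
            if (m, obs.target) not in single_means:
                cells.setdefault((m, obs.target), []).append(g)
    rows = [(src, tgt, float(np.mean(gains)))
            for (src, tgt), gains in sorted(cells.items())]
    return pd.DataFrame(rows, columns=["source", "target", "gain"])


def estimate_method_table(observations) -> dict[str, pd.DataFrame]:
    """Group observations by method and average within each method."""
    by_method: dict[str, list] = {}
    for obs in observations:
        by_method.setdefault(obs.method, []).append(obs)
    return {m: average_within_method(v) for m, v in sorted(by_method.items())}


def _as_cell_map(table: pd.DataFrame) -> dict[tuple[str, str], float]:
    return {(r.source, r.target): r.gain for r in table.itertuples()}


def fit_method_scale(a: pd.DataFrame, b_ref: pd.DataFrame,
                     method: str = "", reference: str = "") -> MethodScale:
    """Through-origin regression of the reference table on table ``a``.

    slope = sum(a*ref)/sum(a^2) over shared cells; multiplying ``a`` by the
    slope puts it on the reference scale.
    """
    cells_a, cells_ref = _as_cell_map(a), _as_cell_map(b_ref)
    shared = sorted(set(cells_a) & set(cells_ref))
    if not shared:
        raise ValueError("no shared cells between the two method tables")
    x = np.array([cells_a[c] for c in shared])
    y = np.array([cells_ref[c] for c in shared])
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("shared cells are all zero; slope undefined")
    slope = float(x @ y) / denom
    if len(shared) >= 2 and np.std(x) > 0 and np.std(y) > 0:
        R = float(np.corrcoef(x, y)[0, 1])
    else:
        R = 1.0
    return MethodScale(method=method, reference=reference, slope=slope,
                       n_shared=len(shared), R=R)


def compile_gain_matrix(
    tables: dict[str, pd.DataFrame],
    chain: tuple[str, str],
    labels=CANONICAL_13,
    return_scales: bool = False,
):
    """Rescale all method tables to the reference scale and merge.

    ``chain`` is (intermediate_tag, reference_tag): methods sharing cells
    with the reference are scaled to it directly; the remaining methods are
    scaled to the intermediate first, and the intermediate itself is scaled
    to the reference.  Cells present in several rescaled tables are
    averaged.  Returns a :class:`GainMatrix` over ``labels`` (and the list
    of fitted :class:`MethodScale` when ``return_scales``).
    """
    intermediate, reference = chain
    if reference not in tables:
        raise ValueError(f"reference method {reference!r} not among tables")
    scales: list[MethodScale] = []
    scaled: dict[str, pd.DataFrame] = {reference: tables[reference]}
    if intermediate in tables and intermediate != reference:
        fit = fit_method_scale(tables[intermediate], tables[reference],
                               method=intermediate, reference=reference)
        scales.append(fit)
        t = tables[intermediate].copy()
        t["gain"] *= fit.slope
        scaled[intermediate] = t

    for tag, table in tables.items():
        if tag in (reference, intermediate):
            continue
        cells = set(map(tuple, table[["source", "target"]].to_numpy()))
        ref_cells = set(map(tuple, tables[reference][["source", "target"]].to_numpy()))
        if cells & ref_cells:  # reference preferred when both chains exist
            fit = fit_method_scale(table, tables[reference],
                                   method=tag, reference=reference)
            total_slope = fit.slope
        elif intermediate in scaled and cells & set(
                map(tuple, tables[intermediate][["source", "target"]].to_numpy())):
            fit = fit_method_scale(table, tables[intermediate],
                                   method=tag, reference=intermediate)
            inter_slope = next(s.slope for s in scales if s.method == intermediate)
            total_slope = fit.slope * inter_slope
        else:
            raise ValueError(f"method {tag!r} has no scaling path to {reference!r}")
        scales.append(fit)
        t = table.copy()
        t["gain"] *= total_slope
        scaled[tag] = t

    merged = pd.concat(scaled.values(), ignore_index=True)
    means = merged.groupby(["source", "target"])["gain"].mean()
    values = pd.DataFrame(np.nan, index=list(labels), columns=list(labels))
    for (src, tgt), g in means.items():
        values.loc[src, tgt] = g
    out = GainMatrix(values)
    return (out, scales) if return_scales else out


def symmetry_stats(G: GainMatrix, magnitude_floor: float = 0.01):
    """Asymmetry statistics over bidirectionally-measured muscle pairs.

    Considers unordered heteronymous pairs (i < j) with gains present in
    both directions; returns (n_pairs, pearson_R, n_sign_discordant,
    discordant_pairs).  Discordance requires strictly opposite signs with
    both magnitudes above ``magnitude_floor``: near-zero strengths carry
    no reliable sign (their sign flips between methods), so the floor —
    one unit of the coarsest printed decimal — keeps them sign-neutral,
    as does an exact zero.  R is NaN (signaled) below 3 pairs.
    """
    labels = G.labels
    xs, ys, pairs = [], [], []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            if G.is_present(a, b) and G.is_present(b, a):
                xs.append(G.gain(a, b))
                ys.append(G.gain(b, a))
                pairs.append((a, b))
    discordant = [(a, b) for (a, b), x, y in zip(pairs, xs, ys)
                  if x * y < 0 and min(abs(x), abs(y)) > magnitude_floor]
    if len(pairs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
        R = float(np.corrcoef(xs, ys)[0, 1])
    else:
        R = float("nan")
    return len(pairs), R, len(discordant), discordant


def collapse_deltoid(G: GainMatrix) -> GainMatrix:
    """Collapse the three deltoid heads to a single Delt by cell means.

    Used when crossing the 13-muscle gain matrix with the 11-muscle delay
    tables; a collapsed cell is present if any contributing cell is.
    """
    labels = list(MUSCLES.delay_11)
    values = pd.DataFrame(np.nan, index=labels, columns=labels)
    sums = pd.DataFrame(0.0, index=labels, columns=labels)
    counts = pd.DataFrame(0, index=labels, columns=labels)
    for a in CANONICAL_13:
        for b in CANONICAL_13:
            if G.is_present(a, b):
                da, db = MUSCLES.delay_map[a], MUSCLES.delay_map[b]
                sums.loc[da, db] += G.gain(a, b)
                counts.loc[da, db] += 1
    present = counts > 0
    values[present] = sums[present] / counts[present]
    return GainMatrix(values)


def sign_vs_ecd_validation(G: GainMatrix, ecd: pd.DataFrame,
                           threshold: float = 0.5):
    """Cross-validate gain signs against excess central delay (ECD).

    Excitatory (monosynaptic) connections have ECD near 0 ms; inhibitory
    (interneuron-mediated) connections have ECD of 1-2 ms.  A heteronymous
    pair with both a nonzero gain and a measured ECD is *consistent* when
    gain > 0 and ECD < threshold, or gain < 0 and ECD >= threshold.
    Deltoid heads are collapsed (mean gain).  Returns
    (n_overlap, n_consistent, inconsistent_pairs).
    """
    Gc = collapse_deltoid(G)
    n_overlap = n_consistent = 0
    inconsistent = []
    for src in Gc.labels:
        for tgt in Gc.labels:
            if src == tgt:
                continue
            e = ecd.loc[src, tgt]
            if np.isnan(e) or not Gc.is_present(src, tgt):
                continue
            g = Gc.gain(src, tgt)
            if g == 0:
                continue  # sign-neutral
            n_overlap += 1
            ok = (g > 0 and e < threshold) or (g < 0 and e >= threshold)
            if ok:
                n_consistent += 1
            else:
                inconsistent.append((src, tgt))
    return n_overlap, n_consistent, inconsistent
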