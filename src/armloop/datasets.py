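"""Loaders for the parameter tables packaged with the model.

Three tables are transcriptions of published values: the relative
muscle-spindle gain matrix, the per-muscle parameter table (maximum forces,
printed GTO gains, solved afferent/efferent delays) and the
excess-of-central-delay matrix.  Two further tables are *synthetic*
reconstructions (their filenames say so): the precursor observation set,
built to reproduce the gain matrix exactly through the estimation pipeline,
and the innervation-length side table, built to be jointly consistent with
the packaged delays at physiological conduction velocities.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import units
from .tables import DelayTables, GainMatrix, load_delay_matrix, load_gain_matrix, load_muscle_table

_K_DEFAULT = 1.27


def _path(name: str):
    return resources.files("armloop.data") / name


def spindle_gain_matrix() -> GainMatrix:
    """The packaged 13x13 relative spindle gain matrix G."""
    return load_gain_matrix(_path("spindle_gain_matrix.csv"))


def muscle_parameters(k: float = _K_DEFAULT) -> pd.DataFrame:
    """Per-muscle parameter table, canonical 13-muscle index.

    Adds ``gto_gain_e3`` recomputed as k/C (display units, 1e-3 MVC/N)
    alongside the printed column, and ``gto_gain_discrepant`` flagging
    muscles where the printed value disagrees with k/C beyond rounding
    (the wrist flexor/extensor printed gains are pairwise swapped).
    """
    df = load_muscle_table(_path("muscle_parameters.csv"))
    computed = units.gto_internal_to_display(k / df["max_force_N"])
    df["gto_gain_e3"] = computed
    df["gto_gain_discrepant"] = (computed - df["gto_gain_printed_e3"]).abs() > 0.005 + 0.01 * computed
    return df


def excess_central_delay() -> pd.DataFrame:
    """The packaged 11x11 excess-of-central-delay matrix (ms)."""
    return load_delay_matrix(_path("excess_central_delay.csv"))


def solved_delays() -> DelayTables:
    """Delay tables with the packaged ECD matrix and solved per-muscle delays."""
    df = load_muscle_table(_path("muscle_parameters.csv"))
    # collapse deltoid heads (identical printed delays) to the 11-muscle set
    aff, eff = {}, {}
    from .muscles import CANONICAL_13, MUSCLES
    for m in CANONICAL_13:
        d = MUSCLES.delay_map[m]
        aff[d] = float(df.loc[m, "afferent_ms"])
        eff[d] = float(df.loc[m, "efferent_ms"])
    return DelayTables(
        ecd=excess_central_delay(),
        afferent=pd.Series(aff).loc[list(MUSCLES.delay_11)],
        efferent=pd.Series(eff).loc[list(MUSCLES.delay_11)],
    )


def precursor_observations() -> pd.DataFrame:
    """Synthetic reconstruction of the per-study reflex observation set.

    The cell-level precursor observations behind the gain matrix were
    published only as supplementary material; this packaged set is a
    synthetic reconstruction, generated by
    :func:`armloop.fixtures.reconstruct_precursor_observations`, that is
    exactly consistent with the packaged gain matrix when run through the
    estimation pipeline.
    """
    return pd.read_csv(_path("precursor_observations_synthetic.csv"), comment="#")


def innervation_lengths() -> pd.Series:
    """Synthetic innervation-length side table (m), 11-muscle index.

    Constructed by least squares so that one length per muscle is jointly
    consistent with the packaged afferent and efferent delays at afferent /
    efferent conduction velocities of 56.8 / 29.1 m/s.
    """
    df = pd.read_csv(_path("innervation_lengths_synthetic.csv"), comment="#")
    return df.set_index("muscle")["length_m"]
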