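"""Centralized unit conventions and converters.

Internal computation uses SI-flavoured units throughout: seconds, meters,
newtons, radians, and activation as a fraction of maximum voluntary
contraction (MVC).  The packaged tables store the printed units of their
sources (milliseconds for delays, 10^-3 MVC/N for force-feedback gains);
conversions happen only through these helpers so the convention lives in
one place.
"""

MS_PER_S = 1000.0
GTO_DISPLAY_SCALE = 1e3  # printed force-feedback gains are in 1e-3 MVC/N


def ms_to_s(value_ms):
    return value_ms / MS_PER_S


def s_to_ms(value_s):
    return value_s * MS_PER_S


def gto_internal_to_display(gain_mvc_per_n):
    """MVC/N -> 10^-3 MVC/N (the printed display unit)."""
    return gain_mvc_per_n * GTO_DISPLAY_SCALE


def gto_display_to_internal(gain_display):
    """10^-3 MVC/N -> MVC/N."""
    return gain_display / GTO_DISPLAY_SCALE
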