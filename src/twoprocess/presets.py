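"""Canonical parameter sets used throughout the package's examples.

All sets use the scaled form (asymptotes 1 and 0), a 24 h cosine forcing
and hours as the time unit.  ``standard`` is the classic human set
(chi_s = 4.2 h, chi_w = 18.2 h, thresholds 0.67 / 0.17); ``mouse`` swaps
in the shorter murine time constants.
"""

from __future__ import annotations

from dataclasses import replace

from .core_model import ModelParams
from .exceptions import ConfigurationError

__all__ = ["PRESETS", "preset"]

_STANDARD = ModelParams(
    chi_w=18.2, chi_s=4.2, H0_plus=0.67, H0_minus=0.17, a=0.12,
    mu_w=1.0, mu_s=0.0, T_f=24.0, waveform="cosine",
)

PRESETS: dict[str, ModelParams] = {
    # monophasic: one sleep per forcing period
    "fig1b": _STANDARD,
    # three sleeps every four days
    "fig1c": replace(_STANDARD, H0_plus=0.75, H0_minus=0.09, a=0.07),
    # three sleeps every two days
    "fig1d": replace(_STANDARD, H0_plus=0.75, H0_minus=0.50, a=0.07),
    # polyphasic: two sleeps per day
    "fig1e": replace(_STANDARD, H0_plus=0.75, H0_minus=0.58, a=0.07),
    # unforced oscillator (natural period ~22.5 h)
    "fig6a": replace(_STANDARD, a=0.0),
    # base set for tongue scans (amplitude is the swept axis)
    "fig7_base": replace(_STANDARD, a=0.08),
    # base set for staircase sweeps at fixed amplitude
    "fig8_base": replace(_STANDARD, a=0.12),
    # murine homeostatic time constants
    "mouse": replace(_STANDARD, chi_w=8.3, chi_s=1.7),
}


def preset(name: str) -> ModelParams:
    """Return a canonical parameter set by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
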