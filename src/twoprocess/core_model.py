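"""Core parameterisation and closed forms for the two-process model.

The model tracks a scalar homeostatic sleep pressure that relaxes
exponentially toward an upper asymptote ``mu_w`` during wake and toward a
lower asymptote ``mu_s`` during sleep.  Switching between the two vigilance
states happens at a pair of circadian-modulated thresholds whose mean
levels are ``H0_plus`` (wake -> sleep) and ``H0_minus`` (sleep -> wake);
the modulation is a shared waveform of period ``T_f`` scaled by the
circadian amplitude ``a``, so the gap between the thresholds is constant.

Everything in this module is closed form: pressure evolution within a
vigilance state, threshold evaluation, the shift-and-rescale reduction
that removes the two asymptote parameters, the natural (unforced) period
of the sleep-wake relaxation oscillation, and its inverse with respect to
the mean upper threshold.  Time is measured in hours throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Union

import numpy as np
from scipy.optimize import brentq

from .exceptions import (
    ConfigurationError,
    InvalidStateError,
    ParameterError,
    PerpetualSleepError,
    PerpetualWakeError,
)

__all__ = [
    "ModelParams",
    "ScaledParams",
    "PeriodSummary",
    "register_waveform",
    "circadian_waveform",
    "wake_pressure",
    "sleep_pressure",
    "threshold_upper",
    "threshold_lower",
    "rescale",
    "natural_periods",
    "invert_natural_period",
    "as_model_params",
]

# A waveform maps (time in hours, period in hours) -> dimensionless value
# in [-1, 1], periodic with the given period.
WaveformFn = Callable[[np.ndarray, float], np.ndarray]

_WAVEFORMS: dict[str, WaveformFn] = {}


def register_waveform(tag: str, fn: WaveformFn) -> None:
    """Register a circadian waveform under ``tag``.

    The function must be periodic in its first argument with period equal
    to its second argument and take values within [-1, 1].  Registering a
    new tag makes it usable from :class:`ModelParams` and the CLI.
    """
    _WAVEFORMS[tag] = fn


register_waveform("cosine", lambda t, T_f: np.cos((2.0 * np.pi / T_f) * np.asarray(t)))


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """The eight parameters of the full model plus the waveform choice.

    Parameters
    ----------
    chi_w, chi_s
        Homeostatic time constants during wake and sleep (hours).
    H0_plus, H0_minus
        Mean levels of the upper (wake -> sleep) and lower
        (sleep -> wake) switching thresholds (pressure units).
    a
        Circadian amplitude of the threshold modulation (pressure units).
    mu_w, mu_s
        Upper and lower asymptotes of the homeostat (pressure units).
        Default to 1 and 0, the scaled form.
    T_f
        Period of the circadian forcing (hours).
    waveform
        Tag of a registered waveform; ``"cosine"`` gives
        ``C(t) = cos(2 pi t / T_f)`` with its maximum at t = 0.

    Notes
    -----
    ``H0_plus >= mu_w`` and ``H0_minus <= mu_s`` are constructible states
    (useful when sweeping parameters) but are flagged by
    :func:`natural_periods` as perpetual wake / perpetual sleep.
    """

    chi_w: float
    chi_s: float
    H0_plus: float
    H0_minus: float
    a: float
    mu_w: float = 1.0
    mu_s: float = 0.0
    T_f: float = 24.0
    waveform: str = "cosine"

    def __post_init__(self) -> None:
        for name in ("chi_w", "chi_s", "H0_plus", "H0_minus", "a", "mu_w", "mu_s", "T_f"):
            _require_finite(name, float(getattr(self, name)))
        if self.chi_w <= 0 or self.chi_s <= 0:
            raise ParameterError("time constants chi_w and chi_s must be positive")
        if self.T_f <= 0:
            raise ParameterError("forcing period T_f must be positive")
        if self.a < 0:
            raise ParameterError("circadian amplitude a must be non-negative")
        if self.mu_w <= self.mu_s:
            raise ParameterError(
                f"upper asymptote mu_w={self.mu_w} must exceed lower asymptote mu_s={self.mu_s}"
            )
        if self.H0_minus > self.H0_plus:
            raise ParameterError(
                f"mean thresholds must be ordered: H0_minus={self.H0_minus} > H0_plus={self.H0_plus}"
            )
        if self.waveform not in _WAVEFORMS:
            raise ConfigurationError(
                f"unknown waveform {self.waveform!r}; registered: {sorted(_WAVEFORMS)}"
            )

    @property
    def mu(self) -> float:
        """Asymptote span ``mu_w - mu_s`` (the rescaled upper asymptote)."""
        return self.mu_w - self.mu_s


@dataclass(frozen=True)
class ScaledParams:
    """Shift-and-rescaled parameters with the asymptotes fixed at 1 and 0.

    Produced by :func:`rescale`; ``as_params`` converts back to a
    :class:`ModelParams` with ``mu_w = 1`` and ``mu_s = 0`` so that the
    scaled set can be fed to any routine that simulates or analyses the
    model.
    """

    chi_w: float
    chi_s: float
    H0_plus_tilde: float
    H0_minus_tilde: float
    a_tilde: float
    T_f: float = 24.0
    waveform: str = "cosine"

    def as_params(self) -> ModelParams:
        return ModelParams(
            chi_w=self.chi_w,
            chi_s=self.chi_s,
            H0_plus=self.H0_plus_tilde,
            H0_minus=self.H0_minus_tilde,
            a=self.a_tilde,
            mu_w=1.0,
            mu_s=0.0,
            T_f=self.T_f,
            waveform=self.waveform,
        )


ParamsLike = Union[ModelParams, ScaledParams]


def as_model_params(p: ParamsLike) -> ModelParams:
    """Coerce either parameter container to a plain :class:`ModelParams`."""
    if isinstance(p, ModelParams):
        return p
    if isinstance(p, ScaledParams):
        return p.as_params()
    raise TypeError(f"expected ModelParams or ScaledParams, got {type(p).__name__}")


@dataclass(frozen=True)
class PeriodSummary:
    """Closed-form durations of the unforced sleep-wake oscillation."""

    T_sleep: float
    T_wake: float
    T_nat: float
    fraction_asleep: float


def circadian_waveform(t, p: ParamsLike):
    """Evaluate the configured waveform C(t) at time ``t`` (hours).

    For the default cosine this is ``cos(2 pi t / T_f)``: the circadian
    maximum sits at t = 0 and the minimum at t = T_f/2 (mod T_f).
    """
    p = as_model_params(p)
    try:
        fn = _WAVEFORMS[p.waveform]
    except KeyError:  # pragma: no cover - construction validates the tag
        raise ConfigurationError(f"unknown waveform {p.waveform!r}") from None
    return fn(t, p.T_f)


def threshold_upper(t, p: ParamsLike):
    """Upper (wake -> sleep) switching threshold at time ``t``."""
    p = as_model_params(p)
    return p.H0_plus + p.a * circadian_waveform(t, p)


def threshold_lower(t, p: ParamsLike):
    """Lower (sleep -> wake) switching threshold at time ``t``."""
    p = as_model_params(p)
    return p.H0_minus + p.a * circadian_waveform(t, p)


def wake_pressure(dt, H_off: float, p: ParamsLike):
    """Homeostatic pressure ``dt`` hours after sleep offset.

    Rises from ``H_off`` exponentially toward the asymptote ``mu_w`` with
    time constant ``chi_w``.  ``dt`` may be a scalar or array of
    non-negative hours.

    Raises
    ------
    InvalidStateError
        If ``H_off >= mu_w``: pressure cannot rise toward the asymptote.
    """
    p = as_model_params(p)
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be non-negative")
    if H_off >= p.mu_w:
        raise InvalidStateError(
            f"pressure at sleep offset H_off={H_off} must lie below the asymptote mu_w={p.mu_w}"
        )
    out = p.mu_w + (H_off - p.mu_w) * np.exp(-dt / p.chi_w)
    return out if out.ndim else float(out)


def sleep_pressure(dt, H_on: float, p: ParamsLike):
    """Homeostatic pressure ``dt`` hours after sleep onset.

    Decays from ``H_on`` exponentially toward the asymptote ``mu_s`` with
    time constant ``chi_s``.

    Raises
    ------
    InvalidStateError
        If ``H_on <= mu_s``: pressure cannot fall toward the asymptote.
    """
    p = as_model_params(p)
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be non-negative")
    if H_on <= p.mu_s:
        raise InvalidStateError(
            f"pressure at sleep onset H_on={H_on} must lie above the asymptote mu_s={p.mu_s}"
        )
    out = p.mu_s + (H_on - p.mu_s) * np.exp(-dt / p.chi_s)
    return out if out.ndim else float(out)


def rescale(p: ModelParams) -> ScaledParams:
    """Shift-and-rescale the parameters so the asymptotes become 1 and 0.

    Thresholds and amplitude map as ``(x - mu_s) / (mu_w - mu_s)``; time
    constants and the forcing period are untouched, so the rescaled model
    produces switch times identical to the original one.
    """
    mu = p.mu_w - p.mu_s
    if mu <= 0:  # pragma: no cover - ModelParams forbids this
        raise ParameterError("mu_w must exceed mu_s")
    return ScaledParams(
        chi_w=p.chi_w,
        chi_s=p.chi_s,
        H0_plus_tilde=(p.H0_plus - p.mu_s) / mu,
        H0_minus_tilde=(p.H0_minus - p.mu_s) / mu,
        a_tilde=p.a / mu,
        T_f=p.T_f,
        waveform=p.waveform,
    )


def natural_periods(p: ParamsLike) -> PeriodSummary:
    """Closed-form periods of the unforced (zero-amplitude) oscillation.

    ``T_sleep = chi_s * log((H0_plus - mu_s) / (H0_minus - mu_s))`` and
    ``T_wake = chi_w * log((mu_w - H0_minus) / (mu_w - H0_plus))``; the
    natural period is their sum.  The circadian amplitude plays no role.

    Raises
    ------
    PerpetualWakeError
        If ``H0_plus >= mu_w`` (pressure never reaches the upper threshold).
    PerpetualSleepError
        If ``H0_minus <= mu_s`` (pressure never falls to the lower threshold).
    """
    p = as_model_params(p)
    if p.H0_plus >= p.mu_w:
        raise PerpetualWakeError(
            f"H0_plus={p.H0_plus} >= mu_w={p.mu_w}: wake would never terminate"
        )
    if p.H0_minus <= p.mu_s:
        raise PerpetualSleepError(
            f"H0_minus={p.H0_minus} <= mu_s={p.mu_s}: sleep would never terminate"
        )
    T_sleep = p.chi_s * math.log((p.H0_plus - p.mu_s) / (p.H0_minus - p.mu_s))
    T_wake = p.chi_w * math.log((p.mu_w - p.H0_minus) / (p.mu_w - p.H0_plus))
    T_nat = T_sleep + T_wake
    fraction = T_sleep / T_nat if T_nat > 0 else float("nan")
    return PeriodSummary(T_sleep=T_sleep, T_wake=T_wake, T_nat=T_nat, fraction_asleep=fraction)


def invert_natural_period(target_T_nat: float, p: ParamsLike) -> float:
    """Mean upper threshold whose natural period equals ``target_T_nat``.

    All other fields of ``p`` are kept; its ``H0_plus`` is ignored.  The
    natural period is continuous and strictly increasing in ``H0_plus`` on
    ``(H0_minus, mu_w)`` with range ``(0, inf)``, so the root is unique and
    located by bracketed scalar root finding to better than 1e-9 h.
    """
    p = as_model_params(p)
    if not (target_T_nat > 0) or not math.isfinite(target_T_nat):
        raise ParameterError(f"target natural period must be positive and finite, got {target_T_nat}")
    if p.H0_minus <= p.mu_s:
        raise PerpetualSleepError(
            f"H0_minus={p.H0_minus} <= mu_s={p.mu_s}: no natural period exists"
        )

    span = p.mu_w - p.H0_minus

    # Large periods push H0_plus exponentially close to mu_w, so solve in
    # u = log(mu_w - H0_plus): the period is affine in u through its wake
    # term and the root stays well conditioned.  The period is evaluated
    # directly in u (never materialising H0_plus) so the bracket search
    # cannot round onto the asymptote.
    def f(u: float) -> float:
        e = math.exp(u)
        T_wake = p.chi_w * (math.log(p.mu_w - p.H0_minus) - u)
        T_sleep = p.chi_s * math.log(((p.mu_w - p.mu_s) - e) / (p.H0_minus - p.mu_s))
        return T_wake + T_sleep - target_T_nat

    u_top = math.log(span)
    delta = 1e-9
    u_hi = u_top - delta
    while f(u_hi) >= 0:
        delta *= 1e-2
        if delta < 1e-17:
            raise ParameterError("failed to bracket target natural period from below")
        u_hi = u_top - delta
    u_lo = u_top - 1.0
    while f(u_lo) <= 0:
        u_lo -= 5.0
        if u_lo < -700.0:
            raise ParameterError("failed to bracket target natural period from above")

    root = brentq(f, u_lo, u_hi, xtol=1e-13, maxiter=200)
    return float(p.mu_w - math.exp(root))
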