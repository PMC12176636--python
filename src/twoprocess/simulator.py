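"""Event-driven simulation of the hybrid sleep-wake system.

Within each vigilance state the homeostat follows its closed form, so the
only numerical work is locating the first crossing of the active
circadian-modulated threshold (upper during wake, lower during sleep).
Crossings are bracketed analytically, scanned on a uniform grid and
refined by root finding; no ODE integration happens anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.optimize import minimize_scalar

from .core_model import (
    ModelParams,
    ParamsLike,
    as_model_params,
    circadian_waveform,
    sleep_pressure,
    threshold_lower,
    threshold_upper,
    wake_pressure,
)
from .exceptions import ParameterError

__all__ = [
    "StateLabel",
    "VigilanceState",
    "Episode",
    "SimResult",
    "find_next_switch",
    "simulate",
    "episodes_to_raster",
    "circadian_min_times",
    "DEFAULT_SCAN_DIVISIONS",
    "MIN_DWELL_H",
]

log = logging.getLogger(__name__)

#: default number of scan points per forcing period for crossing detection
DEFAULT_SCAN_DIVISIONS = 2048

#: minimum dwell (hours) in a state before the next crossing is sought
MIN_DWELL_H = 1e-6


class StateLabel(Enum):
    WAKE = "wake"
    SLEEP = "sleep"

    @property
    def other(self) -> "StateLabel":
        return StateLabel.SLEEP if self is StateLabel.WAKE else StateLabel.WAKE


@dataclass
class VigilanceState:
    """Instantaneous state of the hybrid system."""

    label: StateLabel
    t: float
    H: float


@dataclass(frozen=True)
class Episode:
    """One contiguous wake or sleep interval.

    Phases are fractions of the forcing period elapsed since the last
    circadian maximum (t = 0 convention), in [0, 1).
    """

    kind: StateLabel
    t_start: float
    t_end: float
    phase_start: float
    phase_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class Segment:
    """Internal (unclipped) trajectory segment with its pressure anchors."""

    label: StateLabel
    t_start: float
    t_end: float
    H_start: float
    H_end: float


@dataclass
class SimResult:
    """Episode log of one simulation plus optional sampled trajectories."""

    params: ModelParams
    episodes: list[Episode]
    segments: list[Segment] = field(default_factory=list)
    transient_discarded: float = 0.0
    horizon: float = 0.0
    nonterminating: bool = False
    n_immediate_switches: int = 0
    samples: Optional[pd.DataFrame] = None

    @property
    def sleep_onsets(self) -> list[float]:
        """Raw wake -> sleep switch times over the whole run (hours)."""
        return [
            s.t_start
            for i, s in enumerate(self.segments)
            if i > 0 and s.label is StateLabel.SLEEP
        ]

    @property
    def switch_times(self) -> list[float]:
        return [s.t_start for s in self.segments[1:]]


def _pressure(label: StateLabel, dt, H0: float, p: ModelParams):
    if label is StateLabel.WAKE:
        return wake_pressure(dt, H0, p)
    return sleep_pressure(dt, H0, p)


def _pressure_scalar(label: StateLabel, dt: float, H0: float, p: ModelParams) -> float:
    # math-only fast path used inside root refinement
    if label is StateLabel.WAKE:
        return p.mu_w + (H0 - p.mu_w) * math.exp(-dt / p.chi_w)
    return p.mu_s + (H0 - p.mu_s) * math.exp(-dt / p.chi_s)


def _active_threshold(label: StateLabel, t, p: ModelParams):
    if label is StateLabel.WAKE:
        return threshold_upper(t, p)
    return threshold_lower(t, p)


def _never_crosses(label: StateLabel, p: ModelParams) -> bool:
    """True when the active threshold is provably unreachable."""
    if label is StateLabel.WAKE:
        return p.H0_plus - p.a >= p.mu_w
    return p.H0_minus + p.a <= p.mu_s


def find_next_switch(
    state: VigilanceState,
    p: ParamsLike,
    t_max: float = math.inf,
    scan_step: Optional[float] = None,
    min_dwell: float = MIN_DWELL_H,
) -> Optional[float]:
    """Time of the first crossing of the active threshold after ``state.t``.

    The search starts at ``state.t + min_dwell`` (the dwell guard lets a
    state that sits exactly on its threshold move off it first).  If the
    pressure has already passed the active threshold by then, the guard
    time itself is returned.  Returns ``None`` if no crossing exists
    before ``t_max`` -- either because the crossing is provably impossible
    (asymptote on the wrong side of the whole threshold range) or simply
    because it falls beyond ``t_max``.

    For zero amplitude the crossing is computed from the logarithmic
    closed form.  Otherwise the crossing is bracketed analytically inside
    a window no longer than one forcing period, scanned on a uniform grid
    of step ``scan_step`` (default ``T_f / 2048``) and refined by Brent's
    method to well below 1e-9 h.
    """
    p = as_model_params(p)
    label = state.label
    sgn = 1.0 if label is StateLabel.WAKE else -1.0

    t_start = state.t + min_dwell
    if t_start > t_max:
        return None
    H_start = _pressure_scalar(label, min_dwell, state.H, p)
    thr_start = float(_active_threshold(label, t_start, p))
    if sgn * (H_start - thr_start) >= 0.0:
        return t_start  # already past the threshold: immediate re-switch

    if p.a == 0.0:
        if label is StateLabel.WAKE:
            if p.H0_plus >= p.mu_w:
                return None
            t_star = t_start + p.chi_w * math.log((p.mu_w - H_start) / (p.mu_w - p.H0_plus))
        else:
            if p.H0_minus <= p.mu_s:
                return None
            t_star = t_start + p.chi_s * math.log((H_start - p.mu_s) / (p.H0_minus - p.mu_s))
        return t_star if t_star <= t_max else None

    # Analytic bracket: the crossing cannot happen before the pressure has
    # reached the near edge of the threshold band, and is guaranteed within
    # one forcing period of that moment (the threshold revisits its
    # extremum once per period while the pressure keeps approaching the
    # asymptote monotonically).
    if label is StateLabel.WAKE:
        near, far = p.H0_plus - p.a, p.H0_plus + p.a
        if near >= p.mu_w:
            return None
        t_lo = t_start if H_start >= near else (
            t_start + p.chi_w * math.log((p.mu_w - H_start) / (p.mu_w - near))
        )
        t_hi = math.inf
        if far < p.mu_w and H_start < far:
            t_hi = t_start + p.chi_w * math.log((p.mu_w - H_start) / (p.mu_w - far))
    else:
        near, far = p.H0_minus + p.a, p.H0_minus - p.a
        if near <= p.mu_s:
            return None
        t_lo = t_start if H_start <= near else (
            t_start + p.chi_s * math.log((H_start - p.mu_s) / (near - p.mu_s))
        )
        t_hi = math.inf
        if far > p.mu_s and H_start > far:
            t_hi = t_start + p.chi_s * math.log((H_start - p.mu_s) / (far - p.mu_s))
    t_hi = min(t_hi, t_lo + p.T_f)

    if t_lo > t_max:
        return None

    step = scan_step if scan_step is not None else p.T_f / DEFAULT_SCAN_DIVISIONS

    def g_scalar(t: float) -> float:
        return sgn * (
            _pressure_scalar(label, t - t_start, H_start, p)
            - float(_active_threshold(label, t, p))
        )

    # Scan windows of at most one forcing period until t_max is exhausted.
    w_lo = t_lo
    w_hi = min(t_hi, t_max)
    while True:
        n = max(2, int(math.ceil((w_hi - w_lo) / step)) + 1)
        ts = np.linspace(w_lo, w_hi, n)
        H = _pressure(label, ts - t_start, H_start, p)
        gs = sgn * (H - _active_threshold(label, ts, p))
        crossed = gs >= 0.0
        if crossed.any():
            idx = int(np.argmax(crossed))
            if idx == 0:
                # Float fuzz around the bracket edge; the true sign change
                # sits between the guard time and the window start.
                if gs[0] == 0.0 or w_lo <= t_start:
                    return float(w_lo)
                return float(brentq(g_scalar, t_start, float(ts[0]), xtol=1e-12))
            if gs[idx] == 0.0:
                return float(ts[idx])
            return float(brentq(g_scalar, float(ts[idx - 1]), float(ts[idx]), xtol=1e-12))
        if w_hi >= t_max:
            return None
        w_lo = w_hi
        w_hi = min(w_hi + p.T_f, t_max)


def simulate(
    p: ParamsLike,
    horizon: float,
    init: Optional[VigilanceState] = None,
    transient: Optional[float] = None,
    sample_step: Optional[float] = None,
    scan_step: Optional[float] = None,
    min_dwell: float = MIN_DWELL_H,
) -> SimResult:
    """Simulate the hybrid system and log alternating wake/sleep episodes.

    Parameters
    ----------
    p
        Model parameters (plain or rescaled).
    horizon
        Total simulated time in hours, from t = 0.
    init
        Initial state; defaults to WAKE at t = 0 with pressure midway
        between the mean thresholds.
    transient
        Hours discarded before episodes are retained (default ``50 * T_f``).
        Retained episodes are clipped so they tile ``[transient, horizon]``
        exactly.
    sample_step
        If given, also return uniformly sampled (t, H, upper, lower)
        trajectories over the retained window, reconstructed from the
        closed forms.

    Notes
    -----
    If the active threshold is provably unreachable the final episode is
    extended to the horizon and ``nonterminating`` is set on the result;
    callers that need a hard failure should check the flag.
    """
    p = as_model_params(p)
    if transient is None:
        transient = 50.0 * p.T_f
    if not (horizon > transient >= 0):
        raise ParameterError(f"need horizon > transient >= 0, got {horizon}, {transient}")
    if init is None:
        init = VigilanceState(
            label=StateLabel.WAKE, t=0.0, H=0.5 * (p.H0_plus + p.H0_minus)
        )

    segments: list[Segment] = []
    label, t_cur, H_cur = init.label, float(init.t), float(init.H)
    nonterminating = False
    n_immediate = 0

    while t_cur < horizon:
        t_next = find_next_switch(
            VigilanceState(label, t_cur, H_cur), p, t_max=horizon,
            scan_step=scan_step, min_dwell=min_dwell,
        )
        if t_next is None:
            H_end = _pressure_scalar(label, horizon - t_cur, H_cur, p)
            segments.append(Segment(label, t_cur, horizon, H_cur, H_end))
            if _never_crosses(label, p):
                nonterminating = True
            break
        if t_next - t_cur <= min_dwell * (1.0 + 1e-9):
            n_immediate += 1
            log.warning(
                "immediate re-switch at t=%.6f h: new active threshold already passed",
                t_cur,
            )
        H_end = _pressure_scalar(label, t_next - t_cur, H_cur, p)
        segments.append(Segment(label, t_cur, t_next, H_cur, H_end))
        label, t_cur, H_cur = label.other, t_next, H_end

    episodes: list[Episode] = []
    for seg in segments:
        s = max(seg.t_start, transient)
        e = min(seg.t_end, horizon)
        if e <= s:
            continue
        episodes.append(
            Episode(
                kind=seg.label,
                t_start=s,
                t_end=e,
                phase_start=(s / p.T_f) % 1.0,
                phase_end=(e / p.T_f) % 1.0,
            )
        )

    samples = None
    if sample_step is not None:
        samples = _sample_trajectory(p, segments, transient, horizon, sample_step)

    return SimResult(
        params=p,
        episodes=episodes,
        segments=segments,
        transient_discarded=transient,
        horizon=horizon,
        nonterminating=nonterminating,
        n_immediate_switches=n_immediate,
        samples=samples,
    )


def _sample_trajectory(
    p: ModelParams,
    segments: Sequence[Segment],
    t_lo: float,
    t_hi: float,
    step: float,
) -> pd.DataFrame:
    if step <= 0:
        raise ParameterError("sample_step must be positive")
    ts = np.arange(t_lo, t_hi + 0.5 * step, step)
    ts = ts[ts <= t_hi]
    H = np.empty_like(ts)
    H[:] = np.nan
    for seg in segments:
        mask = (ts >= seg.t_start) & (ts <= seg.t_end)
        if mask.any():
            H[mask] = _pressure(seg.label, ts[mask] - seg.t_start, seg.H_start, p)
    return pd.DataFrame(
        {
            "t_h": ts,
            "H": H,
            "upper": threshold_upper(ts, p),
            "lower": threshold_lower(ts, p),
        }
    )


def episodes_to_raster(
    result: SimResult, row_length: float
) -> list[list[tuple[float, float]]]:
    """Fold the sleep episodes into raster rows of ``row_length`` hours.

    Row ``r`` covers absolute time ``[r * row_length, (r+1) * row_length)``;
    each returned interval is expressed relative to its row start, and
    episodes spanning a row boundary are split so the union of plotted
    intervals conserves total sleep time.
    """
    if row_length <= 0:
        raise ParameterError("row_length must be positive")
    sleeps = [e for e in result.episodes if e.kind is StateLabel.SLEEP]
    if not sleeps:
        return []
    n_rows = int(math.ceil(max(e.t_end for e in sleeps) / row_length - 1e-12))
    rows: list[list[tuple[float, float]]] = [[] for _ in range(n_rows)]
    for e in sleeps:
        t = e.t_start
        while t < e.t_end - 1e-12:
            r = int(math.floor(t / row_length + 1e-12))
            row_end = (r + 1) * row_length
            seg_end = min(e.t_end, row_end)
            rows[r].append((t - r * row_length, seg_end - r * row_length))
            t = seg_end
    return rows


def circadian_min_times(p: ParamsLike, horizon: float) -> list[float]:
    """Times of the circadian minimum in [0, horizon] (hours).

    For the cosine waveform these are ``T_f/2 + k * T_f``.  For any other
    registered waveform the minimiser over one period is located
    numerically (grid scan plus bounded refinement).
    """
    p = as_model_params(p)
    if p.waveform == "cosine":
        first = p.T_f / 2.0
    else:
        grid = np.linspace(0.0, p.T_f, 4096, endpoint=False)
        vals = np.asarray(circadian_waveform(grid, p))
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        res = minimize_scalar(
            lambda t: float(circadian_waveform(t, p)), bounds=(lo, hi), method="bounded"
        )
        first = float(res.x) % p.T_f
    out = []
    t = first
    while t <= horizon:
        out.append(t)
        t += p.T_f
    return out
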