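"""Circle-map machinery: rotation numbers, tongue scans and staircases.

The forced model reduces to a map sending one upper-threshold hit phase
(time modulo the forcing period) to the next.  Iterating the map's lift
gives the rotation number -- the average number of sleep onsets per
forcing period -- which is rational inside entrainment tongues and
irrational in quasiperiodic (internally desynchronised) regimes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    ModelParams,
    ParamsLike,
    as_model_params,
    natural_periods,
    threshold_upper,
)
from .exceptions import (
    ConfigurationError,
    NonTerminatingError,
    ParameterError,
)
from .simulator import (
    SimResult,
    StateLabel,
    VigilanceState,
    find_next_switch,
    _pressure_scalar,
)

__all__ = [
    "EntrainmentStatus",
    "EntrainmentClass",
    "TongueGrid",
    "circle_map_step",
    "rotation_number",
    "classify_rotation",
    "sleeps_per_day",
    "tongue_scan",
    "staircase",
    "SWEEPABLE_PARAMS",
]

log = logging.getLogger(__name__)

SWEEPABLE_PARAMS = ("H0_plus", "H0_minus", "chi_s", "chi_w", "mu_w")


class EntrainmentStatus(Enum):
    RATIONAL = "rational"
    QUASIPERIODIC = "quasiperiodic"
    UNRESOLVED = "unresolved"
    NONTERMINATING = "nonterminating"


@dataclass(frozen=True)
class EntrainmentClass:
    """Rotation number with, when locked, its rational (n, m) tongue label:
    n sleeps per m forcing periods."""

    rho: float
    status: EntrainmentStatus
    n: Optional[int] = None
    m: Optional[int] = None


def circle_map_step(
    phase: float, p: ParamsLike, scan_step: Optional[float] = None
) -> tuple[float, float]:
    """One first-return step of the upper-threshold hit map.

    ``phase`` is a hit phase in [0, 1): at time ``phase * T_f`` the
    pressure sits exactly on the upper threshold and sleep begins.  One
    sleep and one wake segment are simulated; the return value is
    ``(next_phase, advance)`` where ``advance`` is the elapsed time in
    forcing periods (the lift increment) and ``next_phase`` the next hit
    phase.

    Raises
    ------
    NonTerminatingError
        If either segment provably never reaches its threshold.
    """
    p = as_model_params(p)
    t0 = (phase % 1.0) * p.T_f
    H0 = float(threshold_upper(t0, p))
    t1 = find_next_switch(
        VigilanceState(StateLabel.SLEEP, t0, H0), p, t_max=math.inf, scan_step=scan_step
    )
    if t1 is None:
        raise NonTerminatingError("sleep segment never reaches the lower threshold")
    H1 = _pressure_scalar(StateLabel.SLEEP, t1 - t0, H0, p)
    t2 = find_next_switch(
        VigilanceState(StateLabel.WAKE, t1, H1), p, t_max=math.inf, scan_step=scan_step
    )
    if t2 is None:
        raise NonTerminatingError("wake segment never reaches the upper threshold")
    advance = (t2 - t0) / p.T_f
    return (t2 / p.T_f) % 1.0, advance


def rotation_number(
    p: ParamsLike,
    n_iter: int = 400,
    transient_iter: int = 100,
    phase0: float = 0.0,
    scan_step: Optional[float] = None,
) -> float:
    """Average sleep onsets per forcing period from the circle-map lift.

    ``rho = n_iter / sum(advances)`` over ``n_iter`` post-transient
    iterations -- the reciprocal mean lift increment.  For zero amplitude
    this reduces exactly to ``T_f / T_nat``.
    """
    if n_iter < 100:
        raise ParameterError("n_iter must be at least 100 for a meaningful estimate")
    if transient_iter < 0:
        raise ParameterError("transient_iter must be non-negative")
    p = as_model_params(p)
    phase = phase0
    for _ in range(transient_iter):
        phase, _adv = circle_map_step(phase, p, scan_step=scan_step)
    total = 0.0
    for _ in range(n_iter):
        phase, adv = circle_map_step(phase, p, scan_step=scan_step)
        total += adv
    return n_iter / total


def classify_rotation(
    rho: float, q_max: int = 12, tol: float = 1e-3
) -> EntrainmentClass:
    """Label ``rho`` with the lowest-denominator fraction within ``tol``.

    Searches denominators 1..q_max in increasing order, so the returned
    (n, m) is the coarsest rational consistent with the estimate; if none
    fits, the motion is reported as quasiperiodic.
    """
    if not math.isfinite(rho) or rho < 0:
        raise ParameterError(f"rotation number must be finite and non-negative, got {rho}")
    for m in range(1, q_max + 1):
        n = round(rho * m)
        if abs(rho - n / m) < tol:
            g = math.gcd(n, m)
            return EntrainmentClass(
                rho=rho, status=EntrainmentStatus.RATIONAL, n=n // g, m=m // g
            )
    return EntrainmentClass(rho=rho, status=EntrainmentStatus.QUASIPERIODIC)


def sleeps_per_day(result: SimResult) -> float:
    """Empirical sleep onsets per forcing period over the retained window.

    Counts raw wake -> sleep switches after the transient horizon; a
    record shorter than 50 forcing periods triggers a precision warning.
    Cross-check for :func:`rotation_number` (agreement within 1/50 on any
    classified cell).
    """
    T_f = result.params.T_f
    window = result.horizon - result.transient_discarded
    periods = window / T_f
    if periods <= 0:
        raise ParameterError("simulation window is empty")
    if periods < 50:
        warnings.warn(
            f"only {periods:.1f} forcing periods retained; onset-count rotation "
            "estimate is coarse (< 1/50 precision)",
            UserWarning,
            stacklevel=2,
        )
    onsets = [t for t in result.sleep_onsets if t > result.transient_discarded]
    return len(onsets) / periods


@dataclass
class TongueGrid:
    """Rotation numbers on a (swept parameter) x (amplitude) grid.

    ``rho_matrix`` and companions have shape
    ``(len(amplitudes), len(sweep_values))``.  ``T_nat_values`` annotates
    the sweep axis with the analytic natural period (NaN where the swept
    value has no finite period).  ``n_matrix``/``m_matrix`` are 0 where no
    rational label was assigned.
    """

    sweep_param: str
    sweep_values: np.ndarray
    T_nat_values: np.ndarray
    amplitudes: np.ndarray
    rho_matrix: np.ndarray
    status_matrix: np.ndarray
    n_matrix: np.ndarray
    m_matrix: np.ndarray

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: one row per grid cell."""
        rows = []
        for i, amp in enumerate(self.amplitudes):
            for j, v in enumerate(self.sweep_values):
                rows.append(
                    {
                        "sweep_param": self.sweep_param,
                        "sweep_value": v,
                        "T_nat_h": self.T_nat_values[j],
                        "amplitude": amp,
                        "rho": self.rho_matrix[i, j],
                        "status": self.status_matrix[i, j].value,
                    }
                )
        return pd.DataFrame(rows)


def _cell(
    p: ModelParams,
    n_iter: int,
    transient_iter: int,
    q_max: int,
    tol: float,
    scan_step: Optional[float],
) -> EntrainmentClass:
    try:
        rho = rotation_number(
            p, n_iter=n_iter, transient_iter=transient_iter, scan_step=scan_step
        )
    except NonTerminatingError:
        return EntrainmentClass(rho=float("nan"), status=EntrainmentStatus.NONTERMINATING)
    except (ParameterError, FloatingPointError, OverflowError):
        return EntrainmentClass(rho=float("nan"), status=EntrainmentStatus.UNRESOLVED)
    return classify_rotation(rho, q_max=q_max, tol=tol)


def tongue_scan(
    sweep_param: str,
    sweep_values: Sequence[float],
    amplitudes: Sequence[float],
    base: ParamsLike,
    n_iter: int = 400,
    transient_iter: int = 100,
    q_max: int = 12,
    tol: float = 1e-3,
    scan_step: Optional[float] = None,
) -> TongueGrid:
    """Arnold-tongue grid scan: rotation number per (sweep value, amplitude).

    Each cell is an independent pure function of its parameters (results
    do not depend on evaluation order).  Swept values that violate the
    parameter ordering are skipped with a logged warning and left
    UNRESOLVED rather than silently interpolated.
    """
    if sweep_param not in SWEEPABLE_PARAMS:
        raise ConfigurationError(
            f"cannot sweep {sweep_param!r}; choose one of {SWEEPABLE_PARAMS}"
        )
    base = as_model_params(base)
    sweep_values = np.asarray(sweep_values, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    n_amp, n_sweep = amplitudes.size, sweep_values.size

    T_nat = np.full(n_sweep, np.nan)
    rho = np.full((n_amp, n_sweep), np.nan)
    status = np.full((n_amp, n_sweep), EntrainmentStatus.UNRESOLVED, dtype=object)
    n_mat = np.zeros((n_amp, n_sweep), dtype=int)
    m_mat = np.zeros((n_amp, n_sweep), dtype=int)

    for j, v in enumerate(sweep_values):
        try:
            p_sweep = replace(base, **{sweep_param: float(v)})
        except (ParameterError, ConfigurationError) as exc:
            log.warning("skipping %s=%g: %s", sweep_param, v, exc)
            continue
        try:
            T_nat[j] = natural_periods(p_sweep).T_nat
        except ParameterError:
            pass  # perpetual wake/sleep at zero amplitude; cells may still resolve
        for i, amp in enumerate(amplitudes):
            try:
                p_cell = replace(p_sweep, a=float(amp))
            except (ParameterError, ConfigurationError) as exc:
                log.warning("skipping %s=%g, a=%g: %s", sweep_param, v, amp, exc)
                continue
            cls = _cell(p_cell, n_iter, transient_iter, q_max, tol, scan_step)
            rho[i, j] = cls.rho
            status[i, j] = cls.status
            if cls.status is EntrainmentStatus.RATIONAL:
                n_mat[i, j] = cls.n
                m_mat[i, j] = cls.m

    return TongueGrid(
        sweep_param=sweep_param,
        sweep_values=sweep_values,
        T_nat_values=T_nat,
        amplitudes=amplitudes,
        rho_matrix=rho,
        status_matrix=status,
        n_matrix=n_mat,
        m_matrix=m_mat,
    )


def staircase(
    H0_plus_values: Sequence[float],
    base: ParamsLike,
    n_iter: int = 400,
    transient_iter: int = 100,
    q_max: int = 12,
    tol: float = 1e-3,
    scan_step: Optional[float] = None,
) -> pd.DataFrame:
    """Devil's-staircase sweep: rotation number along ascending ``H0_plus``.

    The circadian amplitude is taken from ``base``.  Returns a frame with
    columns H0_plus, T_nat_h, rho, n, m, status.
    """
    base = as_model_params(base)
    values = np.asarray(H0_plus_values, dtype=float)
    if values.size and np.any(np.diff(values) <= 0):
        raise ConfigurationError("H0_plus_values must be sorted strictly ascending")
    rows = []
    for v in values:
        T_nat = float("nan")
        try:
            p = replace(base, H0_plus=float(v))
        except (ParameterError, ConfigurationError) as exc:
            log.warning("skipping H0_plus=%g: %s", v, exc)
            cls = EntrainmentClass(rho=float("nan"), status=EntrainmentStatus.UNRESOLVED)
        else:
            try:
                T_nat = natural_periods(p).T_nat
            except ParameterError:
                pass
            cls = _cell(p, n_iter, transient_iter, q_max, tol, scan_step)
        rows.append(
            {
                "H0_plus": float(v),
                "T_nat_h": T_nat,
                "rho": cls.rho,
                "n": cls.n if cls.n is not None else 0,
                "m": cls.m if cls.m is not None else 0,
                "status": cls.status.value,
            }
        )
    return pd.DataFrame(rows)
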