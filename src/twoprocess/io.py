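"""File writers/readers: JSON parameter files and CSV exports.

Every CSV written here starts with ``#``-prefixed provenance lines (a
parameter echo and the package version) followed by a header row; the
readers skip comment lines, so outputs round-trip.
"""

from __future__ import annotations

import csv
import dataclasses
import io as _io
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd

from . import __version__
from .core_model import ModelParams
from .exceptions import ConfigurationError
from .simulator import Episode, SimResult, StateLabel

__all__ = [
    "PARAM_KEYS",
    "load_config",
    "params_to_dict",
    "write_params_json",
    "write_episodes_csv",
    "read_episodes_csv",
    "write_trajectory_csv",
    "write_circlemap_csv",
    "write_frame_csv",
]

PARAM_KEYS = (
    "chi_w", "chi_s", "mu_w", "mu_s", "H0_plus", "H0_minus", "a", "T_f", "waveform",
)

_DEFAULTS = {"mu_w": 1.0, "mu_s": 0.0, "T_f": 24.0, "waveform": "cosine"}

EPISODE_COLUMNS = ("kind", "t_start_h", "t_end_h", "duration_h", "phase_start", "phase_end")


def params_from_dict(raw: dict) -> ModelParams:
    """Build validated parameters from a plain dict (JSON-shaped).

    Unknown keys and missing required keys raise configuration errors;
    omitted asymptotes default to the scaled form (mu_w=1, mu_s=0).
    """
    if not isinstance(raw, dict):
        raise ConfigurationError(f"parameter file must hold a JSON object, got {type(raw).__name__}")
    unknown = set(raw) - set(PARAM_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}
    missing = [k for k in PARAM_KEYS if k not in merged]
    if missing:
        raise ConfigurationError(f"missing required parameter keys: {missing}")
    return ModelParams(**merged)


def load_config(path: Union[str, Path]) -> ModelParams:
    """Load a JSON parameter file into validated :class:`ModelParams`."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except FileNotFoundError:
        raise ConfigurationError(f"config file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"config file {path} is not valid JSON: {exc}") from None
    return params_from_dict(raw)


def params_to_dict(p: ModelParams) -> dict:
    return {k: getattr(p, k) for k in PARAM_KEYS}


def write_params_json(p: ModelParams, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(params_to_dict(p), indent=2) + "\n")


def _provenance_lines(p: Optional[ModelParams]) -> list[str]:
    lines = [f"# twoprocess v{__version__}"]
    if p is not None:
        lines.append("# params: " + json.dumps(params_to_dict(p)))
    return lines


def _open_sink(path_or_buf) -> tuple[TextIO, bool]:
    if hasattr(path_or_buf, "write"):
        return path_or_buf, False
    return open(path_or_buf, "w", newline=""), True


def write_episodes_csv(result: SimResult, path_or_buf) -> None:
    """Episode log as CSV with 6-decimal fidelity."""
    sink, owned = _open_sink(path_or_buf)
    try:
        for line in _provenance_lines(result.params):
            sink.write(line + "\n")
        writer = csv.writer(sink)
        writer.writerow(EPISODE_COLUMNS)
        for e in result.episodes:
            writer.writerow(
                [e.kind.value]
                + [f"{x:.6f}" for x in (e.t_start, e.t_end, e.duration, e.phase_start, e.phase_end)]
            )
    finally:
        if owned:
            sink.close()


def read_episodes_csv(path_or_buf) -> list[Episode]:
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        text = Path(path_or_buf).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    reader = csv.DictReader(_io.StringIO("\n".join(lines)))
    episodes = []
    for row in reader:
        episodes.append(
            Episode(
                kind=StateLabel(row["kind"]),
                t_start=float(row["t_start_h"]),
                t_end=float(row["t_end_h"]),
                phase_start=float(row["phase_start"]),
                phase_end=float(row["phase_end"]),
            )
        )
    return episodes


def write_trajectory_csv(result: SimResult, path_or_buf) -> None:
    if result.samples is None:
        raise ConfigurationError("simulation was run without trajectory sampling")
    sink, owned = _open_sink(path_or_buf)
    try:
        for line in _provenance_lines(result.params):
            sink.write(line + "\n")
        result.samples.to_csv(
            sink, index=False, float_format="%.6f",
            header=["t_h", "H", "upper", "lower"],
        )
    finally:
        if owned:
            sink.close()


def write_circlemap_csv(rows: Iterable[tuple[float, float, float]], p: ModelParams, path_or_buf) -> None:
    """Rows of (phase, next_phase, advance)."""
    sink, owned = _open_sink(path_or_buf)
    try:
        for line in _provenance_lines(p):
            sink.write(line + "\n")
        writer = csv.writer(sink)
        writer.writerow(["phase", "next_phase", "advance"])
        for phase, nxt, adv in rows:
            writer.writerow([f"{phase:.6f}", f"{nxt:.6f}", f"{adv:.6f}"])
    finally:
        if owned:
            sink.close()


def write_frame_csv(frame: pd.DataFrame, p: Optional[ModelParams], path_or_buf) -> None:
    """Generic long-format export (tongue grids, staircases)."""
    sink, owned = _open_sink(path_or_buf)
    try:
        for line in _provenance_lines(p):
            sink.write(line + "\n")
        frame.to_csv(sink, index=False)
    finally:
        if owned:
            sink.close()
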