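"""Acquisition-segment and temperature-log I/O.

An extraction run is monitored by recording one fixed-length acoustic-emission
(AE) waveform every ``acquisition_period_s`` seconds (default: 10 s of signal
at 1 MHz every 30 s) together with a time-stamped temperature log from a
thermocouple.  This module defines the on-disk formats (IEEE-float WAV or raw
little-endian float32 with a JSON metadata sidecar; CSV for temperature) and
the time-base conventions used everywhere else in the package.

Time base: acquisition index ``n >= 1`` maps to ``time_min = n * period / 60``,
i.e. the first acquisition is taken one full period after the start of
heating.  With the default 30 s period every event time is a multiple of
0.5 min.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import (
    ConfigError,
    NonFiniteSignalError,
    NonMonotoneTimeError,
    SampleCountError,
    SidecarError,
    TemperatureNotReachedError,
)

__all__ = [
    "AcquisitionConfig",
    "AcquisitionSegment",
    "TemperatureTrace",
    "read_segment",
    "write_segment",
    "read_temperature_log",
    "write_temperature_log",
    "time_to_temperature",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition-hardware parameters for one monitoring run.

    Defaults reproduce the laboratory setup: 1 MHz sampling, 10 s of signal
    per acquisition, one acquisition every 30 s, 80 averaging segments, and a
    conditioner gain of 1000 (kept as metadata only; voltages are stored
    as recorded).
    """

    sampling_rate_hz: float = 1_000_000.0
    collection_duration_s: float = 10.0
    acquisition_period_s: float = 30.0
    n_segments: int = 80
    gain: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("sampling_rate_hz", "collection_duration_s",
                     "acquisition_period_s", "gain"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_segments < 1:
            raise ConfigError("n_segments must be a positive integer")
        total = self.sampling_rate_hz * self.collection_duration_s
        if abs(total - round(total)) > 1e-6:
            raise ConfigError(
                "sampling_rate_hz * collection_duration_s must be an integer "
                f"sample count, got {total}")
        if round(total) % self.n_segments != 0:
            raise ConfigError(
                f"total sample count {round(total)} not divisible by "
                f"n_segments={self.n_segments}")
        if self.acquisition_period_s < self.collection_duration_s:
            raise ConfigError(
                "acquisition_period_s must be >= collection_duration_s")

    @property
    def n_samples(self) -> int:
        """Total samples per acquisition."""
        return round(self.sampling_rate_hz * self.collection_duration_s)

    @property
    def segment_length(self) -> int:
        """Samples per averaging segment (125 000 at defaults)."""
        return self.n_samples // self.n_segments

    @property
    def period_min(self) -> float:
        return self.acquisition_period_s / 60.0

    def time_of_index(self, index: int) -> float:
        """Minutes since extraction start of acquisition ``index`` (1-based)."""
        return index * self.period_min

    def to_dict(self) -> dict:
        return {
            "sampling_rate_hz": self.sampling_rate_hz,
            "collection_duration_s": self.collection_duration_s,
            "acquisition_period_s": self.acquisition_period_s,
            "n_segments": self.n_segments,
            "gain": self.gain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        known = {k: d[k] for k in
                 ("sampling_rate_hz", "collection_duration_s",
                  "acquisition_period_s", "n_segments", "gain") if k in d}
        return cls(**known)


@dataclass(frozen=True)
class AcquisitionSegment:
    """One time-stamped raw AE waveform plus its acquisition configuration."""

    index: int
    waveform: np.ndarray
    config: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    time_min: float | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ConfigError("acquisition index starts at 1")
        wf = np.asarray(self.waveform, dtype=np.float64)
        object.__setattr__(self, "waveform", wf)
        if wf.ndim != 1:
            raise SampleCountError("waveform must be one-dimensional")
        if wf.size != self.config.n_samples:
            raise SampleCountError(
                f"waveform has {wf.size} samples, config requires "
                f"{self.config.n_samples}")
        if not np.all(np.isfinite(wf)):
            raise NonFiniteSignalError("waveform contains non-finite samples")
        if self.time_min is None:
            object.__setattr__(self, "time_min",
                               self.config.time_of_index(self.index))


@dataclass(frozen=True)
class TemperatureTrace:
    """Time-stamped temperature log: (minutes since start, deg C)."""

    time_min: np.ndarray
    temperature_c: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=np.float64)
        temp = np.asarray(self.temperature_c, dtype=np.float64)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "temperature_c", temp)
        if t.shape != temp.shape or t.ndim != 1:
            raise ConfigError("time and temperature must be 1-D and equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(temp))):
            raise NonFiniteSignalError("temperature trace contains non-finite values")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise NonMonotoneTimeError(
                "temperature log times must be strictly increasing")

    def __len__(self) -> int:
        return self.time_min.size


def _read_sidecar(sidecar_path: str | Path) -> dict:
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise SidecarError(f"metadata sidecar not found: {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise SidecarError(f"sidecar {sidecar_path} is not valid JSON: {exc}")
    if not isinstance(meta, dict) or "sampling_rate_hz" not in meta:
        raise SidecarError(
            f"sidecar {sidecar_path} lacks acquisition configuration")
    return meta


def read_segment(path: str | Path,
                 sidecar_path: str | Path | None = None) -> AcquisitionSegment:
    """Read one acquisition from WAV (IEEE float) or raw float32 binary.

    The JSON sidecar (default: same stem, ``.json`` suffix) carries the
    :class:`AcquisitionConfig` and the acquisition ``index``; the sample count
    of the file is validated against the config.
    """
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(".json")
    meta = _read_sidecar(sidecar_path)
    config = AcquisitionConfig.from_dict(meta)

    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        if rate != round(config.sampling_rate_hz):
            raise SampleCountError(
                f"WAV rate {rate} != configured {config.sampling_rate_hz}")
        waveform = np.asarray(data, dtype=np.float64)
    else:
        waveform = np.fromfile(path, dtype="<f4").astype(np.float64)

    return AcquisitionSegment(
        index=int(meta.get("index", 1)),
        waveform=waveform,
        config=config,
        time_min=meta.get("time_min"),
    )


def write_segment(segment: AcquisitionSegment, path: str | Path,
                  sidecar_path: str | Path | None = None) -> None:
    """Write a segment as ``.wav`` (float32 PCM) or raw ``.f32`` plus sidecar."""
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(".json")
    data = segment.waveform.astype(np.float32)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, round(segment.config.sampling_rate_hz), data)
    else:
        data.astype("<f4").tofile(path)
    meta = segment.config.to_dict()
    meta["index"] = segment.index
    meta["time_min"] = segment.time_min
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_temperature_log(path: str | Path) -> TemperatureTrace:
    """Read a ``time_min,temperature_c`` CSV into a :class:`TemperatureTrace`."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise NonFiniteSignalError(f"unparseable temperature log: {exc}")
    for col in ("time_min", "temperature_c"):
        if col not in df.columns:
            raise NonFiniteSignalError(
                f"temperature log must have a '{col}' column")
    t = pd.to_numeric(df["time_min"], errors="coerce").to_numpy()
    temp = pd.to_numeric(df["temperature_c"], errors="coerce").to_numpy()
    if np.any(np.isnan(t)) or np.any(np.isnan(temp)):
        raise NonFiniteSignalError("temperature log contains unparseable rows")
    return TemperatureTrace(time_min=t, temperature_c=temp)


def write_temperature_log(trace: TemperatureTrace, path: str | Path) -> None:
    pd.DataFrame({"time_min": trace.time_min,
                  "temperature_c": trace.temperature_c}).to_csv(path, index=False)


def time_to_temperature(trace: TemperatureTrace, threshold_c: float) -> float:
    """First time (minutes) the piecewise-linear trace reaches ``threshold_c``.

    This is the industrial boiling criterion time (``t_temp`` at 100 deg C).
    If the trace starts at or above the threshold, its first timestamp is
    returned; if the threshold is never reached,
    :class:`TemperatureNotReachedError` is raised.
    """
    if len(trace) == 0:
        raise TemperatureNotReachedError("empty temperature trace")
    t, temp = trace.time_min, trace.temperature_c
    if temp[0] >= threshold_c:
        return float(t[0])
    above = np.nonzero(temp >= threshold_c)[0]
    if above.size == 0:
        raise TemperatureNotReachedError(
            f"temperature never reaches {threshold_c} C "
            f"(max {temp.max():.2f} C)")
    i = above[0]
    t0, t1 = t[i - 1], t[i]
    y0, y1 = temp[i - 1], temp[i]
    # linear interpolation inside the first crossing interval
    return float(t0 + (threshold_c - y0) / (y1 - y0) * (t1 - t0))
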