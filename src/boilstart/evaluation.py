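"""Performance metrics: absolute error time, time-shortening ratio, carbon.

Three time stamps summarize a run: ``t_ref`` (true onset of discrete
saturated boiling, from bubble observation or simulation truth), ``t_AE``
(the detector's trigger time), and ``t_temp`` (when the temperature log
first reaches the 100 deg C industrial criterion).  From these:

    AET        = | t_ref - t_AE |                      (minutes)
    delta_time = (t_temp - t_AE) / t_temp * 100        (percent saved)
    CE         = EF * EC                               (kg CO2)

with EF the grid electricity carbon-intensity factor (default
0.5153 kg CO2/kWh, the 2022 Zhejiang provincial grid factor) and EC the
metered electricity in kWh.

Replicate batches are reported in mean +/- sample SD form, computing each
metric per replicate first and then averaging (the per-replicate-then-average
convention; note it can differ in the last digit from applying the metric to
the averaged times).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "RunResult",
    "BatchSummary",
    "CARBON_INTENSITY_KG_PER_KWH",
    "aet",
    "delta_time",
    "carbon_emission",
    "summarize",
]

#: 2022 electricity carbon-intensity factor for the Zhejiang provincial grid.
CARBON_INTENSITY_KG_PER_KWH = 0.5153


def aet(t_ref_min: float, t_ae_min: float) -> float:
    """Absolute error time |t_ref - t_AE| in minutes."""
    if t_ref_min < 0 or t_ae_min < 0:
        raise ConfigError("times must be non-negative")
    return abs(t_ref_min - t_ae_min)


def delta_time(t_temp_min: float, t_ae_min: float) -> float:
    """Time-shortening ratio (t_temp - t_AE)/t_temp * 100, in percent.

    Negative when the detector fires later than the 100 deg C criterion.
    """
    if t_temp_min <= 0:
        raise ConfigError("t_temp must be positive")
    return (t_temp_min - t_ae_min) / t_temp_min * 100.0


def carbon_emission(electricity_kwh: float,
                    factor_kg_per_kwh: float = CARBON_INTENSITY_KG_PER_KWH,
                    ) -> float:
    """Carbon emission CE = EF * EC in kg CO2."""
    if electricity_kwh < 0:
        raise ConfigError("electricity consumption must be non-negative")
    return factor_kg_per_kwh * electricity_kwh


@dataclass(frozen=True)
class RunResult:
    """The three time stamps (and optional metered energy) of one run."""

    t_ref_min: float
    t_ae_min: float
    t_temp_min: float | None = None
    electricity_kwh: float | None = None

    def __post_init__(self) -> None:
        for name in ("t_ref_min", "t_ae_min", "t_temp_min", "electricity_kwh"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def aet_min(self) -> float:
        return aet(self.t_ref_min, self.t_ae_min)

    @property
    def delta_time_pct(self) -> float | None:
        if self.t_temp_min is None:
            return None
        return delta_time(self.t_temp_min, self.t_ae_min)


@dataclass(frozen=True)
class BatchSummary:
    """Per-metric mean and sample SD over replicate runs (SD absent at n=1)."""

    n: int
    mean: dict[str, float]
    sd: dict[str, float] | None

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for k, m in self.mean.items():
            rows[k] = {"mean": m,
                       "sd": self.sd[k] if self.sd is not None else math.nan}
        return pd.DataFrame(rows).T

    def __str__(self) -> str:
        parts = [f"n = {self.n}"]
        for k, m in self.mean.items():
            if self.sd is not None:
                parts.append(f"{k}: {m:.2f} +/- {self.sd[k]:.2f}")
            else:
                parts.append(f"{k}: {m:.2f}")
        return "\n".join(parts)


def summarize(results: list[RunResult]) -> BatchSummary:
    """Mean +/- sample SD (divisor n-1) of each metric over replicates."""
    if not results:
        raise ConfigError("cannot summarize an empty batch")
    cols: dict[str, list[float]] = {"t_ref_min": [], "t_ae_min": [],
                                    "aet_min": []}
    have_temp = all(r.t_temp_min is not None for r in results)
    if have_temp:
        cols["t_temp_min"] = []
        cols["delta_time_pct"] = []
    for r in results:
        cols["t_ref_min"].append(r.t_ref_min)
        cols["t_ae_min"].append(r.t_ae_min)
        cols["aet_min"].append(r.aet_min)
        if have_temp:
            cols["t_temp_min"].append(r.t_temp_min)
            cols["delta_time_pct"].append(r.delta_time_pct)
    n = len(results)
    mean = {k: float(np.mean(v)) for k, v in cols.items()}
    sd = ({k: float(np.std(v, ddof=1)) for k, v in cols.items()}
          if n > 1 else None)
    return BatchSummary(n=n, mean=mean, sd=sd)
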