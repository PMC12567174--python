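"""Self-adaptive boiling-onset detector (growing-window PCA, T2 trigger).

The detector re-fits the PCA monitoring model at every new acquisition on the
whole history seen so far (a growing window), starting once ``n_start``
acquisitions (default 10) are available.  At step M the model is fitted on
acquisitions 1..M, the control limit is recomputed from that model, and the
M-th acquisition's Hotelling's T2 is compared with it — the evaluated point
is deliberately *inside* its own training window, which is what makes the
scheme self-starting without any reference batch.  Boiling is declared when
``consecutive_required`` (default 2) successive acquisitions each exceed the
T2 limit of their own growing-window model; the trigger time ``t_AE`` is the
time of the last of those acquisitions, i.e. the moment the decision becomes
available online.

SPE is computed and exposed in the statistic trail for every step but never
used for the decision: on these signals the T2 trajectory separates the
subcooled and saturated stages more reliably.

The alternative convention — fit on 1..M-1 and test point M out-of-window —
is available via ``DetectorConfig(exclude_test_point=True)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .acquisition import AcquisitionSegment
from .errors import ConfigError, DetectorStateError
from .mspc import MonitorRecord, PCAMonitorResults, fit_pca, records_to_frame
from .spectral import FeatureVector, acquisition_to_features

__all__ = [
    "DetectorConfig",
    "DetectorState",
    "DetectionEvent",
    "BoilStartDetector",
    "update",
    "run",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of the adaptive detector (defaults reproduce the method)."""

    n_start: int = 10
    consecutive_required: int = 2
    alpha: float = 0.01
    variance_ratio_threshold: float = 0.05
    band_lo_khz: float = 75.0
    band_hi_khz: float = 100.0
    acquisition_period_s: float = 30.0
    exclude_test_point: bool = False

    def __post_init__(self) -> None:
        if self.n_start < 4:
            raise ConfigError("n_start must be >= 4 (minimum PCA window)")
        if self.consecutive_required < 1:
            raise ConfigError("consecutive_required must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")

    @property
    def period_min(self) -> float:
        return self.acquisition_period_s / 60.0


@dataclass
class DetectorState:
    """Mutable streaming state: history, statistic trail, trigger status."""

    history: list[FeatureVector] = field(default_factory=list)
    trail: list[MonitorRecord] = field(default_factory=list)
    consecutive_count: int = 0
    triggered: bool = False
    trigger_index: int | None = None
    trigger_time_min: float | None = None
    model_snapshot: PCAMonitorResults | None = None

    @property
    def n_seen(self) -> int:
        return len(self.history)


@dataclass(frozen=True)
class DetectionEvent:
    """Outcome of one monitored run: decision, trigger time, statistic trail."""

    triggered: bool
    t_ae_min: float | None
    trigger_index: int | None
    trail: list[MonitorRecord]
    model_snapshot: PCAMonitorResults | None = None

    def summary(self) -> str:
        lines = ["BoilStart detection", "==================="]
        if self.triggered:
            lines += [
                f"triggered:        yes",
                f"trigger index:    {self.trigger_index}",
                f"t_AE:             {self.t_ae_min:.2f} min",
            ]
        else:
            lines.append("triggered:        no (stream exhausted)")
        lines.append(f"evaluated points: {len(self.trail)}")
        if self.model_snapshot is not None:
            lines.append(
                f"model at trigger: A={self.model_snapshot.n_components}, "
                f"N={self.model_snapshot.n_train}, "
                f"T2 limit={self.model_snapshot.t2_limit:.3f}")
        return "\n".join(lines)

    def trail_frame(self):
        return records_to_frame(self.trail)


class BoilStartDetector:
    """Streaming adaptive detector; feed acquisitions with :meth:`update`."""

    def __init__(self, config: DetectorConfig | None = None):
        self.config = config or DetectorConfig()
        self.state = DetectorState()

    def update(self, x: FeatureVector | np.ndarray) -> MonitorRecord | None:
        """Ingest the next acquisition; returns its record once monitoring runs.

        Raises :class:`DetectorStateError` if called after the trigger.
        """
        cfg = self.config
        state = self.state
        if state.triggered:
            raise DetectorStateError("detector already triggered; no updates")
        if not isinstance(x, FeatureVector):
            x = FeatureVector(values=np.asarray(x, dtype=np.float64),
                              band_lo_khz=cfg.band_lo_khz,
                              band_hi_khz=cfg.band_hi_khz,
                              index=state.n_seen + 1,
                              time_min=(state.n_seen + 1) * cfg.period_min)
        if state.history and len(x) != len(state.history[0]):
            raise ConfigError("feature vector length changed mid-stream")
        state.history.append(x)
        m = state.n_seen
        if m < cfg.n_start:
            return None

        X = np.vstack([fv.values for fv in state.history])
        train = X[:-1] if cfg.exclude_test_point else X
        model = fit_pca(train,
                        variance_ratio_threshold=cfg.variance_ratio_threshold,
                        alpha=cfg.alpha)
        t2_m = model.t2(X[-1])
        spe_m = model.spe(X[-1])
        record = MonitorRecord(index=m, time_min=x.time_min,
                               t2=t2_m, t2_limit=model.t2_limit,
                               spe=spe_m, spe_limit=model.spe_limit)
        state.trail.append(record)

        if record.t2_exceeds:
            state.consecutive_count += 1
        else:
            state.consecutive_count = 0
        if state.consecutive_count >= cfg.consecutive_required:
            state.triggered = True
            state.trigger_index = m
            state.trigger_time_min = m * cfg.period_min
            state.model_snapshot = model
        return record

    def event(self) -> DetectionEvent:
        state = self.state
        return DetectionEvent(triggered=state.triggered,
                              t_ae_min=state.trigger_time_min,
                              trigger_index=state.trigger_index,
                              trail=list(state.trail),
                              model_snapshot=state.model_snapshot)

    def run(self, stream: Iterable[FeatureVector | AcquisitionSegment
                                   | np.ndarray]) -> DetectionEvent:
        """Consume a stream through the first trigger (or exhaustion)."""
        cfg = self.config
        for item in stream:
            if isinstance(item, AcquisitionSegment):
                item = acquisition_to_features(item, cfg.band_lo_khz,
                                               cfg.band_hi_khz)
            self.update(item)
            if self.state.triggered:
                break
        if not self.state.triggered and self.state.n_seen < cfg.n_start:
            warnings.warn(
                f"stream ended after {self.state.n_seen} acquisitions, "
                f"before the detector could start (n_start={cfg.n_start})",
                RuntimeWarning, stacklevel=2)
        return self.event()


# ---------------------------------------------------------------------------
# functional surface


def update(state: DetectorState, x: FeatureVector | np.ndarray,
           config: DetectorConfig | None = None,
           ) -> tuple[DetectorState, MonitorRecord | None]:
    """Functional one-step update; returns the (mutated) state and record."""
    det = BoilStartDetector(config)
    det.state = state
    record = det.update(x)
    return det.state, record


def run(stream: Iterable[FeatureVector | AcquisitionSegment | np.ndarray],
        config: DetectorConfig | None = None) -> DetectionEvent:
    """Run the adaptive detector over an ordered acquisition stream."""
    return BoilStartDetector(config).run(stream)
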