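"""Oxygen-desaturation event detection and the classical oximetry biomarkers.

A desaturation episode is a drop in saturation of at least ``drop_pct`` (%)
relative to the trailing mean of the preceding ``baseline_win_s`` seconds,
sustained for at least ``min_dur_s`` seconds.  From the detected events the
module derives the biomarkers used throughout apnea screening:

ODI     events per hour of recording
POD     fraction of recording time spent inside events
AODmax  event area below the pre-event local maximum, per second of recording
AOD100  event area below the 100 % level, per second of recording
CA      integral of saturation deficit below a fixed level (default 93 %),
        per second of recording
M       percentage of samples at least ``m_offset`` (%) below the median

Durations are measured in seconds (samples x dt), so the same configuration
applies unchanged to coarse-grained series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .series import DomainError, SpO2Series

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesatConfig:
    """Detection and biomarker parameters (all durations in seconds)."""

    drop_pct: float = 3.0
    min_dur_s: float = 10.0
    baseline_win_s: float = 120.0
    ca_threshold: float = 93.0
    m_offset: float = 2.0

    def __post_init__(self) -> None:
        if min(self.drop_pct, self.min_dur_s, self.baseline_win_s,
               self.ca_threshold, self.m_offset) <= 0:
            raise DomainError("all DesatConfig parameters must be positive")
        if self.min_dur_s < 1:
            raise DomainError("min_dur_s must be >= 1 s")
        if self.baseline_win_s < self.min_dur_s:
            raise DomainError("baseline_win_s must be >= min_dur_s")


@dataclass(frozen=True)
class DesaturationEvent:
    """One detected desaturation episode."""

    start_s: float
    dur_s: float
    nadir_pct: float
    depth_pct: float
    area_max: float  # %·s below the pre-event local maximum
    area_100: float  # %·s below the 100 % level


def detect_desaturations(
    series: SpO2Series, cfg: DesatConfig | None = None
) -> list[DesaturationEvent]:
    """Find maximal runs below (trailing baseline − drop_pct) lasting >= min_dur_s.

    The trailing baseline is the mean of valid samples in the preceding
    ``baseline_win_s`` seconds (a shorter prefix is allowed near the start of
    the recording, minimum one valid sample) and is frozen at event onset; an
    event ends when a valid sample rises back above (onset baseline − drop).
    Returned events are disjoint and time-ordered.
    """
    cfg = cfg or DesatConfig()
    if series.n_valid == 0:
        raise DomainError("series has no valid samples")
    if series.duration_s < cfg.min_dur_s:
        logger.warning(
            "recording shorter than min_dur_s (%.0f s); no events detectable",
            cfg.min_dur_s,
        )
        return []

    dt = series.dt_s
    v = series.values
    ok = series.valid_mask
    n = len(series)
    win = max(1, int(round(cfg.baseline_win_s / dt)))

    # trailing mean over [i-win, i), exclusive of the current sample
    cs = np.concatenate(([0.0], np.cumsum(np.where(ok, v, 0.0))))
    cn = np.concatenate(([0], np.cumsum(ok.astype(np.int64))))
    lo = np.maximum(np.arange(n) - win, 0)
    counts = cn[np.arange(n)] - cn[lo]
    sums = cs[np.arange(n)] - cs[lo]
    baseline = np.full(n, np.nan)
    np.divide(sums, counts, out=baseline, where=counts > 0)

    events: list[DesaturationEvent] = []
    i = 0
    while i < n:
        if ok[i] and counts[i] > 0 and v[i] <= baseline[i] - cfg.drop_pct:
            onset_baseline = baseline[i]
            start = i
            j = i + 1
            while j < n:
                if ok[j] and v[j] > onset_baseline - cfg.drop_pct:
                    break
                j += 1
            dur = (j - start) * dt
            if dur >= cfg.min_dur_s:
                seg_ok = ok[start:j]
                seg = v[start:j][seg_ok]
                nadir = float(seg.min())
                ref = _pre_event_maximum(v, ok, start, win)
                area_max = float(np.clip(ref - seg, 0.0, None).sum()) * dt
                area_100 = float((100.0 - seg).sum()) * dt
                events.append(
                    DesaturationEvent(
                        start_s=start * dt,
                        dur_s=dur,
                        nadir_pct=nadir,
                        depth_pct=float(onset_baseline - nadir),
                        area_max=area_max,
                        area_100=area_100,
                    )
                )
            i = j
        else:
            i += 1
    return events


def _pre_event_maximum(v: np.ndarray, ok: np.ndarray, start: int, win: int) -> float:
    """Local reference level: maximum valid value in the window before onset."""
    lo = max(0, start - win)
    seg = v[lo:start][ok[lo:start]]
    if seg.size == 0:  # event at the very start; fall back to the onset value
        return float(v[start])
    return float(seg.max())


@dataclass(frozen=True)
class OximetryMarkers:
    odi: float
    pod: float
    aod_max: float
    aod_100: float
    ca: float
    m: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ODI": self.odi,
            "POD": self.pod,
            "AODmax": self.aod_max,
            "AOD100": self.aod_100,
            "CA": self.ca,
            "M": self.m,
        }


def oximetry_markers(
    series: SpO2Series,
    events: list[DesaturationEvent] | None = None,
    cfg: DesatConfig | None = None,
) -> OximetryMarkers:
    """Compute the event-based and level-based biomarkers for one recording.

    ``events`` defaults to running :func:`detect_desaturations` on the series.
    All area measures are normalised by the total recording time.
    """
    cfg = cfg or DesatConfig()
    if len(series) == 0 or series.n_valid == 0:
        raise DomainError("series has no valid samples")
    if events is None:
        events = detect_desaturations(series, cfg)

    total_s = series.duration_s
    hours = total_s / 3600.0
    valid = series.valid_values()
    dt = series.dt_s

    odi = len(events) / hours
    pod = sum(e.dur_s for e in events) / total_s
    aod_max = sum(e.area_max for e in events) / total_s
    aod_100 = sum(e.area_100 for e in events) / total_s
    ca = float(np.clip(cfg.ca_threshold - valid, 0.0, None).sum()) * dt / total_s
    median = float(np.median(valid))
    m = 100.0 * float((valid <= median - cfg.m_offset).sum()) / valid.size
    return OximetryMarkers(odi=odi, pod=pod, aod_max=aod_max,
                           aod_100=aod_100, ca=ca, m=m)
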