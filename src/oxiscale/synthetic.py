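"""Synthetic overnight oximetry with programmable ground truth.

A simulated recording is a 1 Hz saturation trace built from

* a baseline near 96.5 % with a slow sinusoidal drift and white measurement
  noise, clipped at 100 %;
* apnea-linked desaturation episodes: trapezoidal dips (ramp down, plateau at
  baseline − depth, ramp up) whose onset lags the underlying respiratory
  event by 10–40 s, with depths of 3–10 % and plateau durations of 15–60 s;
* isolated artifact samples below 60 % (to be masked by cleaning).

Event times come from a Poisson process thinned with a hard-core spacing
(``min_gap_s``); the ground-truth AHI is always the *realised* event count per
hour, never the nominal rate.  With ``exact_count=True`` the generator places
exactly ``round(true_rate * duration_h)`` events instead, for tests that need
a known count.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .series import DomainError, SpO2Series

logger = logging.getLogger(__name__)

#: multiclass mix of an SHHS-like cohort: normal/mild/moderate/severe fractions
SHHS_MIX = (0.1359, 0.3842, 0.3032, 0.1767)
_MIX_BANDS = ((0.5, 5.0), (5.0, 15.0), (15.0, 30.0), (30.0, 45.0))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters (times in seconds unless suffixed ``_h``)."""

    duration_h: float = 8.0
    true_rate: float = 10.0  # nominal events per hour
    baseline_mean: float = 96.5
    baseline_sd: float = 0.4  # slow-drift amplitude, %
    noise_sd: float = 0.3  # per-sample measurement noise, %
    depth_range: tuple[float, float] = (3.0, 10.0)
    event_dur_range_s: tuple[float, float] = (15.0, 60.0)
    onset_delay_range_s: tuple[float, float] = (10.0, 40.0)
    ramp_range_s: tuple[float, float] = (5.0, 15.0)
    min_gap_s: float = 130.0  # > the 120 s detection baseline window
    artifact_rate_per_h: float = 1.0
    drift_period_s: float = 3600.0
    noise_smooth_s: int = 6  # oximeter internal moving-average width; 1 = white
    quantize_step: float = 1.0  # output resolution in %, 0 disables rounding
    depth_skew_scale: float = 0.9  # exponential scale of depth above the minimum
    depth_rate_coupling: float = 0.0  # fractional skew-scale increase at 60 ev/h
    major_event_prob: float = 0.0045  # chance an event is a prolonged deep one
    major_dur_mult: float = 3.0  # plateau-duration multiplier of major events
    exact_count: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("depth_range", "event_dur_range_s",
                     "onset_delay_range_s", "ramp_range_s"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise DomainError(f"{name} must be an ordered non-negative range")
        if self.true_rate < 0 or self.artifact_rate_per_h < 0:
            raise DomainError("rates must be non-negative")
        if self.min_gap_s <= 0:
            raise DomainError("min_gap_s must be positive")

    @property
    def max_footprint_s(self) -> float:
        """Largest possible desaturation extent (both ramps + plateau)."""
        return self.event_dur_range_s[1] + 2 * self.ramp_range_s[1]


@dataclass(frozen=True)
class TruthEvent:
    """One programmed desaturation: onset of the saturation dip (not of the
    respiratory event, which precedes it by ``delay_s``)."""

    onset_s: float
    dur_s: float  # plateau duration at full depth
    depth_pct: float
    ramp_down_s: float
    ramp_up_s: float
    delay_s: float

    @property
    def total_dur_s(self) -> float:
        return self.ramp_down_s + self.dur_s + self.ramp_up_s


@dataclass(frozen=True)
class SimulatedRecord:
    series: SpO2Series
    truth_events: tuple[TruthEvent, ...]
    true_ahi: float


def _check_feasible(cfg: SimConfig) -> None:
    duration_s = cfg.duration_h * 3600.0
    expected = cfg.true_rate * cfg.duration_h
    need = expected * (cfg.max_footprint_s + cfg.min_gap_s)
    if need >= duration_s:
        raise DomainError(
            f"infeasible config: {expected:.0f} expected events x "
            f"({cfg.max_footprint_s:.0f} s footprint + {cfg.min_gap_s:.0f} s gap) "
            f"= {need:.0f} s >= recording length {duration_s:.0f} s"
        )


def _draw_depth(rng: np.random.Generator, cfg: SimConfig) -> float:
    """Desaturation depth, right-skewed within ``depth_range``: most events sit
    just above the minimum (near-criterion hypopneic dips), deep ones are rare."""
    lo, hi = cfg.depth_range
    if cfg.depth_skew_scale <= 0 or hi == lo:
        return float(rng.uniform(lo, hi))
    # severe apnea desaturates deeper: the skew scale grows with the event rate
    scale = cfg.depth_skew_scale * (
        1.0 + cfg.depth_rate_coupling * min(cfg.true_rate, 60.0) / 60.0
    )
    return float(min(hi, lo + rng.exponential(scale)))


def _draw_event_shapes(rng: np.random.Generator, cfg: SimConfig, k: int) -> list[dict]:
    shapes = []
    for _ in range(k):
        shape = {
            "dur": rng.uniform(*cfg.event_dur_range_s),
            "depth": _draw_depth(rng, cfg),
            "rd": rng.uniform(*cfg.ramp_range_s),
            "ru": rng.uniform(*cfg.ramp_range_s),
            "delay": rng.uniform(*cfg.onset_delay_range_s),
        }
        if rng.random() < cfg.major_event_prob:
            # prolonged deep desaturation (e.g. REM-related apnea cluster)
            lo, hi = cfg.depth_range
            shape["dur"] *= cfg.major_dur_mult
            shape["depth"] = float(rng.uniform(lo + 0.7 * (hi - lo), hi))
        shapes.append(shape)
    return shapes


def _place_exact(rng: np.random.Generator, shapes: list[dict],
                 duration_s: float, min_gap_s: float) -> list[float]:
    """Exactly len(shapes) onsets with pairwise spacing >= min_gap_s."""
    k = len(shapes)
    if k == 0:
        return []
    footprints = [s["rd"] + s["dur"] + s["ru"] for s in shapes]
    # leading delay margin so the first event never starts at t=0
    required = sum(footprints) + (k - 1) * min_gap_s + min_gap_s
    free = duration_s - required
    if free < 0:
        raise DomainError(
            f"cannot place {k} events with spacing {min_gap_s:.0f} s in "
            f"{duration_s:.0f} s (needs {required:.0f} s)"
        )
    cuts = np.sort(rng.uniform(0.0, free, size=k))
    slack = np.diff(np.concatenate(([0.0], cuts)))
    onsets = []
    t = min_gap_s
    for i in range(k):
        t += slack[i]
        onsets.append(t)
        t += footprints[i] + min_gap_s
    return onsets


def _place_poisson(rng: np.random.Generator, cfg: SimConfig,
                   duration_s: float) -> list[dict]:
    """Poisson candidate onsets thinned by a hard-core (non-paralyzable) rule.

    The nominal intensity is inflated by the dead-time correction
    lambda = r / (1 - r * tau), tau = mean footprint + gap, so the *realised*
    rate tracks the requested one despite thinning.
    """
    mean_fp = (np.mean(cfg.event_dur_range_s) + 2 * np.mean(cfg.ramp_range_s))
    tau_h = (mean_fp + cfg.min_gap_s) / 3600.0
    r = cfg.true_rate
    lam = r / max(1e-9, 1.0 - r * tau_h) if r * tau_h < 0.95 else 20.0 * r
    n_cand = rng.poisson(lam * cfg.duration_h)
    onsets = np.sort(rng.uniform(cfg.min_gap_s, duration_s, size=n_cand))
    shapes = _draw_event_shapes(rng, cfg, n_cand)
    placed = []
    t_free = 0.0
    for onset, shape in zip(onsets, shapes):
        fp = shape["rd"] + shape["dur"] + shape["ru"]
        if onset >= t_free and onset + fp + cfg.min_gap_s <= duration_s:
            shape["onset"] = float(onset)
            placed.append(shape)
            t_free = onset + fp + cfg.min_gap_s
    return placed


def simulate_record(cfg: SimConfig | None = None, subject_id: str = "sim") -> SimulatedRecord:
    """Generate one annotated 1 Hz recording; identical seeds give identical traces."""
    cfg = cfg or SimConfig()
    _check_feasible(cfg)
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_h * 3600.0))
    duration_s = float(n)
    t = np.arange(n, dtype=float)

    phase = rng.uniform(0.0, 2 * np.pi)
    trace = (
        cfg.baseline_mean
        + cfg.baseline_sd * np.sin(2 * np.pi * t / cfg.drift_period_s + phase)
        + _measurement_noise(rng, cfg, n)
    )

    if cfg.exact_count:
        k = int(round(cfg.true_rate * cfg.duration_h))
        shapes = _draw_event_shapes(rng, cfg, k)
        onsets = _place_exact(rng, shapes, duration_s, cfg.min_gap_s)
        for shape, onset in zip(shapes, onsets):
            shape["onset"] = onset
        placed = shapes
    else:
        placed = _place_poisson(rng, cfg, duration_s)

    events = []
    for s in placed:
        onset = s["onset"]
        dip = _trapezoid(t, onset, s["rd"], s["dur"], s["ru"], s["depth"])
        trace -= dip
        events.append(TruthEvent(onset_s=onset, dur_s=s["dur"], depth_pct=s["depth"],
                                 ramp_down_s=s["rd"], ramp_up_s=s["ru"],
                                 delay_s=s["delay"]))

    np.clip(trace, 0.0, 100.0, out=trace)
    if cfg.quantize_step > 0:
        trace = np.round(trace / cfg.quantize_step) * cfg.quantize_step

    n_art = rng.poisson(cfg.artifact_rate_per_h * cfg.duration_h)
    if n_art:
        pos = rng.integers(0, n, size=n_art)
        trace[pos] = rng.uniform(20.0, 55.0, size=n_art)

    series = SpO2Series(subject_id=subject_id, values=trace, dt_s=1.0, scale_s=1)
    return SimulatedRecord(
        series=series,
        truth_events=tuple(events),
        true_ahi=len(events) / cfg.duration_h,
    )


def _measurement_noise(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Sensor noise: white per-sample noise of SD ``noise_sd`` passed through the
    oximeter's internal moving average (``noise_smooth_s`` samples), which
    attenuates it by sqrt(width) and leaves it autocorrelated — real 1 Hz
    oximetry is much smoother than white noise."""
    if cfg.noise_sd <= 0:
        return np.zeros(n)
    k = max(1, int(cfg.noise_smooth_s))
    w = rng.normal(0.0, cfg.noise_sd, size=n + k - 1)
    if k == 1:
        return w[:n]
    return np.convolve(w, np.ones(k) / k, mode="valid")[:n]


def _trapezoid(t: np.ndarray, onset: float, rd: float, dur: float,
               ru: float, depth: float) -> np.ndarray:
    """Piecewise-linear dip profile: 0 before onset, ramp to `depth`, plateau,
    ramp back to 0."""
    dip = np.zeros_like(t)
    x = t - onset
    down = (x >= 0) & (x < rd)
    dip[down] = depth * x[down] / max(rd, 1e-9)
    plat = (x >= rd) & (x < rd + dur)
    dip[plat] = depth
    up = (x >= rd + dur) & (x < rd + dur + ru)
    dip[up] = depth * (1.0 - (x[up] - rd - dur) / max(ru, 1e-9))
    return dip


def _adapt_for_rate(cfg: SimConfig, rate: float) -> SimConfig:
    """Shrink spacing and event durations when a nominal rate cannot fit.

    Severe apnea produces back-to-back events with short recovery intervals,
    so for high rates the inter-event gap and plateau durations shorten; the
    defaults are kept whenever they are feasible.
    """
    cfg = replace(cfg, true_rate=rate)
    if rate <= 0:
        return cfg
    budget = 3600.0 / rate * 0.85  # per-event time budget with safety margin
    if cfg.max_footprint_s + cfg.min_gap_s < budget:
        return cfg
    gap = max(15.0, budget * 0.55)
    ramp_hi = min(cfg.ramp_range_s[1], max(3.0, budget * 0.08))
    ramp_lo = min(cfg.ramp_range_s[0], ramp_hi)
    dur_hi = max(12.0, budget - gap - 2 * ramp_hi)
    dur_lo = min(cfg.event_dur_range_s[0], dur_hi)
    return replace(
        cfg,
        min_gap_s=gap,
        ramp_range_s=(ramp_lo, ramp_hi),
        event_dur_range_s=(dur_lo, dur_hi),
    )


RateSampler = Callable[[np.random.Generator], float]


def uniform_rates(lo: float, hi: float) -> RateSampler:
    def sample(rng: np.random.Generator) -> float:
        return float(rng.uniform(lo, hi))

    return sample


def shhs_mix_rates(mix: Sequence[float] = SHHS_MIX) -> RateSampler:
    """Severity-class mixture emulating a large clinical cohort: the class is
    drawn from ``mix`` and the nominal rate uniformly within the class band."""

    def sample(rng: np.random.Generator) -> float:
        cls = rng.choice(len(mix), p=np.asarray(mix) / np.sum(mix))
        lo, hi = _MIX_BANDS[cls]
        return float(rng.uniform(lo, hi))

    return sample


def parse_rate_spec(spec: str) -> RateSampler:
    """``uniform:LO:HI`` or ``shhs-mix``."""
    if spec == "shhs-mix":
        return shhs_mix_rates()
    parts = spec.split(":")
    if len(parts) == 3 and parts[0] == "uniform":
        return uniform_rates(float(parts[1]), float(parts[2]))
    raise ValueError(f"unknown rate spec {spec!r}")


def simulate_cohort(
    n: int,
    rate_sampler: RateSampler | str,
    cfg_base: SimConfig | None = None,
    seed: int = 0,
) -> tuple[list[SimulatedRecord], pd.DataFrame]:
    """Generate ``n`` independent records plus their label table.

    Per-subject seeds are spawned from the master ``seed``; the label table has
    columns ``subject_id`` and ``ahi`` (= realised true AHI).
    """
    if n < 1:
        raise DomainError("cohort size must be >= 1")
    cfg_base = cfg_base or SimConfig()
    if isinstance(rate_sampler, str):
        rate_sampler = parse_rate_spec(rate_sampler)
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n)
    rate_seeds = master.integers(0, 2**31 - 1, size=n)
    rates = [rate_sampler(np.random.default_rng(s)) for s in rate_seeds]
    # one event morphology for the whole cohort (feasible at the largest nominal
    # rate), so severity is driven by the event *rate* alone, not by shape
    cfg_cohort = _adapt_for_rate(cfg_base, max(rates))
    records = []
    rows = []
    for i in range(n):
        cfg = replace(cfg_cohort, true_rate=rates[i], seed=int(child_seeds[i]))
        sid = f"s{i:04d}"
        rec = simulate_record(cfg, subject_id=sid)
        records.append(rec)
        rows.append({"subject_id": sid, "ahi": rec.true_ahi})
    return records, pd.DataFrame(rows)
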