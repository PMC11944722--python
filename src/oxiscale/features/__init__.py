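"""Feature bank: statistical, entropy and complexity descriptors of a series.

Every feature is a pure function of one (possibly coarse-grained) series.
Entropy/complexity features operate on the valid samples concatenated in time
order (masked gaps closed); the oximetry biomarkers keep the time axis.  A
feature that cannot be computed (series too short, no anchors, infeasible DFA
range) is reported as ``nan`` — per-feature degradation, never an exception —
which feeds the downstream missingness filter naturally.

Additional features can be registered with :func:`register_feature`; names
must not collide with the built-in bank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable

import numpy as np

from ..desaturation import DesatConfig, oximetry_markers
from ..series import SpO2Series
from . import complexity as _cx
from . import entropy as _en
from . import statistical as _st

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the feature bank.

    Embedding dimensions (``*_m``), the tolerance fraction ``r_frac`` (times
    the series SD, shared by the tolerance-based entropies) and the symbolic
    alphabet sizes follow the conventional defaults of each estimator.
    """

    apen_m: int = 1
    r_frac: float = 0.25
    sampen_m: int = 1
    fuzzen_m: int = 2
    fuzzen_exp: float = 2.0
    permen_order: int = 3
    permen_delay: int = 1
    dispen_classes: int = 6
    dispen_m: int = 2
    incren_quant: int = 4
    incren_m: int = 2
    k2en_m: int = 2
    conden_classes: int = 6
    conden_max_order: int = 5
    disten_m: int = 2
    disten_bins: int = 512
    phasen_sectors: int = 8
    ctm_radius: float = 0.25
    prsa_d: int = 10
    dfa_win_min: int = 4
    dfa_n_windows: int = 12
    shannon_bin_edges: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.arange(59.5, 101.0, 1.0))
    )

    def __post_init__(self) -> None:
        if self.permen_order < 2 or self.dispen_classes < 2:
            raise ValueError("permen_order and dispen_classes must be >= 2")
        if self.ctm_radius <= 0 or self.r_frac <= 0:
            raise ValueError("radii/tolerances must be positive")


_STAT_FUNCS: Dict[str, Callable[[np.ndarray, FeatureConfig], float]] = {
    "mean_abs_change": lambda x, c: _st.mean_abs_change(x),
    "kurtosis": lambda x, c: _st.kurtosis(x),
    "variance": lambda x, c: _st.variance(x),
    "zc": lambda x, c: _st.zero_crossing_rate(x),
    "hjm": lambda x, c: _st.hjorth_mobility(x),
    "hjc": lambda x, c: _st.hjorth_complexity(x),
    "ctm": lambda x, c: _st.central_tendency_measure(x, c.ctm_radius),
}

_ENTROPY_FUNCS: Dict[str, Callable[[np.ndarray, FeatureConfig], float]] = {
    "ApEn": lambda x, c: _en.approximate_entropy(x, c.apen_m, c.r_frac),
    "SampEn": lambda x, c: _en.sample_entropy(x, c.sampen_m, c.r_frac),
    "FuzzEn": lambda x, c: _en.fuzzy_entropy(x, c.fuzzen_m, c.r_frac, c.fuzzen_exp),
    "PermEn": lambda x, c: _en.permutation_entropy(x, c.permen_order, c.permen_delay),
    "ShannonEn": lambda x, c: _en.shannon_entropy(x, np.asarray(c.shannon_bin_edges)),
    "DispEn": lambda x, c: _en.dispersion_entropy(x, c.dispen_classes, c.dispen_m),
    "IncrEn": lambda x, c: _en.increment_entropy(x, c.incren_quant, c.incren_m),
    "K2En": lambda x, c: _en.k2_entropy(x, c.k2en_m, c.r_frac),
    "CondEn": lambda x, c: _en.conditional_entropy(x, c.conden_classes, c.conden_max_order),
    "DistEn": lambda x, c: _en.distribution_entropy(x, c.disten_m, c.disten_bins),
    "PhasEn": lambda x, c: _en.phase_entropy(x, c.phasen_sectors),
    "ComplexEn": lambda x, c: _en.complexity_entropy(x, c.permen_order, c.permen_delay),
}

_COMPLEXITY_FUNCS: Dict[str, Callable[[np.ndarray, FeatureConfig], float]] = {
    "LZ": lambda x, c: _cx.lempel_ziv_complexity(x),
    "alpha": lambda x, c: _cx.dfa_alpha(x, c.dfa_win_min, n_windows=c.dfa_n_windows,
                                        overlap=False),
    "alphaOverlap": lambda x, c: _cx.dfa_alpha(x, c.dfa_win_min,
                                               n_windows=c.dfa_n_windows, overlap=True),
    "PRSAc": lambda x, c: _cx.prsa_capacity(x, c.prsa_d),
}

MARKER_NAMES = ("ODI", "POD", "AODmax", "AOD100", "CA", "M")


def _apply(funcs: Dict[str, Callable], series: SpO2Series,
           cfg: FeatureConfig) -> Dict[str, float]:
    x = series.valid_values()
    out = {}
    for name, fn in funcs.items():
        try:
            out[name] = float(fn(x, cfg))
        except Exception as exc:
            logger.warning("feature %s failed on %s: %s", name, series.subject_id, exc)
            out[name] = float("nan")
    return out


def statistical_features(series: SpO2Series, cfg: FeatureConfig | None = None) -> Dict[str, float]:
    return _apply(_STAT_FUNCS, series, cfg or FeatureConfig())


def entropy_features(series: SpO2Series, cfg: FeatureConfig | None = None) -> Dict[str, float]:
    if series.n_valid < 10:
        logger.warning("series %s: <10 valid samples, entropy features missing",
                       series.subject_id)
        return {k: float("nan") for k in _ENTROPY_FUNCS}
    return _apply(_ENTROPY_FUNCS, series, cfg or FeatureConfig())


def complexity_features(series: SpO2Series, cfg: FeatureConfig | None = None) -> Dict[str, float]:
    return _apply(_COMPLEXITY_FUNCS, series, cfg or FeatureConfig())


#: user-registered extra features: name -> callable(series, cfg) -> float
EXTRA_FEATURES: Dict[str, Callable[[SpO2Series, FeatureConfig], float]] = {}


def register_feature(name: str, func: Callable[[SpO2Series, FeatureConfig], float]) -> None:
    """Add a custom feature to the bank; the name must be new."""
    if name in feature_names() or name in EXTRA_FEATURES:
        raise ValueError(f"feature name {name!r} already registered")
    EXTRA_FEATURES[name] = func


def feature_names() -> tuple[str, ...]:
    """All built-in feature names, in extraction order."""
    return (*_STAT_FUNCS, *_ENTROPY_FUNCS, *_COMPLEXITY_FUNCS, *MARKER_NAMES)


def extract_all(
    series: SpO2Series,
    cfg: FeatureConfig | None = None,
    desat_cfg: DesatConfig | None = None,
    include: Iterable[str] | None = None,
) -> Dict[str, float]:
    """Feature vector for one series: statistics, entropies, complexity
    measures and oximetry biomarkers, with ``nan`` for per-feature failures.

    ``include`` restricts computation to the named features (unknown names
    raise); by default the whole bank is computed.
    """
    cfg = cfg or FeatureConfig()
    desat_cfg = desat_cfg or DesatConfig()
    wanted = set(feature_names()) | set(EXTRA_FEATURES) if include is None else set(include)
    unknown = wanted - set(feature_names()) - set(EXTRA_FEATURES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")

    out: Dict[str, float] = {}
    x = series.valid_values()
    short_for_entropy = x.size < 10
    for group in (_STAT_FUNCS, _ENTROPY_FUNCS, _COMPLEXITY_FUNCS):
        for name, fn in group.items():
            if name not in wanted:
                continue
            if group is _ENTROPY_FUNCS and short_for_entropy:
                out[name] = float("nan")
                continue
            try:
                out[name] = float(fn(x, cfg))
            except Exception as exc:
                logger.warning("feature %s failed on %s: %s",
                               name, series.subject_id, exc)
                out[name] = float("nan")
    if wanted & set(MARKER_NAMES):
        try:
            markers = oximetry_markers(series, cfg=desat_cfg).as_dict()
        except Exception as exc:
            logger.warning("series %s: oximetry markers failed (%s)",
                           series.subject_id, exc)
            markers = {k: float("nan") for k in MARKER_NAMES}
        out.update({k: v for k, v in markers.items() if k in wanted})
    for name, func in EXTRA_FEATURES.items():
        if name not in wanted:
            continue
        try:
            out[name] = float(func(series, cfg))
        except Exception as exc:
            logger.warning("extra feature %s failed: %s", name, exc)
            out[name] = float("nan")
    return out
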