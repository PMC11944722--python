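"""Canonical SpO2 time-series container and the physiological-range cleaning rule.

A pulse-oximetry trace is represented as a fixed-clock array of saturation
values (percent) plus a per-sample validity mask.  Cleaning never deletes
samples -- out-of-range readings are *masked* so that window-based biomarkers
downstream keep an intact 1 Hz clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import numpy.typing as npt

logger = logging.getLogger(__name__)

#: Physiological saturation range; readings strictly outside are artifacts.
SPO2_MIN = 60.0
SPO2_MAX = 100.0


class DomainError(ValueError):
    """Raised when an operation's physiological or structural precondition fails."""


@dataclass(frozen=True)
class SpO2Series:
    """One subject's saturation trace on a uniform clock.

    Parameters
    ----------
    subject_id
        Identifier of the recording.
    values
        Saturation in percent, one sample per ``dt_s`` seconds.
    valid_mask
        Per-sample validity; ``False`` marks removed/missing samples.  Invalid
        samples keep their stored value but must be ignored by all statistics.
    dt_s
        Sampling interval in seconds (1.0 at native resolution).
    scale_s
        Coarse-graining timescale tag in seconds (1 for a native series).
    """

    subject_id: str
    values: npt.NDArray[np.float64]
    valid_mask: npt.NDArray[np.bool_] = field(default=None)  # type: ignore[assignment]
    dt_s: float = 1.0
    scale_s: int = 1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        mask = self.valid_mask
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        object.__setattr__(self, "valid_mask", mask)
        if values.ndim != 1:
            raise DomainError("values must be one-dimensional")
        if mask.shape != values.shape:
            raise DomainError("valid_mask length must match values")
        if not self.dt_s > 0:
            raise DomainError("dt_s must be positive")
        if self.scale_s < 1:
            raise DomainError("scale_s must be >= 1")

    def __len__(self) -> int:
        return int(self.values.shape[0])

    @property
    def duration_s(self) -> float:
        """Total recording span in seconds (masked samples included)."""
        return len(self) * self.dt_s

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> npt.NDArray[np.float64]:
        """Valid samples concatenated in time order (gaps closed)."""
        return self.values[self.valid_mask]

    def replace(self, **kwargs) -> "SpO2Series":
        return replace(self, **kwargs)


def clean_spo2(raw: SpO2Series) -> SpO2Series:
    """Mask saturation readings outside the physiological range.

    Values strictly below 60 % or strictly above 100 % are measurement
    artifacts and get ``valid_mask=False``; the boundary values 60.0 and 100.0
    are retained.  Values themselves are never altered, so the operation is
    idempotent and keeps the series time-aligned.
    """
    if len(raw) == 0:
        raise DomainError("cannot clean an empty series")
    out_of_range = (raw.values < SPO2_MIN) | (raw.values > SPO2_MAX)
    n_removed = int((out_of_range & raw.valid_mask).sum())
    if n_removed:
        logger.info(
            "clean_spo2(%s): masked %d/%d out-of-range samples",
            raw.subject_id, n_removed, len(raw),
        )
    return raw.replace(valid_mask=raw.valid_mask & ~out_of_range)
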