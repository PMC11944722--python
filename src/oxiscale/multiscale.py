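"""Coarse-graining of SpO2 series over a grid of timescales.

Coarse-graining at timescale ``tau`` replaces the native 1 Hz series by the
means of consecutive non-overlapping tau-second windows, acting as a low-pass
averaging filter.  The standard grid spans 1-10 s in 1 s steps, 15-60 s in
5 s steps and 120-600 s in 60 s steps (29 scales, native scale included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .series import DomainError, SpO2Series


@dataclass(frozen=True)
class TimescaleGrid:
    """Strictly increasing sequence of integer timescales in seconds."""

    scales_s: tuple[int, ...]

    def __post_init__(self) -> None:
        scales = tuple(int(s) for s in self.scales_s)
        object.__setattr__(self, "scales_s", scales)
        if not scales:
            raise DomainError("grid must contain at least one scale")
        if any(s < 1 for s in scales):
            raise DomainError("all timescales must be >= 1 s")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise DomainError("timescales must be strictly increasing")

    def __iter__(self):
        return iter(self.scales_s)

    def __len__(self) -> int:
        return len(self.scales_s)


def standard_grid() -> TimescaleGrid:
    """The 29-scale study grid: {1..10} ∪ {15,20,...,60} ∪ {120,180,...,600}."""
    scales = list(range(1, 11)) + list(range(15, 61, 5)) + list(range(120, 601, 60))
    return TimescaleGrid(tuple(scales))


def coarse_grain(series: SpO2Series, tau: int) -> SpO2Series:
    """Average a native series over non-overlapping windows of ``tau`` samples.

    Output sample ``j`` is the mean of the *valid* samples in window
    ``[j*tau, (j+1)*tau)``; a window with no valid sample yields a masked
    output.  The trailing remainder shorter than ``tau`` is discarded, so the
    output has ``floor(n / tau)`` samples at ``dt_s = scale_s = tau``.
    """
    if not float(tau).is_integer() or tau < 1:
        raise DomainError(f"tau must be a positive integer, got {tau!r}")
    tau = int(tau)
    if series.scale_s != 1:
        raise DomainError("coarse_grain expects a native-resolution series")
    if tau == 1:
        return series
    n_windows = len(series) // tau
    v = series.values[: n_windows * tau].reshape(n_windows, tau)
    m = series.valid_mask[: n_windows * tau].reshape(n_windows, tau)
    counts = m.sum(axis=1)
    sums = np.where(m, v, 0.0).sum(axis=1)
    out_mask = counts > 0
    out_values = np.full(n_windows, np.nan)
    np.divide(sums, counts, out=out_values, where=out_mask)
    # masked outputs carry a placeholder value; mask is authoritative
    out_values[~out_mask] = 0.0
    return SpO2Series(
        subject_id=series.subject_id,
        values=out_values,
        valid_mask=out_mask,
        dt_s=series.dt_s * tau,
        scale_s=tau,
    )


def coarse_grain_all(
    series: SpO2Series, grid: TimescaleGrid | Sequence[int] | None = None
) -> Dict[int, SpO2Series]:
    """Coarse-grain a native series at every scale of ``grid`` (default: standard)."""
    if grid is None:
        grid = standard_grid()
    return {int(tau): coarse_grain(series, int(tau)) for tau in grid}
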