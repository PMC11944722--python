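"""Readers and writers for SpO2 signals and AHI label tables.

Supported signal containers are EDF (the format polysomnography studies
distribute) and a two-column delimited text dialect ``time_s,spo2_percent``.
Label tables are delimited text keyed by ``subject_id``; the default AHI
column name follows the NSRR convention (``nsrr_ahi_hp3r_aasm15``, the
AASM-2015 hypopnea scoring).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .series import DomainError, SpO2Series

logger = logging.getLogger(__name__)

#: Default AHI column name in NSRR-style exports.
DEFAULT_AHI_COLUMN = "nsrr_ahi_hp3r_aasm15"

#: Channel labels tried (case-insensitively) when reading EDF oximetry.
DEFAULT_EDF_ALIASES = ("SaO2", "SpO2", "OSAT", "SAO2-SAO2")


class ChannelNotFoundError(KeyError):
    """The requested oximetry channel is absent from the EDF file."""


class FormatError(ValueError):
    """The file does not conform to the expected dialect."""


class IntegrityError(ValueError):
    """A label table violates uniqueness or range constraints."""


def read_spo2(
    path: str | Path,
    format: str | None = None,
    channel_name: str | None = None,
) -> SpO2Series:
    """Read a native-resolution SpO2 series from an EDF or CSV file.

    ``format`` is inferred from the suffix when omitted.  The returned series
    has an all-true validity mask -- cleaning is a separate, explicit step.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        return _read_edf(path, channel_name)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> SpO2Series:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "spo2_percent"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        dt = 1.0
    else:
        steps = np.diff(t)
        dt = float(steps[0])
        if dt <= 0 or not np.allclose(steps, dt, rtol=0.0, atol=1e-6):
            raise FormatError(f"{path}: non-uniform time axis (tolerance 1e-6 s)")
    values = df["spo2_percent"].to_numpy(dtype=float)
    mask = np.ones(len(values), dtype=bool)
    if "valid" in df.columns:
        mask = df["valid"].to_numpy(dtype=bool)
    return SpO2Series(subject_id=path.stem, values=values, valid_mask=mask, dt_s=dt)


def _read_edf(path: Path, channel_name: str | None) -> SpO2Series:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    wanted = [channel_name] if channel_name else list(DEFAULT_EDF_ALIASES)
    lookup = {name.lower(): name for name in raw.ch_names}
    for cand in wanted:
        actual = lookup.get(cand.lower())
        if actual is not None:
            data = raw.get_data(picks=[actual])[0]
            return SpO2Series(
                subject_id=path.stem,
                values=np.asarray(data, dtype=float),
                dt_s=1.0 / float(raw.info["sfreq"]),
            )
    raise ChannelNotFoundError(
        f"{path}: none of {wanted} found; available channels: {raw.ch_names}"
    )


def write_spo2_csv(series: SpO2Series, path: str | Path) -> None:
    """Write the canonical cleaned-series dialect ``time_s,spo2_percent,valid``."""
    t = np.arange(len(series)) * series.dt_s
    df = pd.DataFrame(
        {
            "time_s": t,
            "spo2_percent": series.values,
            "valid": series.valid_mask.astype(int),
        }
    )
    # %.17g guarantees a bit-exact float64 round trip through text
    df.to_csv(path, index=False, float_format="%.17g")


def read_labels(
    path: str | Path,
    ahi_column: str = DEFAULT_AHI_COLUMN,
    subject_column: str = "subject_id",
) -> pd.DataFrame:
    """Read a per-subject AHI table.

    Returns a DataFrame with columns ``subject_id`` and ``ahi``.  Rows with
    missing AHI are dropped (count logged).  Duplicate subjects and negative
    AHI values are integrity errors rather than silent fixes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if subject_column not in df.columns:
        raise FormatError(f"{path}: missing column {subject_column!r}")
    if ahi_column not in df.columns:
        raise FormatError(f"{path}: missing AHI column {ahi_column!r}")
    out = df[[subject_column, ahi_column]].rename(
        columns={subject_column: "subject_id", ahi_column: "ahi"}
    )
    out["subject_id"] = out["subject_id"].astype(str)
    n_missing = int(out["ahi"].isna().sum())
    if n_missing:
        logger.info("read_labels(%s): dropped %d rows with missing AHI", path, n_missing)
        out = out.dropna(subset=["ahi"])
    if out["subject_id"].duplicated().any():
        dupes = out.loc[out["subject_id"].duplicated(), "subject_id"].tolist()
        raise IntegrityError(f"{path}: duplicate subject ids {dupes}")
    if (out["ahi"] < 0).any():
        raise IntegrityError(f"{path}: negative AHI values present")
    return out.reset_index(drop=True)


def write_labels(
    labels: pd.DataFrame, path: str | Path, ahi_column: str = DEFAULT_AHI_COLUMN
) -> None:
    """Write a label table using the NSRR-style AHI column name."""
    labels.rename(columns={"ahi": ahi_column}).to_csv(path, index=False)
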