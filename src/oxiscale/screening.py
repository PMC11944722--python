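"""Multi-scale feature matrix assembly, quality filtering, Spearman screening
and scale-trend classification.

The matrix is subjects x (feature, timescale), with columns labelled
``{feature}@{tau}s``.  Columns dominated by missing or zero values are
excluded before correlation screening (defaults: >20 % missing or >40 %
zeros, strict inequalities).  Each surviving feature's Spearman-correlation
profile across timescales is summarised and assigned to one of four trend
groups:

A  decaying      — strong at fine scales, roughly halved by 30 s
B  coarser peak  — weak natively, peak relevance at a coarser scale
C  polarity shift— correlation changes sign across scales
D  constant high — |rho| > 0.4 at every scale up to 60 s
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .series import DomainError

logger = logging.getLogger(__name__)

_COL_RE = re.compile(r"^(?P<feature>.+)@(?P<tau>\d+)s$")


def column_label(feature: str, tau: int) -> str:
    return f"{feature}@{int(tau)}s"


def parse_column(label: str) -> tuple[str, int]:
    m = _COL_RE.match(label)
    if not m:
        raise ValueError(f"column label {label!r} is not of the form feature@<tau>s")
    return m.group("feature"), int(m.group("tau"))


class IntegrityError(ValueError):
    pass


def build_feature_matrix(
    records: Iterable[tuple[str, int, Mapping[str, float]]]
) -> pd.DataFrame:
    """Assemble (subject_id, tau, feature-vector) records into a wide matrix.

    Returns a DataFrame indexed by subject with one ``{feature}@{tau}s``
    column per (feature, timescale); absent entries become NaN.  Duplicate
    (subject, tau, feature) triples are an integrity error.
    """
    rows: dict[str, dict[str, float]] = {}
    for subject_id, tau, vector in records:
        row = rows.setdefault(str(subject_id), {})
        for feature, value in vector.items():
            label = column_label(feature, tau)
            if label in row:
                raise IntegrityError(
                    f"duplicate entry for subject {subject_id!r}, column {label!r}"
                )
            row[label] = value
    if not rows:
        raise DomainError("no records supplied")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"

    def sort_key(label: str) -> tuple[str, int]:
        feat, tau = parse_column(label)
        return (feat, tau)

    return df[sorted(df.columns, key=sort_key)]


def column_quality(m: pd.DataFrame) -> pd.DataFrame:
    """Per-column missing and zero fractions (zeros among non-missing cells)."""
    n = len(m)
    missing = m.isna().sum() / n
    zero = (m == 0).sum() / n
    return pd.DataFrame({"missing_frac": missing, "zero_frac": zero})


def filter_features(
    m: pd.DataFrame, max_missing: float = 0.20, max_zero: float = 0.40
) -> pd.DataFrame:
    """Drop columns with more than ``max_missing`` missing or ``max_zero`` zero
    values (strict inequalities; boundary columns are retained)."""
    q = column_quality(m)
    drop = q.index[(q["missing_frac"] > max_missing) | (q["zero_frac"] > max_zero)]
    if len(drop) == len(m.columns):
        raise DomainError("feature filter would drop every column")
    if len(drop):
        logger.info("filter_features: dropped %d columns: %s",
                    len(drop), ", ".join(drop[:20]))
    return m.drop(columns=drop)


@dataclass(frozen=True)
class TrendConfig:
    """Operational thresholds of the four trend groups.

    ``high_rho`` bounds group D (constant-high), ``weak_native`` and
    ``peak_rho``/``peak_tau_min`` bound group B (coarser peak), ``decay_ratio``
    and ``peak_tau_max`` bound group A (decaying), ``flip_min_rho`` is the
    minimum magnitude for a sign flip to count as a polarity shift (group C).
    """

    high_rho: float = 0.4
    high_tau_max: int = 60
    flip_min_rho: float = 0.1
    weak_native: float = 0.3
    peak_rho: float = 0.4
    peak_tau_min: int = 6
    peak_tau_max: int = 5
    decay_check_tau: int = 30
    decay_ratio: float = 0.5


GROUP_A = "A_decaying"
GROUP_B = "B_coarser_peak"
GROUP_C = "C_polarity_shift"
GROUP_D = "D_constant_high"
UNCLASSIFIED = "unclassified"


def spearman_screen(m: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of every column against AHI on pairwise-complete rows.

    ``labels`` must have columns ``subject_id`` and ``ahi``.  Returns a tidy
    frame with columns ``feature, tau, rho, n_used`` (rho NaN when fewer than
    3 complete pairs exist).  Ties receive average ranks.
    """
    lab = labels.set_index("subject_id")["ahi"]
    common = m.index.intersection(lab.index)
    if len(common) < 3:
        raise DomainError("fewer than 3 subjects shared between matrix and labels")
    m = m.loc[common]
    y = lab.loc[common].to_numpy(dtype=float)
    out = []
    for col in m.columns:
        x = m[col].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        n_used = int(ok.sum())
        if n_used < 3 or np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
            rho = float("nan")
        else:
            rho = float(stats.spearmanr(x[ok], y[ok]).statistic)
        feature, tau = parse_column(col)
        out.append({"feature": feature, "tau": tau, "rho": rho, "n_used": n_used})
    return pd.DataFrame(out).sort_values(["feature", "tau"]).reset_index(drop=True)


def summarize_profiles(report: pd.DataFrame) -> pd.DataFrame:
    """Per-feature profile summary: max/min/median rho and the timescale of
    the largest |rho| (the shape of a per-feature relevance table)."""
    rows = []
    for feature, grp in report.dropna(subset=["rho"]).groupby("feature"):
        rho = grp["rho"].to_numpy()
        taus = grp["tau"].to_numpy()
        k = int(np.argmax(np.abs(rho)))
        rows.append({
            "feature": feature,
            "rho_max": float(rho.max()),
            "rho_min": float(rho.min()),
            "rho_median": float(np.median(rho)),
            "rho_best": float(rho[k]),
            "tau_best": int(taus[k]),
        })
    return pd.DataFrame(rows)


def classify_trends(
    report: pd.DataFrame, cfg: TrendConfig | None = None
) -> pd.DataFrame:
    """Assign each feature's rho-vs-timescale profile to a trend group.

    Precedence D > C > B > A: constant-high beats polarity-shift beats
    coarser-peak beats decaying; profiles lacking the reference scales
    (native, 30 s, 60 s) are left unclassified.  Returns the profile summary
    with a ``trend_group`` column.
    """
    cfg = cfg or TrendConfig()
    summary = summarize_profiles(report)
    groups = []
    for _, row in summary.iterrows():
        grp = report[(report["feature"] == row["feature"]) & report["rho"].notna()]
        profile = dict(zip(grp["tau"], grp["rho"]))
        groups.append(_classify_one(profile, cfg))
    summary["trend_group"] = groups
    return summary


def _classify_one(profile: dict[int, float], cfg: TrendConfig) -> str:
    taus = sorted(profile)
    required = {1, cfg.decay_check_tau, cfg.high_tau_max}
    if len(taus) < 5 or not required.issubset(profile):
        logger.warning("trend profile lacks required scales %s; unclassified", required)
        return UNCLASSIFIED
    rho = np.array([profile[t] for t in taus])
    abs_rho = np.abs(rho)
    max_abs = abs_rho.max()
    tau_best = taus[int(np.argmax(abs_rho))]

    sub60 = [profile[t] for t in taus if t <= cfg.high_tau_max]
    if all(abs(r) > cfg.high_rho for r in sub60):
        return GROUP_D
    signs = np.sign(rho[abs_rho >= cfg.flip_min_rho])
    if signs.size >= 2 and (signs.min() < 0 < signs.max()):
        return GROUP_C
    if abs(profile[1]) < cfg.weak_native and max_abs >= cfg.peak_rho and tau_best >= cfg.peak_tau_min:
        return GROUP_B
    if tau_best <= cfg.peak_tau_max and abs(profile[cfg.decay_check_tau]) <= cfg.decay_ratio * max_abs:
        return GROUP_A
    return UNCLASSIFIED
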