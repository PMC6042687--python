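"""Population-level aggregation of per-cell territory measurements.

Builds the standard summaries from a ``cells.csv`` table: the asymmetric
median-overlap heatmap, the symmetric contact-frequency heatmap with
whole-chromosome pairing frequencies on the diagonal, mean radial shell
profiles, Tukey box summaries, least-squares R², two-group tests
(Mann-Whitney rank sum, Fisher's exact), and a screen for translocation
candidates (channel pairs whose median overlap stands far above the rest).

Aggregation is median-of-cells, not pooled-voxel.  Missing per-cell fields
are excluded entry-wise, with the contributing n reported per entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationSummary",
    "TukeySummary",
    "aggregate",
    "r_squared",
    "tukey_summary",
    "compare_groups",
    "translocation_screen",
]


@dataclass
class TukeySummary:
    """Five-number Tukey box summary with 1.5·IQR whiskers and outliers."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int


@dataclass
class PopulationSummary:
    """Aggregated heatmaps and per-entry sample sizes for one population."""

    channels: list[str]
    overlap_median: pd.DataFrame  # entry (row, col) = median O(row|col); diagonal NaN
    overlap_n: pd.DataFrame
    contact_freq: pd.DataFrame  # symmetric off-diagonal; diagonal = pairing frequency
    contact_n: pd.DataFrame
    shell_profiles: pd.DataFrame | None = None  # channels × shell1..shellK means
    intermixing_median: pd.Series | None = None
    n_cells: int = 0
    extras: dict = field(default_factory=dict)


def _series(df: pd.DataFrame, col: str) -> pd.Series | None:
    if col not in df.columns:
        return None
    return pd.to_numeric(df[col], errors="coerce").dropna()


def aggregate(cells: pd.DataFrame, channels: list[str], n_shells: int = 5) -> PopulationSummary:
    """Aggregate a cells table into a :class:`PopulationSummary`.

    Expects the ``cells.csv`` column scheme (``ovf_A_given_B``,
    ``contact_A_B``, ``paired_CH``, ``shell{i}_CH``, ``intermix_CH``).
    """
    if len(cells) == 0:
        raise ValueError("cannot aggregate an empty cells table")
    k = len(channels)
    ov = pd.DataFrame(np.full((k, k), np.nan), index=channels, columns=channels)
    ov_n = pd.DataFrame(np.zeros((k, k), dtype=int), index=channels, columns=channels)
    ct = pd.DataFrame(np.full((k, k), np.nan), index=channels, columns=channels)
    ct_n = pd.DataFrame(np.zeros((k, k), dtype=int), index=channels, columns=channels)

    for a in channels:
        for b in channels:
            if a == b:
                continue
            s = _series(cells, f"ovf_{a}_given_{b}")
            if s is not None and len(s):
                ov.loc[a, b] = float(s.median())
                ov_n.loc[a, b] = len(s)

    for a, b in combinations(channels, 2):
        key_a, key_b = sorted((a, b))
        col = f"contact_{key_a}_{key_b}"
        if col in cells.columns:
            s = cells[col].dropna()
            if len(s):
                freq = float(s.astype(bool).mean())
                ct.loc[a, b] = ct.loc[b, a] = freq
                ct_n.loc[a, b] = ct_n.loc[b, a] = len(s)

    for ch in channels:
        col = f"paired_{ch}"
        if col in cells.columns:
            s = cells[col].dropna()
            if len(s):
                ct.loc[ch, ch] = float(s.astype(bool).mean())
                ct_n.loc[ch, ch] = len(s)

    shells = None
    shell_cols = {ch: [f"shell{i}_{ch}" for i in range(1, n_shells + 1)] for ch in channels}
    if all(c in cells.columns for cols in shell_cols.values() for c in cols):
        shells = pd.DataFrame(
            {ch: [float(pd.to_numeric(cells[c], errors="coerce").mean()) for c in cols]
             for ch, cols in shell_cols.items()},
            index=[f"shell{i}" for i in range(1, n_shells + 1)],
        ).T

    inter = None
    inter_cols = {ch: f"intermix_{ch}" for ch in channels if f"intermix_{ch}" in cells.columns}
    if inter_cols:
        inter = pd.Series(
            {ch: float(pd.to_numeric(cells[col], errors="coerce").median())
             for ch, col in inter_cols.items()}
        )

    return PopulationSummary(
        channels=list(channels),
        overlap_median=ov,
        overlap_n=ov_n,
        contact_freq=ct,
        contact_n=ct_n,
        shell_profiles=shells,
        intermixing_median=inter,
        n_cells=len(cells),
    )


def r_squared(x, y) -> float:
    """Coefficient of determination of the least-squares line of y on x.

    A constant y is defined as R² = 0; a constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("r_squared needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the regression is undefined")
    if np.ptp(y) == 0:
        return 0.0
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def tukey_summary(values) -> TukeySummary:
    """Tukey five-number summary with linear-interpolation quartiles.

    Whiskers extend to the most extreme data within 1.5·IQR of the quartiles;
    points beyond are outliers.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("tukey_summary needs at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return TukeySummary(
        minimum=float(v.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(v.max()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(outliers),
        n=len(v),
    )


def compare_groups(a, b, kind: str = "rank_sum") -> tuple[float, float]:
    """Two-sided two-group test.

    ``rank_sum`` — Mann-Whitney U on two value arrays; ``fisher_2x2`` —
    Fisher's exact test where ``a`` and ``b`` are the two rows of a 2×2 count
    table.  Returns (statistic, p).
    """
    if kind == "rank_sum":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("rank_sum requires two non-empty groups")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if kind == "fisher_2x2":
        table = np.asarray([a, b], dtype=int)
        if table.shape != (2, 2) or np.any(table < 0):
            raise ValueError("fisher_2x2 requires two rows of two non-negative counts")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown test kind {kind!r}; use 'rank_sum' or 'fisher_2x2'")


def translocation_screen(
    summary: PopulationSummary | pd.DataFrame,
    fold_threshold: float = 1.5,
) -> list[tuple[str, str]]:
    """Flag channel pairs whose overlap stands far above the population norm.

    A pair's statistic is the mean of its two directional median overlaps;
    pairs exceeding ``fold_threshold`` × the median of all pair statistics are
    flagged as translocation candidates.  Needs at least 3 channel pairs.
    """
    ov = summary.overlap_median if isinstance(summary, PopulationSummary) else summary
    channels = list(ov.index)
    pairs = list(combinations(channels, 2))
    if len(pairs) < 3:
        raise ValueError("translocation_screen needs at least 3 channel pairs")
    pair_stats = {}
    for a, b in pairs:
        vals = [ov.loc[a, b], ov.loc[b, a]]
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            pair_stats[(a, b)] = float(np.mean(vals))
    if not pair_stats:
        return []
    overall = float(np.median(list(pair_stats.values())))
    if overall == 0:
        return [p for p, v in pair_stats.items() if v > 0]
    return [p for p, v in pair_stats.items() if v > fold_threshold * overall]
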