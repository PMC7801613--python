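"""Replicate statistics and time-series analysis of run records.

Covers the quantities the dosing experiments are judged on: per-arm mean
and SD of the final new-vessel length and final tumour count, pairwise
pooled-variance Student t-tests with Bonferroni correction, the mean
Ang2/Ang1 ratio at branch points, and detection of the proliferative /
regressive / re-proliferative motif in a vessel-length series.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInput

__all__ = [
    "branch_ang_ratio",
    "two_sample_t",
    "bonferroni",
    "summarize_arms",
    "phase_detect",
    "PhaseReport",
]


def branch_ang_ratio(network, a1: np.ndarray, a2: np.ndarray,
                     floor: float = 1e-12) -> float:
    """Mean a2/a1 over current branch points (candidates and sprouted
    anchors); 0 with none."""
    points = network.branch_points()
    if not points:
        return 0.0
    vals = [a2[p] / max(a1[p], floor) for p in points]
    return float(np.mean(vals))


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Classic pooled-variance Student t-test, two-sided.

    Raises DegenerateInput when both groups are constant with equal means
    (the statistic is undefined there).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInput("each group needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateInput("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError("m must be >= number of tests")
    return np.minimum(1.0, m * p)


def summarize_arms(arm_records: dict[str, list]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-arm summary and all pairwise Bonferroni-adjusted t-tests.

    ``arm_records`` maps arm name -> list of RunRecords (n >= 2 each).
    Returns (summary, tests): summary has mean/SD of final new-vessel
    length and final alive tumour count per arm; tests has one row per
    arm pair and endpoint.
    """
    if len(arm_records) < 2:
        raise ValueError("need at least two arms")
    finals = {
        arm: pd.DataFrame({
            "length_mm": [r.frame["length_mm"].iloc[-1] for r in records],
            "alive": [r.frame["alive"].iloc[-1] for r in records],
        })
        for arm, records in arm_records.items()
    }
    summary = pd.DataFrame([
        {
            "arm": arm, "n": len(df),
            "length_mean": df["length_mm"].mean(),
            "length_sd": df["length_mm"].std(ddof=1),
            "alive_mean": df["alive"].mean(),
            "alive_sd": df["alive"].std(ddof=1),
        }
        for arm, df in finals.items()
    ])
    pairs = list(combinations(sorted(finals), 2))
    m = len(pairs)
    rows = []
    for endpoint in ("length_mm", "alive"):
        for a, b in pairs:
            t, p = two_sample_t(finals[a][endpoint], finals[b][endpoint])
            rows.append({"endpoint": endpoint, "arm_a": a, "arm_b": b,
                         "t": t, "p": p})
    tests = pd.DataFrame(rows)
    tests["p_adj"] = np.concatenate([
        bonferroni(tests.loc[tests.endpoint == ep, "p"].to_numpy(), m)
        for ep in ("length_mm", "alive")
    ])
    return summary, tests


@dataclass
class PhaseReport:
    labels: list[tuple[str, int, int]]   # (phase, start index, end index)
    motif: bool                          # rise-fall-rise present?
    peak: float | None = None
    peak_index: int | None = None
    trough: float | None = None
    trough_index: int | None = None


def phase_detect(series, window: int = 1, rel_drop: float = 0.05) -> PhaseReport:
    """Label maximal monotone runs of a (smoothed) length series.

    ``window`` is the moving-mean width in samples (use steps_per_day for a
    1-day smoothing of a per-step series).  The rise-fall-rise motif is
    reported when an increasing run is followed by a decreasing run losing
    at least ``rel_drop`` of the running peak, followed by another
    increasing run.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValueError("series must have length >= 3")
    if window > 1:
        kernel = np.ones(window) / window
        y = np.convolve(y, kernel, mode="valid")
    d = np.diff(y)
    signs = np.sign(d)
    labels: list[tuple[str, int, int]] = []
    i = 0
    while i < signs.size:
        s = signs[i]
        j = i
        while j + 1 < signs.size and signs[j + 1] == s:
            j += 1
        if s > 0:
            labels.append(("proliferative", i, j + 1))
        elif s < 0:
            labels.append(("regressive", i, j + 1))
        i = j + 1
    motif = False
    peak = peak_idx = trough = trough_idx = None
    best_drop = 0.0
    # scan for rise -> (deep enough) fall -> rise; keep the deepest fall
    for idx in range(len(labels) - 1):
        name, start, end = labels[idx]
        if name != "regressive":
            continue
        before = [lb for lb in labels[:idx] if lb[0] == "proliferative"]
        after = [lb for lb in labels[idx + 1:] if lb[0] == "proliferative"]
        if not before or not after:
            continue
        peak_val = y[start]
        trough_val = y[end]
        if peak_val <= 0:
            continue
        drop = (peak_val - trough_val) / peak_val
        if drop >= rel_drop and drop > best_drop:
            motif = True
            best_drop = drop
            peak, peak_idx = float(peak_val), int(start)
            trough, trough_idx = float(trough_val), int(end)
    return PhaseReport(labels, motif, peak, peak_idx, trough, trough_idx)
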