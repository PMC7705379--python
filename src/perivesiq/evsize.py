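"""Extracellular-vesicle size statistics and group comparisons.

NTA-style summaries (mean and the D10/D50/D90 diameter percentiles) and
cytometry-style size-interval counts, plus the ANOVA/Tukey and
Kruskal–Wallis/Dunn plumbing used to compare patient groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class SizeSummary:
    """Mean and D-percentiles of a particle diameter sample, in nm.

    D10 is the diameter below which 10% of particles fall, D50 the
    median, D90 the 90% bound.
    """

    mean_nm: float
    d10_nm: float
    d50_nm: float
    d90_nm: float
    n: int
    concentration_per_ml: float | None = None


def size_summary(
    diameters_nm: np.ndarray, volume_ml: float | None = None
) -> SizeSummary:
    """Summarise a diameter sample: arithmetic mean and D10/D50/D90.

    Percentiles use linear interpolation between order statistics. With a
    known analysed volume, a particles-per-mL concentration is attached.
    """
    d = np.asarray(diameters_nm, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter sample")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    d10, d50, d90 = np.percentile(d, [10, 50, 90])
    conc = d.size / volume_ml if volume_ml else None
    return SizeSummary(
        mean_nm=float(d.mean()),
        d10_nm=float(d10),
        d50_nm=float(d50),
        d90_nm=float(d90),
        n=d.size,
        concentration_per_ml=conc,
    )


DEFAULT_INTERVALS_UM = ((0.1, 1.0), (1.0, 3.0), (3.0, 6.0))


def count_size_intervals(
    diameters_nm: np.ndarray,
    intervals_um: tuple[tuple[float, float], ...] = DEFAULT_INTERVALS_UM,
    volume_ml: float | None = None,
) -> dict:
    """Count particles per size interval (half-open [lo, hi) in μm).

    The last interval is closed at its upper bound. Particles below the
    first bound and above the last are reported under ``below`` and
    ``above``. With a volume, per-mL rates are added.
    """
    iv = sorted(intervals_um)
    for (lo1, hi1), (lo2, _) in zip(iv, iv[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping intervals {(lo1, hi1)} and starting {lo2}")
    d_um = np.asarray(diameters_nm, dtype=float) / 1000.0
    counts = {}
    for i, (lo, hi) in enumerate(iv):
        last = i == len(iv) - 1
        sel = (d_um >= lo) & ((d_um <= hi) if last else (d_um < hi))
        counts[f"{lo:g}-{hi:g}um"] = int(sel.sum())
    counts["below"] = int((d_um < iv[0][0]).sum())
    counts["above"] = int((d_um > iv[-1][1]).sum())
    if volume_ml:
        counts["per_ml"] = {k: v / volume_ml for k, v in counts.items() if k != "per_ml"}
    return counts


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with tie correction and Bonferroni
    adjustment over all pairs."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(all_vals)
    n = len(all_vals)
    # tie correction term
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
        rows.append({"group1": a, "group2": b, "z": z, "p_adj": p})
    return pd.DataFrame(rows)


def group_compare(
    values: pd.Series | dict[str, np.ndarray],
    labels: pd.Series | None = None,
    parametric: bool | None = None,
    alpha: float = 0.05,
    pairwise: bool = True,
) -> dict:
    """Compare ≥2 groups: one-way ANOVA + Tukey HSD, or Kruskal–Wallis + Dunn.

    With ``parametric=None`` the path is chosen by a Shapiro–Wilk
    normality gate on the pooled group residuals (parametric if no group
    rejects at ``alpha``). ``pairwise=False`` skips the post-hoc table
    (cheaper when only the omnibus test matters, e.g. in simulations).

    Returns a dict with the omnibus statistic and p-value, the pairwise
    table (or ``None``), and which path was taken.
    """
    if isinstance(values, dict):
        groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    else:
        if labels is None:
            raise ValueError("labels required when values is a Series")
        groups = {
            g: np.asarray(values[labels == g], dtype=float) for g in labels.unique()
        }
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    if parametric is None:
        parametric = True
        for v in groups.values():
            if len(v) >= 3 and np.ptp(v) > 0:
                if stats.shapiro(v).pvalue < alpha:
                    parametric = False
                    break

    arrays = list(groups.values())
    if parametric:
        f, p = stats.f_oneway(*arrays)
        table = None
        if pairwise:
            flat = np.concatenate(arrays)
            labs = np.concatenate([[g] * len(v) for g, v in groups.items()])
            tk = pairwise_tukeyhsd(flat, labs, alpha=alpha)
            table = pd.DataFrame(
                tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
            )
        return {
            "test": "anova",
            "statistic": float(f),
            "p_value": float(p),
            "pairwise": table,
        }
    h, p = stats.kruskal(*arrays)
    return {
        "test": "kruskal",
        "statistic": float(h),
        "p_value": float(p),
        "pairwise": _dunn_pairwise(groups) if pairwise else None,
    }
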