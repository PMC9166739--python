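"""Population-level statistics on gated two-channel particle intensities.

This module is the arithmetic engine behind the headline figures of a
sorting experiment: per-frame quadrant proportions with mean +/- SEM
across frames (the frame being the unit of replication), conditional
proportions (of particles positive for a reference marker, the percentage
also positive for a second marker), enrichment ratios of a population
fraction after vs before sorting, subpopulation intensity comparisons
(Mann-Whitney and Kolmogorov-Smirnov), robust FDR-based outlier removal
for distance data, and centre-to-centre distance profiling with a
Kruskal-Wallis omnibus test and Dunn's pairwise follow-up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

__all__ = [
    "QuadrantGates",
    "PopulationSummary",
    "DistanceProfile",
    "estimate_gate",
    "estimate_gates",
    "classify_quadrants",
    "frame_proportions",
    "conditional_proportion",
    "enrichment_ratio",
    "subpop_intensity_compare",
    "remove_outliers",
    "distance_profile",
    "dunn_posthoc",
]

QUADRANTS = ["pp", "pn", "np", "nn"]  # (A,B) signs: ++, +-, -+, --


@dataclass
class QuadrantGates:
    """Per-channel positivity thresholds on corrected integrated intensity.

    Positivity is strict: an event is positive when its intensity exceeds
    the threshold; an event exactly at the threshold is negative.
    """

    thresholds: dict[str, float]
    method: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, t in self.thresholds.items():
            if not math.isfinite(t):
                raise ValueError(f"gate for {ch} is not finite")


def estimate_gate(intensities, k: float = 3.0) -> tuple[float, str]:
    """Automated surrogate for manual gate placement on one channel.

    A Gaussian kernel-density estimate is built on robust-scaled
    intensities; if two or more modes are found, the threshold is the
    minimum-density point between the background (lowest-intensity) mode
    and the next mode.  If the distribution is unimodal the fallback is
    background mode + ``k`` robust SDs.  Returns (threshold, method tag).
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 events to estimate a gate")
    med = np.median(x)
    scale = stats.median_abs_deviation(x, scale="normal")
    if scale == 0:
        scale = x.std() or 1.0
    t = (x - med) / scale
    grid = np.linspace(t.min() - 1.0, t.max() + 1.0, 1024)
    kde = stats.gaussian_kde(t)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=0.05 * dens.max())
    if len(peaks) >= 2:
        bg, nxt = peaks[0], peaks[1]
        valley = bg + int(np.argmin(dens[bg:nxt + 1]))
        return float(grid[valley] * scale + med), "kde_valley"
    mode = float(grid[int(np.argmax(dens))])
    return float((mode + k) * scale + med), "unimodal_fallback"


def estimate_gates(intensities_by_channel: dict[str, np.ndarray],
                   k: float = 3.0,
                   overrides: dict[str, float] | None = None) -> QuadrantGates:
    """Estimate one gate per channel; manual overrides bypass the estimator."""
    thresholds: dict[str, float] = {}
    methods: dict[str, str] = {}
    overrides = overrides or {}
    for ch, vals in intensities_by_channel.items():
        if ch in overrides:
            thresholds[ch] = float(overrides[ch])
            methods[ch] = "manual_override"
        else:
            thresholds[ch], methods[ch] = estimate_gate(vals, k=k)
    return QuadrantGates(thresholds, methods)


def classify_quadrants(df: pd.DataFrame, gates: QuadrantGates,
                       columns: tuple[str, str] = ("intensity_ch1", "intensity_ch2"),
                       frame_col: str = "frame_id") -> pd.DataFrame:
    """Per-frame quadrant counts (n_pp, n_pn, n_np, n_nn).

    Channel order follows ``columns`` = (A, B); gate keys must match.
    Each event lands in exactly one quadrant; positivity is strict (>).
    """
    ca, cb = columns
    ta, tb = (gates.thresholds[ca], gates.thresholds[cb])
    pos_a = df[ca].to_numpy() > ta
    pos_b = df[cb].to_numpy() > tb
    quad = np.where(pos_a & pos_b, "pp",
                    np.where(pos_a, "pn", np.where(pos_b, "np", "nn")))
    out = (pd.DataFrame({frame_col: df[frame_col].to_numpy(), "quad": quad})
           .groupby([frame_col, "quad"], observed=False).size().unstack(fill_value=0))
    for q in QUADRANTS:
        if q not in out.columns:
            out[q] = 0
    out = out[QUADRANTS].rename(columns={q: f"n_{q}" for q in QUADRANTS})
    return out


@dataclass
class PopulationSummary:
    """Per-frame quadrant percentages with mean and SEM across frames."""

    frame_percentages: pd.DataFrame  # columns pct_pp..pct_nn, index frame
    mean_pct: pd.Series
    sem_pct: pd.Series
    n_frames: int
    excluded_frames: list = field(default_factory=list)
    sem_defined: bool = True


def frame_proportions(counts: pd.DataFrame) -> PopulationSummary:
    """Quadrant percentages per frame; mean and SEM (SD/sqrt(n)) across frames.

    Frames with zero events are excluded and reported.  With a single
    frame the SEM is undefined and reported as 0 with ``sem_defined``
    cleared.
    """
    cols = [f"n_{q}" for q in QUADRANTS]
    totals = counts[cols].sum(axis=1)
    excluded = list(counts.index[totals == 0])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} frame(s) with zero events",
                      stacklevel=2)
    kept = counts.loc[totals > 0, cols]
    if kept.empty:
        raise ValueError("no frames with events")
    pct = 100.0 * kept.div(kept.sum(axis=1), axis=0)
    pct.columns = [f"pct_{q}" for q in QUADRANTS]
    n = len(pct)
    mean = pct.mean()
    if n > 1:
        sem = pct.std(ddof=1) / math.sqrt(n)
        defined = True
    else:
        sem = pd.Series(0.0, index=pct.columns)
        defined = False
    return PopulationSummary(pct, mean, sem, n, excluded, defined)


def conditional_proportion(a: float, b: float) -> float:
    """100 * a / (a + b): of a reference-positive population split into two
    subgroups at percentages a and b, the percentage falling in the first.

    Full precision is returned; round to the nearest integer for headline
    figures.  Scale-invariant in (a, b).
    """
    if a < 0 or b < 0:
        raise ValueError("percentages must be non-negative")
    if a + b == 0:
        raise ValueError("a + b must be positive")
    return 100.0 * a / (a + b)


def enrichment_ratio(post_pct: float, pre_pct: float) -> float:
    """Fold-change of a population fraction after vs before sorting."""
    if pre_pct <= 0:
        raise ValueError("pre-sort percentage must be positive")
    return post_pct / pre_pct


def subpop_intensity_compare(group_a, group_b) -> dict:
    """Compare staining intensities of two subpopulations.

    Two-sided Mann-Whitney U (rank-sum) and two-sample Kolmogorov-Smirnov
    tests, with the descriptive set (median, mean +/- SEM, n) per group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    ks = stats.ks_2samp(a, b)
    return {
        "n": (len(a), len(b)),
        "median": (float(np.median(a)), float(np.median(b))),
        "mean": (float(a.mean()), float(b.mean())),
        "sem": (float(a.std(ddof=1) / math.sqrt(len(a))),
                float(b.std(ddof=1) / math.sqrt(len(b)))),
        "mannwhitney_u": float(mw.statistic),
        "mannwhitney_p": float(mw.pvalue),
        "ks_d": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


def remove_outliers(values, q: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Robust FDR-based univariate outlier removal (ROUT-style variant).

    Robust centre = median; robust scale = 68.27th percentile of absolute
    deviations (the robust-SD analogue); each point gets a two-tailed
    p-value from a t distribution with n-1 df on its robust z-score, and
    outliers are flagged by Benjamini-Hochberg stepping at rate ``q`` (in
    percent, default 1).  Returns (retained, removed).  With n < 10 no
    removal is attempted; a zero robust scale (constant data) flags
    nothing.

    This is a documented reimplementation of the published idea behind
    ROUT (outlier FDR control), not the proprietary regression-based
    original.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    if n < 10:
        warnings.warn("fewer than 10 values: outlier removal skipped",
                      stacklevel=2)
        return x, np.empty(0)
    center = np.median(x)
    absdev = np.abs(x - center)
    scale = np.percentile(absdev, 68.27)
    if scale == 0:
        return x, np.empty(0)
    p = 2.0 * stats.t.sf(absdev / scale, df=n - 1)
    order = np.argsort(p)
    thresh = (q / 100.0) * (np.arange(1, n + 1) / n)
    passing = np.nonzero(p[order] <= thresh)[0]
    outlier_mask = np.zeros(n, dtype=bool)
    if passing.size:
        outlier_mask[order[: passing.max() + 1]] = True
    return x[~outlier_mask], x[outlier_mask]


@dataclass
class DistanceProfile:
    """Summary of centre-to-centre distances for one marker pair."""

    marker: str
    distances_um: np.ndarray  # retained after outlier removal
    removed_um: np.ndarray
    mean_um: float
    sem_um: float
    median_um: float
    q25_um: float
    q75_um: float
    outlier_removal: bool  # False when n < 10 (flagged, nothing removed)

    @property
    def n(self) -> int:
        return len(self.distances_um)


def _profile_one(marker: str, d: np.ndarray, q: float) -> DistanceProfile:
    if len(d) >= 10:
        retained, removed = remove_outliers(d, q=q)
        did = True
    else:
        retained, removed, did = d, np.empty(0), False
    n = len(retained)
    sem = float(retained.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return DistanceProfile(
        marker, retained, removed,
        mean_um=float(retained.mean()), sem_um=sem,
        median_um=float(np.median(retained)),
        q25_um=float(np.percentile(retained, 25)),
        q75_um=float(np.percentile(retained, 75)),
        outlier_removal=did,
    )


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after a Kruskal-Wallis test.

    Standard rank-sum z statistic with the tie correction, two-sided
    normal p, Bonferroni-adjusted over all pairs.
    """
    names = list(groups)
    sizes = {k: len(groups[k]) for k in names}
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    ranks = stats.rankdata(pooled)
    big_n = len(pooled)
    mean_rank: dict[str, float] = {}
    i = 0
    for k in names:
        mean_rank[k] = float(ranks[i:i + sizes[k]].mean())
        i += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = big_n * (big_n + 1) / 12.0 - tie_term / (12.0 * (big_n - 1))
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ka, kb = names[a], names[b]
            se = math.sqrt(var_base * (1.0 / sizes[ka] + 1.0 / sizes[kb]))
            z = (mean_rank[ka] - mean_rank[kb]) / se
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
            rows.append({"group_1": ka, "group_2": kb, "z": z, "p_adjusted": p})
    return pd.DataFrame(rows)


def distance_profile(distances_by_marker: dict[str, np.ndarray],
                     q: float = 1.0) -> tuple[list[DistanceProfile], dict | None]:
    """Profile each marker's distances and compare markers.

    Per marker: outlier removal (skipped and flagged below 10 values),
    then mean +/- SEM, median and quartiles.  With >= 2 markers an omnibus
    Kruskal-Wallis test on the retained distances is returned together
    with Dunn's pairwise follow-up; with a single marker the omnibus part
    is ``None``.
    """
    if not distances_by_marker:
        raise ValueError("no markers supplied")
    profiles = [_profile_one(m, np.asarray(d, float), q)
                for m, d in distances_by_marker.items()]
    if len(profiles) < 2:
        return profiles, None
    retained = {p.marker: p.distances_um for p in profiles}
    kw = stats.kruskal(*retained.values())
    omnibus = {
        "kruskal_h": float(kw.statistic),
        "kruskal_p": float(kw.pvalue),
        "dunn": dunn_posthoc(retained),
    }
    return profiles, omnibus
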