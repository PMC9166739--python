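"""Label-free proteome enrichment screen (sorted vs control replicates).

The screen compares FASS (sorted) against SYN (control) peptide
intensities: sample totals are normalized to the grand-mean total
(emulating equal protein loading), each protein's ratio is the median of
all valid pairwise FASS_i / SYN_j peptide ratios, and significance comes
from a background-based robust z test: assuming most protein abundances
do not change, the centre and spread of the log-ratio background
population are estimated robustly and each protein is tested against
them.  P-values are Benjamini-Hochberg adjusted and proteins are classed
as enriched (ratio above ``fold_up`` and adjusted p below ``alpha``),
depleted (below ``fold_down``), retained, or under-quantified (fewer than
``min_peptides`` quantified peptides).

The background test here is a documented robust-z construction from the
stated assumptions of the vendor "background based t-test", not the
proprietary statistic itself; output records carry a method tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenParams",
    "total_normalize",
    "protein_ratio",
    "background_test",
    "bh_adjust",
    "classify",
    "screen",
    "ms_if_correlation",
]

BACKGROUND_TEST_TAG = "robust-z background test (non-vendor reimplementation)"


@dataclass(frozen=True)
class ScreenParams:
    min_peptides: int = 2
    fold_up: float = 1.5
    fold_down: float = 1.0 / 1.5  # 0.75 also defensible; both are exposed
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.fold_up > 1.0 > self.fold_down > 0.0):
            raise ValueError("need fold_up > 1 > fold_down > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def total_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so all sample totals equal the grand-mean total."""
    totals = table.groupby("sample")["intensity"].sum()
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"sample(s) with non-positive total intensity: {bad}")
    factors = totals.mean() / totals
    out = table.copy()
    out["intensity"] = out["intensity"] * out["sample"].map(factors).to_numpy()
    return out


def _sample_matrix(sub: pd.DataFrame, syn_samples: list[str],
                   fass_samples: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Peptide x replicate intensity matrices (NaN where missing)."""
    pivot = sub.pivot_table(index="peptide_id", columns="sample",
                            values="intensity", aggfunc="first")
    peptides = list(pivot.index)
    syn = pivot.reindex(columns=syn_samples).to_numpy()
    fass = pivot.reindex(columns=fass_samples).to_numpy()
    return syn, fass, peptides


def protein_ratio(syn: np.ndarray, fass: np.ndarray) -> tuple[float, int]:
    """Median of all valid pairwise FASS_i / SYN_j peptide ratios.

    ``syn`` and ``fass`` are peptide x replicate matrices; missing or
    non-positive denominators are skipped pairwise.  Returns (ratio,
    number of peptides contributing >= 1 valid pair); raises ValueError
    when no valid pair exists.  Even-count median is the midpoint of the
    two central values.
    """
    syn = np.atleast_2d(np.asarray(syn, dtype=float))
    fass = np.atleast_2d(np.asarray(fass, dtype=float))
    ratios: list[np.ndarray] = []
    n_peptides = 0
    for s_row, f_row in zip(syn, fass):
        s = s_row[np.isfinite(s_row) & (s_row > 0)]
        f = f_row[np.isfinite(f_row) & (f_row > 0)]
        if s.size == 0 or f.size == 0:
            continue
        ratios.append((f[:, None] / s[None, :]).ravel())
        n_peptides += 1
    if not ratios:
        raise ValueError("no valid FASS/SYN replicate pair for this protein")
    return float(np.median(np.concatenate(ratios))), n_peptides


def background_test(log_ratios: np.ndarray, z_trim: float = 2.5,
                    min_retained_frac: float = 0.5,
                    max_iter: int = 50) -> tuple[np.ndarray, dict]:
    """Two-sided p-values testing each log-ratio against the background.

    The background population (proteins that do not change) is located at
    the median of all log-ratios; its scale is the 68.27th percentile of
    absolute deviations within an iteratively trimmed central band
    (|z| <= ``z_trim``), trimming until the retained set is stable while
    keeping at least ``min_retained_frac`` of proteins.  Each protein's
    robust z-score against that background yields a two-sided normal p.
    Location shifts of all log-ratios leave the p-values unchanged.
    """
    lr = np.asarray(log_ratios, dtype=float)
    if lr.size < 20:
        raise ValueError("background test needs at least 20 quantified proteins")
    center = float(np.median(lr))
    absdev = np.abs(lr - center)
    retained = np.ones(lr.size, dtype=bool)
    scale = float(np.percentile(absdev, 68.27))
    if scale == 0:
        import warnings
        warnings.warn("all protein ratios identical: degenerate background "
                      "scale, p-values set to 1", stacklevel=2)
        return np.ones(lr.size), {"center": center, "scale": 0.0,
                                  "n_background": int(lr.size),
                                  "method": BACKGROUND_TEST_TAG}
    for _ in range(max_iter):
        new = absdev <= z_trim * scale
        if new.sum() < min_retained_frac * lr.size:
            break
        if np.array_equal(new, retained):
            break
        retained = new
        new_scale = float(np.percentile(absdev[retained], 68.27))
        if new_scale == 0:
            break
        scale = new_scale
    z = (lr - center) / scale
    p = 2.0 * stats.norm.sf(np.abs(z))
    info = {"center": center, "scale": scale,
            "n_background": int(retained.sum()), "method": BACKGROUND_TEST_TAG}
    return p, info


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(ratio: float, adjusted_p: float, n_peptides: int,
             params: ScreenParams = ScreenParams()) -> str:
    """Assign enriched / depleted / retained / under_quantified."""
    if n_peptides < params.min_peptides:
        return "under_quantified"
    if ratio > params.fold_up and adjusted_p < params.alpha:
        return "enriched"
    if ratio < params.fold_down and adjusted_p < params.alpha:
        return "depleted"
    return "retained"


def screen(table: pd.DataFrame, params: ScreenParams = ScreenParams(),
           normalize: bool = True) -> pd.DataFrame:
    """Run the full enrichment screen on a long-format peptide table.

    Expects columns ``protein_id, peptide_id, unique_flag, sample,
    intensity`` with samples named ``SYN_*`` and ``FASS_*``.  Returns one
    row per quantifiable protein: ratio, log2_ratio, n_unique_peptides,
    p_value, adjusted_p, klass, plus volcano-ready ``neg_log10_adj_p``.
    Proteins with no valid replicate pair are dropped (their count is in
    ``df.attrs['n_dropped']``); the background-test tag and parameters are
    recorded in ``df.attrs``.
    """
    required = {"protein_id", "peptide_id", "sample", "intensity"}
    if not required <= set(table.columns):
        raise ValueError(f"peptide table must have columns {sorted(required)}")
    if "unique_flag" in table.columns:
        table = table[table["unique_flag"].astype(bool)]
    samples = sorted(table["sample"].unique())
    syn_samples = [s for s in samples if s.upper().startswith("SYN")]
    fass_samples = [s for s in samples if s.upper().startswith("FASS")]
    if not syn_samples or not fass_samples:
        raise ValueError("need both SYN_* and FASS_* samples")
    if normalize:
        table = total_normalize(table)

    rows = []
    n_dropped = 0
    for pid, sub in table.groupby("protein_id", sort=True):
        syn, fass, _ = _sample_matrix(sub, syn_samples, fass_samples)
        try:
            ratio, n_pep = protein_ratio(syn, fass)
        except ValueError:
            n_dropped += 1
            continue
        rows.append({"protein_id": pid, "ratio": ratio,
                     "log2_ratio": math.log2(ratio),
                     "n_unique_peptides": n_pep})
    df = pd.DataFrame(rows).set_index("protein_id")

    quantified = df["n_unique_peptides"] >= params.min_peptides
    p, info = background_test(df.loc[quantified, "log2_ratio"].to_numpy())
    df["p_value"] = np.nan
    df.loc[quantified, "p_value"] = p
    df["adjusted_p"] = np.nan
    df.loc[quantified, "adjusted_p"] = bh_adjust(p)
    df["klass"] = [
        classify(r.ratio, r.adjusted_p if np.isfinite(r.adjusted_p) else 1.0,
                 r.n_unique_peptides, params)
        for r in df.itertuples()
    ]
    df["neg_log10_adj_p"] = -np.log10(df["adjusted_p"])
    df.attrs.update({"n_dropped": n_dropped, "background": info,
                     "params": params.__dict__})
    return df


def ms_if_correlation(ms_ratios, if_ratios) -> dict:
    """Pearson correlation of MS vs immunofluorescence enrichment ratios.

    The IF enrichment ratio of a marker is (FASS %)/(SYN %) of
    marker-positive events.  Returns r, r^2 and the two-tailed p from the
    t transform.
    """
    ms = np.asarray(ms_ratios, dtype=float)
    iff = np.asarray(if_ratios, dtype=float)
    if ms.size != iff.size or ms.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if ms.std() == 0 or iff.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(ms, iff)
    return {"r": float(r), "r_squared": float(r * r), "p": float(p),
            "n": int(ms.size)}
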