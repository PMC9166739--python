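"""Spot detection on standardized, merged, smoothed channel images.

The detection path mirrors a classic two-channel particle macro: each
channel is standardized (mean subtracted, divided by its SD), the
pixelwise maximum across channels is taken so particles present in either
channel appear in one working image, the merged image is median-filtered
and Gaussian-blurred, and bell-shaped blobs are located with a
noise-tolerant local-maximum detector.  "Tolerance to noise" is a
prominence threshold in standardized-intensity units: a local maximum is
kept only if its value exceeds the level at which its basin merges with a
higher basin by at least the tolerance.

Manual thumbnail review is replaced by the two automatable rejection
rules: proximity to the image border (the measurement circle plus the
background annulus must fit inside the grid) and the presence of a
competing particle within a configurable distance.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .frames import ImageFrame

__all__ = [
    "DetectionParams",
    "CandidateEvent",
    "standardize_channel",
    "combine_max",
    "smooth",
    "find_maxima",
    "qc_filter",
    "detect_frame",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection stage tunables.

    ``gaussian_radius_px`` follows the common blur-radius convention
    sigma = radius / 2.  ``noise_tolerance`` is in standardized-intensity
    units (the merged image is built from z-scored channels, so 3 is about
    3 SDs).  ``border_margin_px`` of ``None`` resolves at run time to the
    background-annulus outer radius when quantification parameters are
    known, else to ``roi_radius_px``.
    """

    median_radius_px: int = 3
    gaussian_radius_px: float = 3.0
    noise_tolerance: float = 3.0
    roi_radius_px: int = 24
    border_margin_px: int | None = None
    competing_distance_px: float | None = None  # default 2 * roi_radius_px

    def __post_init__(self) -> None:
        if self.median_radius_px <= 0 or self.gaussian_radius_px <= 0:
            raise ValueError("filter radii must be positive")
        if self.noise_tolerance <= 0:
            raise ValueError("noise_tolerance must be positive")
        if self.roi_radius_px <= 0:
            raise ValueError("roi_radius_px must be positive")

    @property
    def gaussian_sigma_px(self) -> float:
        return self.gaussian_radius_px / 2.0

    @property
    def effective_competing_px(self) -> float:
        return (self.competing_distance_px
                if self.competing_distance_px is not None
                else 2.0 * self.roi_radius_px)


@dataclass
class CandidateEvent:
    """One detected maximum (0-based continuous coords, x = column)."""

    x_px: float
    y_px: float
    merged_peak_value: float
    qc_status: str = "accepted"


def standardize_channel(grid: np.ndarray, name: str = "channel") -> np.ndarray:
    """Centre and reduce a grid: subtract its mean, divide by its SD."""
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError(f"{name}: empty grid")
    sd = g.std()
    if sd == 0:
        raise ValueError(f"{name}: zero variance, cannot standardize")
    return (g - g.mean()) / sd


def combine_max(zA: np.ndarray, zB: np.ndarray) -> np.ndarray:
    """Pixelwise maximum of two (standardized) grids."""
    zA = np.asarray(zA, dtype=float)
    zB = np.asarray(zB, dtype=float)
    if zA.shape != zB.shape:
        raise ValueError(f"shape mismatch: {zA.shape} vs {zB.shape}")
    return np.maximum(zA, zB)


def smooth(grid: np.ndarray, params: DetectionParams = DetectionParams()) -> np.ndarray:
    """Median filter (circular footprint) then Gaussian blur."""
    g = np.asarray(grid, dtype=float)
    med = ndimage.median_filter(g, footprint=disk(params.median_radius_px))
    return ndimage.gaussian_filter(med, sigma=params.gaussian_sigma_px)


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _plateau_centroid(g: np.ndarray, row: int, col: int) -> tuple[float, float]:
    """Centroid (x, y) of the 8-connected equal-valued plateau at a peak."""
    h, w = g.shape
    v = g[row, col]
    seen = {(row, col)}
    queue = deque([(row, col)])
    sr = sc = 0.0
    n = 0
    while queue:
        r, c = queue.popleft()
        sr += r
        sc += c
        n += 1
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and (rr, cc) not in seen and g[rr, cc] == v:
                seen.add((rr, cc))
                queue.append((rr, cc))
    return sc / n, sr / n  # (x, y)


def find_maxima(grid: np.ndarray, noise_tolerance: float) -> list[CandidateEvent]:
    """Noise-tolerant local maxima (prominence >= tolerance).

    A union-find sweep over pixels in descending intensity order tracks,
    for every growing basin, the value and location of its peak.  When a
    basin merges into a higher one at level ``v``, its peak is retained
    only if ``peak - v >= noise_tolerance``; the last surviving basin is
    retained if its peak clears the global minimum by the tolerance.
    Equal-valued plateaus report their centroid.  The result is invariant
    to adding a constant to the grid.
    """
    if noise_tolerance <= 0:
        raise ValueError("noise_tolerance must be positive")
    g = np.asarray(grid, dtype=float)
    h, w = g.shape
    flat = g.ravel()
    order = np.argsort(-flat, kind="stable")  # desc value, then row-major

    parent = np.full(flat.size, -1, dtype=np.int64)
    peak_of = np.empty(flat.size, dtype=np.int64)  # root -> peak flat index
    birth = np.empty(flat.size, dtype=np.int64)    # root -> processing rank
    retained: list[int] = []

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    for rank, p in enumerate(order):
        r, c = divmod(int(p), w)
        roots = set()
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                q = rr * w + cc
                if parent[q] != -1:
                    roots.add(find(q))
        if not roots:
            parent[p] = p
            peak_of[p] = p
            birth[p] = rank
            continue
        survivor = min(roots, key=lambda t: birth[t])
        parent[p] = survivor
        for t in roots:
            if t == survivor:
                continue
            if flat[peak_of[t]] - flat[p] >= noise_tolerance:
                retained.append(int(peak_of[t]))
            parent[t] = survivor

    # the last surviving basin: prominence measured to the global minimum
    final_root = find(int(order[0]))
    if flat[peak_of[final_root]] - flat.min() >= noise_tolerance:
        retained.append(int(peak_of[final_root]))

    events = []
    for p in retained:
        r, c = divmod(p, w)
        x, y = _plateau_centroid(g, r, c)
        events.append(CandidateEvent(x_px=x, y_px=y, merged_peak_value=float(flat[p])))
    events.sort(key=lambda e: (-e.merged_peak_value, e.y_px, e.x_px))
    return events


def qc_filter(events: list[CandidateEvent], shape: tuple[int, int],
              params: DetectionParams = DetectionParams(),
              outer_radius_px: int | None = None) -> list[CandidateEvent]:
    """Set qc_status on each candidate (border and competing-particle rules).

    ``outer_radius_px`` is the background-annulus outer radius of the
    quantification stage; when given (and no explicit border margin is
    configured) it defines the border margin so that every accepted event
    can be fully measured.  Competing candidates within
    ``competing_distance_px`` reject each other; a border rejection takes
    precedence.  Accepted + rejected always equals the number of inputs.
    """
    h, w = shape
    margin = params.border_margin_px
    if margin is None:
        margin = outer_radius_px if outer_radius_px is not None else params.roi_radius_px
    comp_d = params.effective_competing_px

    out = [replace(e, qc_status="accepted") for e in events]
    for e in out:
        if not (margin <= e.x_px <= w - 1 - margin and margin <= e.y_px <= h - 1 - margin):
            e.qc_status = "rejected_border"
    if len(out) > 1:
        xy = np.array([[e.x_px, e.y_px] for e in out])
        d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        crowded = (d2 < comp_d ** 2).any(axis=1)
        for e, bad in zip(out, crowded):
            if bad and e.qc_status == "accepted":
                e.qc_status = "rejected_competing"
    return out


def detect_frame(frame: ImageFrame, params: DetectionParams = DetectionParams(),
                 outer_radius_px: int | None = None,
                 channels: list[str] | None = None
                 ) -> tuple[list[CandidateEvent], np.ndarray]:
    """Full detection path on one frame.

    standardize each channel -> pixelwise max-merge -> median + Gaussian
    smoothing -> noise-tolerant maxima -> QC.  Returns the QC-labelled
    candidates and the merged smoothed working image.
    """
    names = channels or frame.channel_names
    z = standardize_channel(frame.channels[names[0]], names[0])
    for n in names[1:]:
        z = combine_max(z, standardize_channel(frame.channels[n], n))
    sm = smooth(z, params)
    events = find_maxima(sm, params.noise_tolerance)
    return qc_filter(events, frame.shape, params, outer_radius_px), sm
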