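"""Per-event, per-channel intensity and centroid measurement.

For each accepted detection a circular region of interest (default radius
24 px) is placed at the shared detection centre on the *raw* channel
grids (standardization and smoothing exist only for detection).  Local
background per pixel is the median (configurable: mean) of a
doughnut-shaped annulus surrounding the circle; the integrated intensity
is the ROI sum minus background times the ROI pixel count.  Per-channel
centroids are intensity-weighted means of the background-subtracted,
floored-at-zero ROI pixels, and the inter-signal distance is the
Euclidean distance between the two channel centroids in micrometres.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .detection import CandidateEvent
from .frames import ImageFrame

__all__ = [
    "QuantParams",
    "ChannelMeasurement",
    "EventMeasurement",
    "measure_channel",
    "measure_event",
    "write_cytofile",
    "read_cytofile",
    "CYTOFILE_COLUMNS",
]


@dataclass(frozen=True)
class QuantParams:
    """Quantification tunables.

    ``background_statistic`` defaults to the annulus mean: the competing-
    particle QC rule already guarantees a particle-free annulus for
    accepted events, and the mean is ~25% less noisy than the median,
    which matters because the background error is multiplied by the ROI
    area.  The median remains available for data measured without
    competing-particle rejection.

    ``centroid_mode`` selects how the per-channel centroid is localized:
    ``"refined"`` (default) iterates an intensity-weighted centroid inside
    a small moving disc (radius ``refine_radius_px``) seeded at the
    brightest ROI pixel, which removes the systematic pull toward the ROI
    centre that positive-clipped noise exerts over a wide ROI;
    ``"full_roi"`` is the plain one-shot weighted centroid over the whole
    measurement circle.
    """

    roi_radius_px: int = 24
    doughnut_outer_px: int = 30
    background_statistic: str = "mean"  # or "median"
    centroid_mode: str = "refined"  # or "full_roi"
    refine_radius_px: int = 6

    def __post_init__(self) -> None:
        if self.doughnut_outer_px <= self.roi_radius_px:
            raise ValueError("doughnut_outer_px must exceed roi_radius_px")
        if self.background_statistic not in ("median", "mean"):
            raise ValueError("background_statistic must be 'median' or 'mean'")
        if self.centroid_mode not in ("refined", "full_roi"):
            raise ValueError("centroid_mode must be 'refined' or 'full_roi'")
        if not 0 < self.refine_radius_px <= self.roi_radius_px:
            raise ValueError("refine_radius_px must be in (0, roi_radius_px]")


@dataclass
class ChannelMeasurement:
    centroid_px: tuple[float, float]  # (x, y) in pixels, continuous
    integrated_corrected: float
    background_per_pixel: float


@dataclass
class EventMeasurement:
    frame_id: str
    event_id: int
    channels: dict[str, ChannelMeasurement]
    inter_signal_distance_um: float
    qc_status: str = "accepted"


@lru_cache(maxsize=16)
def _masks(roi_radius: int, outer_radius: int):
    """Offsets of ROI-disc and annulus pixels relative to the centre."""
    r = outer_radius
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = xx ** 2 + yy ** 2
    roi = d2 <= roi_radius ** 2
    ring = (d2 > roi_radius ** 2) & (d2 <= outer_radius ** 2)
    return (yy[roi], xx[roi]), (yy[ring], xx[ring])


@lru_cache(maxsize=16)
def _disc(radius: int):
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    m = xx ** 2 + yy ** 2 <= radius ** 2
    return yy[m], xx[m]


def _refined_centroid(g: np.ndarray, cx: int, cy: int, bg: float,
                      roi_dy: np.ndarray, roi_dx: np.ndarray,
                      refine_radius: int, max_iter: int = 30
                      ) -> tuple[float, float]:
    """Moving-window floored-weight centroid seeded at the brightest ROI pixel.

    The window is a disc of ``refine_radius`` pixels re-centred on the
    running estimate each iteration; because the window is symmetric about
    the estimate, clipped noise exerts no net pull once converged.
    """
    h, w = g.shape
    vals = np.maximum(g[cy + roi_dy, cx + roi_dx] - bg, 0.0)
    if vals.sum() <= 0:
        return float(cx), float(cy)
    k = int(np.argmax(vals))
    x, y = float(cx + roi_dx[k]), float(cy + roi_dy[k])
    dy, dx = _disc(refine_radius)
    for _ in range(max_iter):
        ix, iy = int(round(x)), int(round(y))
        ix = min(max(ix, refine_radius), w - 1 - refine_radius)
        iy = min(max(iy, refine_radius), h - 1 - refine_radius)
        wts = np.maximum(g[iy + dy, ix + dx] - bg, 0.0)
        total = wts.sum()
        if total <= 0:
            break
        nx = ix + float((wts * dx).sum()) / total
        ny = iy + float((wts * dy).sum()) / total
        if abs(nx - x) + abs(ny - y) < 1e-3:
            return nx, ny
        x, y = nx, ny
    return x, y


def measure_channel(grid: np.ndarray, center_px: tuple[float, float],
                    params: QuantParams = QuantParams()) -> ChannelMeasurement:
    """Background-corrected integrated intensity and centroid in one channel.

    The ROI and annulus must lie fully inside the grid (the QC border rule
    guarantees this for accepted events); a violation raises ValueError.
    Centroid falls back to the geometric centre when the corrected mass in
    the ROI is not positive.
    """
    g = np.asarray(grid, dtype=float)
    h, w = g.shape
    cx, cy = int(round(center_px[0])), int(round(center_px[1]))
    r_out = params.doughnut_outer_px
    if not (r_out <= cx <= w - 1 - r_out and r_out <= cy <= h - 1 - r_out):
        raise ValueError(
            f"ROI at ({cx}, {cy}) with outer radius {r_out} exits the "
            f"{h}x{w} grid; qc_filter should have rejected this event")
    (roi_dy, roi_dx), (ring_dy, ring_dx) = _masks(params.roi_radius_px, r_out)
    roi_vals = g[cy + roi_dy, cx + roi_dx]
    ring_vals = g[cy + ring_dy, cx + ring_dx]
    bg = float(np.median(ring_vals) if params.background_statistic == "median"
               else np.mean(ring_vals))
    integrated = float(roi_vals.sum() - bg * roi_vals.size)
    if params.centroid_mode == "refined":
        centroid = _refined_centroid(g, cx, cy, bg, roi_dy, roi_dx,
                                     params.refine_radius_px)
    else:
        weights = np.maximum(roi_vals - bg, 0.0)
        total = weights.sum()
        if total <= 0:
            centroid = (float(cx), float(cy))
        else:
            centroid = (float(cx + (weights * roi_dx).sum() / total),
                        float(cy + (weights * roi_dy).sum() / total))
    return ChannelMeasurement(centroid, integrated, bg)


def measure_event(frame: ImageFrame, event: CandidateEvent, event_id: int = 0,
                  params: QuantParams = QuantParams()) -> EventMeasurement:
    """Measure every channel at the shared detection centre of one event."""
    center = (event.x_px, event.y_px)
    channels = {name: measure_channel(grid, center, params)
                for name, grid in frame.channels.items()}
    names = frame.channel_names
    if len(names) >= 2:
        (x1, y1) = channels[names[0]].centroid_px
        (x2, y2) = channels[names[1]].centroid_px
        dist = math.hypot(x2 - x1, y2 - y1) * frame.pixel_size_um
    else:
        dist = 0.0
    return EventMeasurement(frame.frame_id, event_id, channels, dist,
                            qc_status=event.qc_status)


CYTOFILE_COLUMNS = [
    "frame_id", "event_id",
    "x_um_ch1", "y_um_ch1", "x_um_ch2", "y_um_ch2",
    "intensity_ch1", "intensity_ch2",
    "background_ch1", "background_ch2",
    "distance_um", "qc_status",
]


def write_cytofile(measurements: list[EventMeasurement], path,
                   pixel_size_um: float,
                   channel_order: list[str] | None = None) -> None:
    """Write the pooled per-event table (one row per accepted event).

    Column layout is fixed (see ``CYTOFILE_COLUMNS``); channel 1 and 2
    follow ``channel_order`` (default: key order of the first event).
    Coordinates are centroids in micrometres.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CYTOFILE_COLUMNS)
        for m in measurements:
            order = channel_order or list(m.channels)
            c1, c2 = m.channels[order[0]], m.channels[order[1]]
            values = [
                c1.centroid_px[0] * pixel_size_um,
                c1.centroid_px[1] * pixel_size_um,
                c2.centroid_px[0] * pixel_size_um,
                c2.centroid_px[1] * pixel_size_um,
                c1.integrated_corrected, c2.integrated_corrected,
                c1.background_per_pixel, c2.background_per_pixel,
                m.inter_signal_distance_um,
            ]
            writer.writerow([m.frame_id, m.event_id,
                             *(repr(float(v)) for v in values), m.qc_status])


def read_cytofile(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CYTOFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cytofile columns {sorted(missing)}")
    return df
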