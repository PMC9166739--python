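"""Multi-channel image frames and TIFF round-tripping.

The observational unit of the pipeline is a small number of co-registered
2-D fluorescence channels sharing one pixel grid and a physical pixel size
in micrometres.  Frames are stored on disk as multi-page 32-bit float TIFF,
one page per channel, with the channel names, pixel size and frame id
embedded as JSON in the TIFF description tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageFrame:
    """Named channel grids plus pixel size.

    Parameters
    ----------
    channels
        Mapping of channel label to 2-D intensity grid (arbitrary units).
        All grids must share identical dimensions.
    pixel_size_um
        Physical pixel size in micrometres per pixel; must be positive.
    frame_id
        Free-text identifier carried through all downstream tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    frame_id: str = "frame_0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageFrame requires at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: np.asarray(g).shape for name, g in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError("channel grids must be 2-D")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel grids differ in shape: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def to_tiff(self, path) -> None:
        stack = np.stack([self.channels[c] for c in self.channel_names]).astype(np.float32)
        desc = json.dumps(
            {
                "channels": self.channel_names,
                "pixel_size_um": self.pixel_size_um,
                "frame_id": self.frame_id,
            }
        )
        tifffile.imwrite(path, stack, description=desc)

    @classmethod
    def from_tiff(cls, path, channels: list[str] | None = None,
                  pixel_size_um: float | None = None,
                  frame_id: str | None = None) -> "ImageFrame":
        """Read a frame written by :meth:`to_tiff`.

        Metadata arguments override anything found in the file, which allows
        reading plain TIFF stacks produced elsewhere.
        """
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description or ""
        meta: dict = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        if stack.ndim == 2:
            stack = stack[None]
        names = channels or meta.get("channels") or [f"ch{i + 1}" for i in range(len(stack))]
        px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
        if px is None:
            raise ValueError(f"{path}: pixel size neither in file metadata nor supplied")
        fid = frame_id or meta.get("frame_id") or "frame_0"
        return cls({n: stack[i] for i, n in enumerate(names)}, float(px), fid)
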