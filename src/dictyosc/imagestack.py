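"""Image stacks: ordered grayscale frames with timestamps and a pixel size.

Stacks are written as multi-page 16-bit grayscale TIFF with a sidecar CSV of
frame timestamps (columns ``frame_index,time_s``), the on-disk contract
between the simulator and the image-analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """Ordered grayscale frames sharing a shape, with per-frame times.

    role is a free label ("bf" for bright-field-like, "tirf" for
    TIRF-like) used by the pipeline to pick the right descriptors.
    """

    frames: np.ndarray  # (n_frames, H, W)
    time_s: np.ndarray  # (n_frames,)
    pixel_size_um: float
    role: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.time_s.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("frame timestamps must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    # ---------------------------------------------------------------- I/O
    def write(self, tiff_path: str | Path, timestamps_path: str | Path | None = None) -> None:
        """Write frames as multi-page 16-bit TIFF plus a timestamp CSV.

        Frames are clipped to [0, 65535] and rounded; the sidecar defaults
        to ``<tiff stem>_timestamps.csv`` next to the TIFF.
        """
        tiff_path = Path(tiff_path)
        if timestamps_path is None:
            timestamps_path = tiff_path.with_name(tiff_path.stem + "_timestamps.csv")
        data = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(tiff_path, data, metadata={"pixel_size_um": self.pixel_size_um})
        pd.DataFrame(
            {"frame_index": np.arange(len(self)), "time_s": self.time_s}
        ).to_csv(timestamps_path, index=False)

    @classmethod
    def read(
        cls,
        tiff_path: str | Path,
        timestamps_path: str | Path | None = None,
        pixel_size_um: float | None = None,
        role: str = "",
    ) -> "ImageStack":
        tiff_path = Path(tiff_path)
        if timestamps_path is None:
            timestamps_path = tiff_path.with_name(tiff_path.stem + "_timestamps.csv")
        with tifffile.TiffFile(tiff_path) as tf:
            frames = tf.asarray()
            if pixel_size_um is None:
                meta = tf.shaped_metadata or []
                for m in meta:
                    if "pixel_size_um" in m:
                        pixel_size_um = float(m["pixel_size_um"])
                        break
        if pixel_size_um is None:
            raise ValueError("pixel_size_um not in TIFF metadata; pass it explicitly")
        if frames.ndim == 2:
            frames = frames[None]
        ts = pd.read_csv(timestamps_path)["time_s"].to_numpy()
        return cls(frames.astype(float), ts, pixel_size_um, role=role)
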