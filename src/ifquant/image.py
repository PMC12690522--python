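"""In-memory image containers and TIFF round-tripping.

A :class:`MIPImage` holds the channels of one maximum-intensity-projected
field of view as named 2D uint16 rasters plus the physical pixel size.
Multi-channel images are stored on disk as multi-page 16-bit grayscale TIFF,
one page per channel, with the channel name in each page description and the
pixel size in the file's JSON shaped metadata.

Coordinates are (row, col), 0-based, origin top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class MIPImage:
    """Multi-channel 2D 16-bit raster with physical pixel size.

    Parameters
    ----------
    channels
        Mapping channel name -> 2D uint16 array. All channels share a shape.
    pixel_size
        Physical edge length of one pixel in micrometres (> 0).
    image_id
        Identifier used to group measurements downstream.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MIPImage requires at least one channel")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if ch.dtype != np.uint16:
                raise ValueError(f"channel {name!r} must be uint16, got {ch.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)


@dataclass
class LabelMask:
    """Labeled segmentation: 0 = background, objects numbered 1..n_objects."""

    labels: np.ndarray
    n_objects: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if self.n_objects < 0:
            self.n_objects = int(self.labels.max(initial=0))
        present = np.unique(self.labels)
        if not np.array_equal(present[present > 0], np.arange(1, self.n_objects + 1)):
            raise ValueError("labels are not consecutive 1..n_objects")


def write_mip(path, image: MIPImage) -> None:
    """Write a MIPImage as a multi-page 16-bit TIFF, one page per channel."""
    meta = {"pixel_size_um": image.pixel_size, "image_id": image.image_id,
            "channels": image.channel_names}
    with tifffile.TiffWriter(path) as tif:
        for i, (name, ch) in enumerate(image.channels.items()):
            desc = json.dumps(meta) if i == 0 else name
            tif.write(ch, photometric="minisblack", description=desc)


def read_mip(path, channel_names: list[str] | None = None,
             pixel_size: float | None = None, image_id: str | None = None) -> MIPImage:
    """Read a single- or multi-page 16-bit TIFF into a MIPImage.

    Channel names and pixel size are recovered from the metadata written by
    :func:`write_mip`; for foreign TIFFs supply them explicitly
    (channels default to ``ch0, ch1, ...`` and pixel size to 1 µm).
    """
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        desc = tif.pages[0].description or ""
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    names = channel_names or meta.get("channels") or [f"ch{i}" for i in range(len(pages))]
    if len(names) != len(pages):
        raise ValueError(f"{len(names)} channel names for {len(pages)} TIFF pages")
    px = pixel_size if pixel_size is not None else float(meta.get("pixel_size_um", 1.0))
    iid = image_id if image_id is not None else str(meta.get("image_id", ""))
    channels = {n: np.asarray(p, dtype=np.uint16) for n, p in zip(names, pages)}
    return MIPImage(channels=channels, pixel_size=px, image_id=iid)


def write_labels(path, mask: LabelMask) -> None:
    """Write a label mask as 16-bit TIFF (labels above 65535 are rejected)."""
    if mask.n_objects > 65535:
        raise ValueError("more than 65535 objects cannot be stored as 16-bit labels")
    tifffile.imwrite(path, mask.labels.astype(np.uint16), photometric="minisblack")


def read_labels(path) -> LabelMask:
    labels = np.asarray(tifffile.imread(path)).astype(np.int32)
    return LabelMask(labels=labels)
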