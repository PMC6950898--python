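"""Multi-channel image container and OME-TIFF IO.

Images are kept as named 2-D float channels with a physical pixel size in
micrometres.  On disk they are OME-TIFFs whose Channel names and
PhysicalSizeX/Y carry the same information, so bundles round-trip without a
sidecar file.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MultiChannelImage:
    """Named-channel 2-D intensity grid with pixel size (um/px)."""

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image needs at least one channel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {', '.join(self.names)}") from None

    def stack(self) -> np.ndarray:
        return np.stack([self.channels[n] for n in self.names])


def write_image(path: str | Path, img: MultiChannelImage,
                dtype: str | None = None, compression: str = "zlib") -> None:
    """Write as OME-TIFF (axes CYX) with channel names and pixel size."""
    data = img.stack()
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(
        Path(path), data, ome=True, compression=compression,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": img.names},
            "PhysicalSizeX": img.pixel_size, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": img.pixel_size, "PhysicalSizeYUnit": "µm",
        })


def read_image(path: str | Path, channel_names: list[str] | None = None,
               pixel_size: float | None = None) -> MultiChannelImage:
    """Read a TIFF / OME-TIFF as a :class:`MultiChannelImage`.

    Channel names and pixel size come from OME metadata when present;
    ``channel_names`` / ``pixel_size`` override or fill in.  A file without
    a pixel size and no override is an error — downstream measurements are
    physical areas.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_names, meta_px = _parse_ome(tf)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 2-D or CYX stack, got {data.shape}")
    names = channel_names or meta_names
    if not names:
        names = [f"C{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} channels but names {names}")
    px = pixel_size if pixel_size is not None else meta_px
    if px is None or px <= 0:
        raise ValueError(
            f"{path}: no pixel size in metadata; pass pixel_size explicitly")
    return MultiChannelImage({n: data[i] for i, n in enumerate(names)}, px)


def _parse_ome(tf: tifffile.TiffFile) -> tuple[list[str] | None, float | None]:
    if not tf.is_ome or not tf.ome_metadata:
        return None, None
    try:
        root = ET.fromstring(tf.ome_metadata)
    except ET.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0][1:]} if root.tag.startswith("{") else {}
    pixels = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    if pixels is None:
        return None, None
    px = pixels.get("PhysicalSizeX")
    chans = (pixels.findall("ome:Channel", ns) if ns
             else pixels.findall("Channel"))
    names = [c.get("Name") for c in chans]
    names = names if names and all(names) else None
    return names, (float(px) if px else None)
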