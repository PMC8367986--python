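"""Multi-channel immunofluorescence image container and TIFF I/O.

An :class:`AnnotatedVesselImage` holds the three channels of a stained tumour
section — CD31 (endothelium / vessels), αSMA (pericytes) and DAPI (nuclei,
used as a tissue proxy) — together with the physical pixel pitch.  Images are
persisted as multi-page TIFF, one page per channel, with the channel name in
each page description so files are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

#: canonical channel names, in page order when written to TIFF
CHANNELS = ("CD31", "aSMA", "DAPI")

#: default physical pixel pitch, µm per pixel (10 px corresponds to 3.2 µm)
DEFAULT_PIXEL_PITCH = 0.32


@dataclass
class AnnotatedVesselImage:
    """Two-dimensional multi-channel raster with physical calibration.

    Parameters
    ----------
    channels
        Mapping of channel name to 2-D intensity array.  All channels must
        share one shape.
    pixel_pitch
        Physical size of one pixel in µm (isotropic).
    """

    channels: dict[str, np.ndarray]
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        if not shapes:
            raise ValueError("image needs at least one channel")
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError(f"channels must be 2-D rasters, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


def write_image_tiff(path: str | Path, image: AnnotatedVesselImage) -> Path:
    """Write one page per channel; channel name goes into the page description."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, arr in image.channels.items():
            tif.write(
                np.asarray(arr, dtype=np.float32),
                description=name,
                metadata=None,
                resolution=(1e4 / image.pixel_pitch, 1e4 / image.pixel_pitch),
                resolutionunit="CENTIMETER",
            )
    return path


def read_image_tiff(
    path: str | Path,
    pixel_pitch: float | None = None,
    channel_map: Mapping[int, str] | None = None,
) -> AnnotatedVesselImage:
    """Read a multi-page TIFF back into an :class:`AnnotatedVesselImage`.

    Channel names are taken from page descriptions; ``channel_map`` (page
    index → name) overrides them for third-party files without descriptions.
    The pitch is recovered from the TIFF resolution tags unless given.
    """
    path = Path(path)
    channels: dict[str, np.ndarray] = {}
    pitch = pixel_pitch
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            if channel_map is not None and i in channel_map:
                name = channel_map[i]
            else:
                desc = (page.description or "").strip()
                name = desc if desc else f"page{i}"
            channels[name] = page.asarray()
            if pitch is None:
                res = page.tags.get("XResolution")
                if res is not None:
                    num, den = res.value
                    if num:
                        pitch = 1e4 * den / num  # pixels/cm back to µm/pixel
    if pitch is None:
        pitch = DEFAULT_PIXEL_PITCH
    return AnnotatedVesselImage(channels=channels, pixel_pitch=pitch)


def write_mask_tiff(path: str | Path, mask: np.ndarray, description: str = "mask") -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8), description=description)
    return path


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(bool)
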