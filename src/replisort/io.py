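"""Image containers and TIFF input/output.

The pipeline works on single optical sections of multi-channel fluorescence
images: a DNA counterstain (used to segment nuclei), a replication-foci
channel (EdU) and optionally a transcription-foci channel (e.g. elongating
RNA Pol II).  Every stage of the analysis consumes the light-weight
containers defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

#: Default physical pixel size (nm) used when the TIFF carries no calibration.
DEFAULT_PIXEL_SIZE_NM = 45.0

CHANNEL_ROLES = ("DNA", "RF", "TF")


@dataclass
class ChannelImage:
    """A single 2-D intensity image of one channel of one frame.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative, finite intensities (any unsigned integer
        or float dtype; converted to float64).
    pixel_size_nm : float
        Physical size of one pixel in nanometres.
    channel_role : {"DNA", "RF", "TF"}
        DNA counterstain, replication foci or transcription foci.
    frame_id : str
        Identifier shared by all channels of one field of view.
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    channel_role: str = "RF"
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"channel_role must be one of {CHANNEL_ROLES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Copy of this image with replaced pixel data (metadata kept)."""
        return ChannelImage(pixels, self.pixel_size_nm, self.channel_role, self.frame_id)


@dataclass
class CountMask:
    """Integer-labelled nucleus mask; label 0 is background.

    ``excluded_labels`` holds manually flagged nuclei (e.g. mitotic cells)
    that every downstream stage skips.
    """

    labels: np.ndarray
    excluded_labels: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.excluded_labels = set(int(v) for v in self.excluded_labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def present_labels(self, include_excluded: bool = False) -> list[int]:
        vals = np.unique(self.labels)
        labels = [int(v) for v in vals if v != 0]
        if not include_excluded:
            labels = [v for v in labels if v not in self.excluded_labels]
        return labels


@dataclass
class FociBinaryMask:
    """Boolean replication-foci mask plus the threshold that produced it."""

    mask: np.ndarray
    threshold_value: float
    background_level: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Pixel size in nm from TIFF resolution tags, if present and sane."""
    try:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0 or den == 0:
            return None
        pixels_per_unit = num / den
        # ResolutionUnit: 2 = inch, 3 = cm; anything else is unit-less.
        if unit is not None and getattr(unit.value, "value", unit.value) == 3:
            return 1e7 / pixels_per_unit  # cm -> nm
        return None
    except Exception:  # pragma: no cover - defensive against exotic tags
        return None


def read_image_set(
    paths: Sequence[str | Path],
    channel_roles: Sequence[str],
    frame_id: str | None = None,
    pixel_size_nm: float | None = None,
) -> list[ChannelImage]:
    """Read one frame's channels from one multi-page TIFF or several TIFFs.

    With a single path and several roles the pages of the file are split into
    channels; with several paths each file supplies one channel.  All channels
    of a frame must share their shape.  When neither the file metadata nor
    ``pixel_size_nm`` provides a calibration, 45 nm is assumed with a warning.
    """
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(str(p))
    if frame_id is None:
        frame_id = paths[0].stem

    planes: list[np.ndarray] = []
    meta_pixel_size: float | None = None
    if len(paths) == 1 and len(channel_roles) > 1:
        with tifffile.TiffFile(paths[0]) as tf:
            arr = tf.asarray()
            meta_pixel_size = _pixel_size_from_tiff(tf)
        arr = np.atleast_3d(arr)
        if arr.ndim != 3:
            raise ValueError("expected a multi-page 2-D TIFF")
        # accept either (pages, H, W) or (H, W, channels)
        if arr.shape[0] == len(channel_roles):
            planes = [arr[i] for i in range(arr.shape[0])]
        elif arr.shape[-1] == len(channel_roles):
            planes = [arr[..., i] for i in range(arr.shape[-1])]
        else:
            raise ValueError(
                f"file has {arr.shape[0]} pages but {len(channel_roles)} roles given"
            )
    else:
        if len(paths) != len(channel_roles):
            raise ValueError("need one path per channel role")
        for p in paths:
            with tifffile.TiffFile(p) as tf:
                planes.append(np.squeeze(tf.asarray()))
                if meta_pixel_size is None:
                    meta_pixel_size = _pixel_size_from_tiff(tf)

    shapes = {plane.shape for plane in planes}
    if len(shapes) != 1:
        raise ValueError(f"channel shape mismatch within frame: {sorted(shapes)}")

    if pixel_size_nm is None:
        pixel_size_nm = meta_pixel_size
    if pixel_size_nm is None:
        warnings.warn(
            f"no pixel size available; assuming {DEFAULT_PIXEL_SIZE_NM} nm",
            stacklevel=2,
        )
        pixel_size_nm = DEFAULT_PIXEL_SIZE_NM

    return [
        ChannelImage(plane, pixel_size_nm, role, frame_id)
        for plane, role in zip(planes, channel_roles)
    ]


def write_channel_image(path: str | Path, img: ChannelImage) -> None:
    """Write an intensity image as a float32 TIFF with resolution tags."""
    px_per_cm = 1e7 / img.pixel_size_nm
    tifffile.imwrite(
        str(path),
        img.pixels.astype(np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def write_count_mask(path: str | Path, mask: CountMask) -> None:
    """Write a label mask as a 16-bit TIFF (labels must fit in uint16)."""
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def read_count_mask(path: str | Path, excluded_labels: set[int] | None = None) -> CountMask:
    labels = np.squeeze(tifffile.imread(str(path))).astype(np.int64)
    return CountMask(labels, excluded_labels or set())


def write_foci_mask(path: str | Path, foci: FociBinaryMask) -> None:
    """Write a foci mask as an 8-bit {0, 255} TIFF (ImageJ binary convention)."""
    tifffile.imwrite(str(path), (foci.mask.astype(np.uint8) * 255))


def read_foci_mask(
    path: str | Path, threshold_value: float = float("nan"), background_level: float = float("nan")
) -> FociBinaryMask:
    arr = np.squeeze(tifffile.imread(str(path)))
    return FociBinaryMask(arr > 0, threshold_value, background_level)
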