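"""Pre-processing: nucleus segmentation, background handling, foci binarization.

The replication-foci analysis needs three prepared inputs per frame: a count
mask of nuclei (from the DNA channel), a background-subtracted foci intensity
image, and a binary foci mask obtained by thresholding the raw foci image at
a multiple of the background level measured in EdU-negative (G1/G2) nuclei.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage import filters, measure, restoration

from .io import ChannelImage, CountMask, FociBinaryMask

DEFAULT_MIN_AREA_PX = 500
DEFAULT_BALL_RADIUS_PX = 10
DEFAULT_FOCI_FACTOR = 1.5


def segment_nuclei(
    dna: ChannelImage,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    fill_holes: bool = True,
) -> CountMask:
    """Segment nuclei from the DNA channel into a labelled count mask.

    A global isodata (iterative intermeans) threshold binarizes the image;
    holes are optionally filled; 8-connected components with area below
    ``min_area_px`` are dropped and the survivors relabelled 1..n.

    A blank (zero-variance) image yields an empty mask with a warning.
    """
    if dna.channel_role != "DNA":
        raise ValueError("segment_nuclei expects the DNA channel")
    px = dna.pixels
    if np.ptp(px) == 0:
        warnings.warn("blank DNA image: no nuclei segmented", stacklevel=2)
        return CountMask(np.zeros(px.shape, dtype=np.int32))
    thr = filters.threshold_isodata(px)
    binary = px >= thr
    if fill_holes:
        binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    if min_area_px > 1 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        keep = areas >= min_area_px
        keep[0] = False
        labels = np.where(keep[labels], labels, 0)
    # relabel sequentially so downstream tables have compact ids
    labels = measure.label(labels > 0, connectivity=2)
    return CountMask(labels.astype(np.int32))


def subtract_background(
    img: ChannelImage, ball_radius_px: int = DEFAULT_BALL_RADIUS_PX
) -> ChannelImage:
    """Rolling-ball background subtraction, clipped at zero.

    Standard rolling-ball estimate (ball structuring element of the given
    radius rolled under the intensity surface); the smooth background is
    subtracted from the image.  A constant image maps to all zeros.
    """
    if ball_radius_px < 1:
        raise ValueError("radius must be ≥ 1")
    background = restoration.rolling_ball(img.pixels, radius=ball_radius_px)
    out = np.clip(img.pixels - background, 0.0, None)
    return img.with_pixels(out)


def estimate_background_level(
    rf: ChannelImage, mask: CountMask, reference_labels: set[int]
) -> float:
    """Median raw foci-channel intensity over pixels of reference nuclei.

    The reference nuclei are EdU-negative (G1/G2) cells, typically from the
    first frame of a dataset; their pooled pixel median estimates the
    background level of the foci channel.
    """
    if not reference_labels:
        raise ValueError(
            "empty reference set: provide reference (G1/G2) nuclei labels "
            "or an explicit background value"
        )
    if rf.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    sel = np.isin(mask.labels, list(reference_labels))
    if not sel.any():
        raise ValueError("reference labels not present in the mask")
    return float(np.median(rf.pixels[sel]))


def binarize_foci(
    rf: ChannelImage,
    background_level: float | None = None,
    factor: float = DEFAULT_FOCI_FACTOR,
    explicit_threshold: float | None = None,
) -> FociBinaryMask:
    """Threshold the raw foci channel into a binary foci mask.

    The threshold is ``factor × background_level`` (default factor 1.5)
    unless an explicit absolute threshold is supplied.  Pixels exactly at
    the threshold count as foreground.
    """
    if explicit_threshold is not None:
        threshold = float(explicit_threshold)
        background = float(background_level) if background_level is not None else float("nan")
    else:
        if background_level is None:
            raise ValueError("provide background_level or explicit_threshold")
        if factor <= 0:
            raise ValueError("factor must be positive")
        if background_level < 0:
            raise ValueError("background_level must be ≥ 0")
        if background_level == 0:
            raise ValueError(
                "background level is 0; factor-based thresholding is undefined — "
                "pass explicit_threshold instead"
            )
        background = float(background_level)
        threshold = factor * background
    return FociBinaryMask(rf.pixels >= threshold, threshold, background)


def auto_reference_labels(
    rf: ChannelImage, mask: CountMask, fraction: float = 0.25
) -> set[int]:
    """Pick likely EdU-negative nuclei as background references.

    Nuclei are ranked by their mean raw foci-channel intensity and the
    dimmest ``fraction`` (at least one) returned.  This automates the
    first-pass identification of G1/G2 cells used to set the background
    level; an explicit user-supplied reference set always takes precedence.
    """
    labels = mask.present_labels()
    if not labels:
        raise ValueError("mask contains no nuclei")
    means = ndimage.mean(rf.pixels, labels=mask.labels, index=labels)
    order = np.argsort(means, kind="stable")
    n_ref = max(1, int(round(fraction * len(labels))))
    return {int(labels[i]) for i in order[:n_ref]}
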