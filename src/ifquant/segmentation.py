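"""Nuclear segmentation: probability map, Otsu binarization, watershed split.

The chain mirrors standard semi-automated image cytometry: a per-pixel
nuclear probability map is binarized with Otsu's threshold and touching
nuclei are separated by a distance-transform watershed. The probability map
here is a deterministic classical operator (Gaussian smoothing + robust
percentile rescaling); a trained pixel classifier can be slotted in by
passing its output straight to :func:`otsu_threshold`.

Conventions: 4-connectivity for object labeling and flooding, 8-connectivity
for local-maximum (seed) detection; binarization uses strict ``>``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import DegenerateImageError
from .image import LabelMask, MIPImage

__all__ = ["nuclear_probability", "otsu_threshold", "watershed_split", "segment_nuclei"]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def nuclear_probability(image: MIPImage, channel: str,
                        smoothing_scale: float = 0.5) -> np.ndarray:
    """Map a counterstain channel to a [0,1] nuclear probability raster.

    Gaussian smoothing at ``smoothing_scale`` (um; sigma in pixels is
    scale / pixel_size) followed by linear rescaling between the 0.1th and
    99.9th intensity percentiles, clipped to [0,1]. Deterministic.

    Raises
    ------
    KeyError
        If ``channel`` is not present in the image.
    DegenerateImageError
        If the channel is constant (no dynamic range to rescale).
    """
    if channel not in image.channels:
        raise KeyError(f"channel {channel!r} not in {image.channel_names}")
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be >= 0")
    raw = image.channels[channel].astype(np.float64)
    if raw.max() == raw.min():
        raise DegenerateImageError(
            f"channel {channel!r} is constant (value {raw.flat[0]:.0f}); "
            "cannot form a probability map")
    sigma = smoothing_scale / image.pixel_size
    smoothed = ndi.gaussian_filter(raw, sigma=sigma) if sigma > 0 else raw
    lo, hi = np.percentile(smoothed, [0.1, 99.9])
    if hi == lo:  # pathological after smoothing; fall back to full range
        lo, hi = smoothed.min(), smoothed.max()
    return np.clip((smoothed - lo) / (hi - lo), 0.0, 1.0)


def otsu_threshold(prob: np.ndarray, n_bins: int = 256) -> tuple[float, np.ndarray]:
    """Otsu's threshold of a probability map, plus the binary mask.

    The threshold maximizes the between-class variance over an ``n_bins``
    histogram of the map's value range and is reported as the center of the
    argmax bin; the mask is ``prob > threshold`` (strict). Only cuts placed
    directly after a non-empty bin are considered — a cut after an empty bin
    produces the same class partition as an earlier cut, so each candidate
    partition is scored exactly once and ties resolve to the lowest cut.

    Raises :class:`DegenerateImageError` on a constant map (no valid split).
    """
    values = np.asarray(prob, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty probability map")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateImageError("constant probability map: no valid Otsu split")
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts.astype(np.float64) / counts.sum()
    w0 = np.cumsum(p)                       # class-0 weight for cut after bin k
    m = np.cumsum(p * centers)              # running first moment
    mt = m[-1]
    w0c, mc = w0[:-1], m[:-1]               # valid cuts: after bins 0..n_bins-2
    w1c = 1.0 - w0c
    valid = (w0c > 0) & (w1c > 0) & (counts[:-1] > 0)
    var_between = np.zeros(n_bins - 1)
    mu0 = np.divide(mc, w0c, out=np.zeros_like(mc), where=valid)
    mu1 = np.divide(mt - mc, w1c, out=np.zeros_like(mc), where=valid)
    var_between[valid] = (w0c * w1c * (mu0 - mu1) ** 2)[valid]
    idx = int(np.argmax(var_between))
    threshold = float(centers[idx])
    return threshold, values > threshold


def watershed_split(mask: np.ndarray, min_seed_distance: float = 2.5,
                    pixel_size: float = 1.0) -> LabelMask:
    """Split a binary nuclear mask into labeled objects by watershed.

    Seeds are local maxima of the Euclidean distance transform separated by
    at least ``min_seed_distance`` micrometres (8-connected maxima); flooding
    of the negated distance transform assigns every foreground pixel exactly
    one label. Foreground components that received no seed (smaller than the
    seed spacing) keep one label each, so the labeling partitions the mask.

    An empty mask returns a LabelMask with ``n_objects == 0``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return LabelMask(labels=np.zeros(mask.shape, dtype=np.int32), n_objects=0)
    distance = ndi.distance_transform_edt(mask)
    components, _ = ndi.label(mask, structure=_FOUR_CONN)
    min_dist_px = max(1, int(round(min_seed_distance / pixel_size)))
    peaks = peak_local_max(distance, min_distance=min_dist_px, labels=components,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers=markers, mask=mask, connectivity=1)
    # components too small/flat to yield a peak would stay unlabeled: keep them
    orphan = mask & (labels == 0)
    if orphan.any():
        extra, n_extra = ndi.label(orphan, structure=_FOUR_CONN)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    # compact to consecutive 1..n
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return LabelMask(labels=lut[labels], n_objects=len(ids))


def segment_nuclei(image: MIPImage, channel: str, smoothing_scale: float = 0.5,
                   n_bins: int = 256, min_seed_distance: float = 2.5,
                   ) -> tuple[LabelMask, dict]:
    """Full chain: probability map -> Otsu mask -> watershed labels.

    Returns the label mask and a per-image segmentation report
    (threshold, n_objects, foreground_fraction).
    """
    prob = nuclear_probability(image, channel, smoothing_scale)
    threshold, mask = otsu_threshold(prob, n_bins=n_bins)
    labels = watershed_split(mask, min_seed_distance, image.pixel_size)
    report = {
        "image_id": image.image_id,
        "threshold": threshold,
        "n_objects": labels.n_objects,
        "foreground_fraction": float(mask.mean()),
    }
    return labels, report
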