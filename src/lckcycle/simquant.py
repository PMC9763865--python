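"""Membrane/cytoplasm image quantification.

Pipeline (matching a standard ImageJ-style workflow): per-channel modal
background subtraction with 16-bit rescale, average projection of the
central z-planes, Gaussian blur, Otsu segmentation of the nuclear-dye
and membrane-marker channels into nuclear / plasma-membrane (PM) /
cytoplasm (CP) ROIs, and the PM/CP mean-intensity ratio of the target
channel.  ``ratio_to_fraction`` converts a PM/CP ratio r into the
percentage of signal resident at the membrane via ``100*r/(1+r)`` —
this conversion reproduces ratios-to-percent mappings such as
2.5 -> 71%, 1.7 -> 63% and 2.2-2.3 -> ~70%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import ConfigError, SegmentationError

__all__ = [
    "ImageStack",
    "ROISet",
    "PMCPResult",
    "mode_offset",
    "mode_threshold",
    "project_central",
    "blur",
    "make_rois",
    "pm_cp_ratio",
    "ratio_to_fraction",
    "quantify_stack",
]

U16_MAX = 65535.0


@dataclass
class ImageStack:
    """Multi-channel z-stack with named channel roles.

    ``data`` has axes (z, channel, y, x); ``roles`` maps role names
    ("nuclear_dye", "pm_marker", "target") to channel indices.
    """

    data: np.ndarray
    roles: dict[str, int]

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 4:
            raise ConfigError("stack must have axes (z, channel, y, x)")
        idx = list(self.roles.values())
        if len(set(idx)) != len(idx) or any(
                not 0 <= i < self.data.shape[1] for i in idx):
            raise ConfigError("channel roles must resolve uniquely")

    def channel(self, role: str) -> np.ndarray:
        return self.data[:, self.roles[role]]


@dataclass
class ROISet:
    """Pairwise-disjoint binary masks on the projected frame."""

    pm_mask: np.ndarray
    nuclear_mask: np.ndarray
    cp_mask: np.ndarray

    def __post_init__(self):
        overlap = (self.pm_mask & self.nuclear_mask) | \
            (self.pm_mask & self.cp_mask) | (self.nuclear_mask & self.cp_mask)
        if overlap.any():
            raise SegmentationError("ROI masks overlap")


@dataclass(frozen=True)
class PMCPResult:
    pm_mean: float
    cp_mean: float

    @property
    def ratio(self) -> float:
        return self.pm_mean / self.cp_mean

    @property
    def pm_fraction_pct(self) -> float:
        return ratio_to_fraction(self.ratio)


def mode_offset(image: np.ndarray) -> float:
    """Histogram mode of an intensity image (center of the noise peak).

    Values are rounded to integers for the histogram, so integer-valued
    backgrounds are recovered exactly.
    """
    values = np.round(np.asarray(image, float).ravel()).astype(np.int64)
    vmin = values.min()
    return float(np.bincount(values - vmin).argmax() + vmin)


def mode_threshold(stack: ImageStack) -> ImageStack:
    """Subtract each channel's modal intensity, clip at zero and rescale
    to the 16-bit range.  Idempotent: after one pass the mode is 0 and
    the maximum is 65535, so a second pass is the identity."""
    out = np.empty_like(stack.data)
    for c in range(stack.data.shape[1]):
        chan = stack.data[:, c]
        shifted = np.clip(chan - mode_offset(chan), 0, None)
        peak = shifted.max()
        out[:, c] = shifted * (U16_MAX / peak) if peak > 0 else shifted
    return ImageStack(out, dict(stack.roles))


def project_central(stack: ImageStack, n_planes: int = 4) -> ImageStack:
    """Average the central ``n_planes`` z-planes (ties toward lower z).

    Returns a single-plane stack so downstream ops keep one code path.
    """
    z = stack.data.shape[0]
    if z < n_planes:
        raise ConfigError(f"stack has {z} planes < n_planes={n_planes}")
    start = (z - n_planes) // 2
    proj = stack.data[start:start + n_planes].mean(axis=0, keepdims=True)
    return ImageStack(proj, dict(stack.roles))


def blur(image: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Gaussian blur with reflective boundaries (sum-preserving in the
    interior)."""
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(image, float).copy()
    return ndimage.gaussian_filter(np.asarray(image, float), sigma=sigma,
                                   mode="reflect")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = cc_label(mask)
    if labels.max() == 0:
        return mask
    counts = np.bincount(labels.ravel())[1:]
    return labels == (counts.argmax() + 1)


def _otsu_mask(image: np.ndarray, what: str) -> np.ndarray:
    if not np.any(image > 0) or np.ptp(image) == 0:
        raise SegmentationError(f"no foreground in {what} channel")
    return image > threshold_otsu(image)


_FOOTPRINTS = {
    "square": np.ones((3, 3), bool),
    "cross": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
}


def make_rois(projected: ImageStack, erode_iterations: int = 1,
              footprint: str = "square") -> ROISet:
    """Segment nuclear, PM and CP ROIs from a projected frame.

    Otsu threshold per channel, fill holes, single-iteration erosion
    (3x3 square by default), largest connected component per mask.  The
    PM ROI is the marker-positive ring; the CP ROI is the filled PM
    contour minus the ring and the nuclear area.  Assumes one cell per
    field (largest component); crop multi-cell fields beforehand.
    """
    struct = _FOOTPRINTS[footprint]
    nuc_img = projected.channel("nuclear_dye")[0]
    pm_img = projected.channel("pm_marker")[0]
    nuc_raw = _otsu_mask(nuc_img, "nuclear_dye")
    pm_raw = _otsu_mask(pm_img, "pm_marker")

    nuc_filled = ndimage.binary_fill_holes(nuc_raw)
    nuclear = _largest_component(
        ndimage.binary_erosion(nuc_filled, struct, iterations=erode_iterations))
    pm_filled = ndimage.binary_fill_holes(pm_raw)
    pm_ring = _largest_component(
        ndimage.binary_erosion(pm_raw, struct, iterations=erode_iterations))
    interior = ndimage.binary_erosion(pm_filled, struct,
                                      iterations=erode_iterations)
    # subtract the un-eroded masks so the three ROIs stay disjoint
    cp = interior & ~pm_raw & ~nuc_filled & ~nuclear & ~pm_ring
    cp = _largest_component(cp)
    if not cp.any():
        raise SegmentationError("cytoplasm ROI is empty")
    if not nuclear.any() or not pm_ring.any():
        raise SegmentationError("nuclear or PM ROI is empty after erosion")
    return ROISet(pm_mask=pm_ring, nuclear_mask=nuclear, cp_mask=cp)


def pm_cp_ratio(target: np.ndarray, rois: ROISet,
                eps: float = 1e-9) -> PMCPResult:
    """Mean target intensity over the PM and CP ROIs and their ratio."""
    target = np.asarray(target, float)
    if target.ndim == 3:  # single-plane (1, y, x)
        target = target[0]
    if not rois.pm_mask.any() or not rois.cp_mask.any():
        raise SegmentationError("empty ROI")
    pm_mean = float(target[rois.pm_mask].mean())
    cp_mean = float(target[rois.cp_mask].mean())
    if cp_mean <= eps:
        raise SegmentationError(f"cp_mean={cp_mean} below floor; ratio undefined")
    return PMCPResult(pm_mean=pm_mean, cp_mean=cp_mean)


def ratio_to_fraction(r: float, ndigits: int | None = None) -> float:
    """Percent of signal PM-resident implied by a PM/CP ratio: 100*r/(1+r)."""
    if r <= 0:
        raise ConfigError("ratio must be positive")
    pct = 100.0 * r / (1.0 + r)
    return round(pct, ndigits) if ndigits is not None else pct


def quantify_stack(stack: ImageStack, n_planes: int = 4,
                   sigma: float = 3.0) -> tuple[PMCPResult, ROISet]:
    """Full pipeline: modal threshold -> central projection -> blur ->
    ROIs -> PM/CP ratio of the target channel."""
    proj = project_central(mode_threshold(stack), n_planes=n_planes)
    blurred = ImageStack(
        np.stack([blur(proj.data[0, c], sigma=sigma)
                  for c in range(proj.data.shape[1])])[None],
        dict(proj.roles))
    rois = make_rois(blurred)
    result = pm_cp_ratio(blurred.channel("target"), rois)
    return result, rois
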