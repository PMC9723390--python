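"""Pixel-wise fiber orientation from Sobel gradients.

The gradient field is the cross-correlation (not convolution) of the image
with the 3×3 Sobel kernels

    Gx = [[+1, 0, -1],          Gy = [[+1, +2, +1],
          [+2, 0, -2],                [ 0,  0,  0],
          [+1, 0, -1]]                [-1, -2, -1]]

with reflect (symmetric) border padding, so the output keeps the input
shape.  The local gradient direction φ = atan2(Gy, Gx), folded to the axial
range [0, 180), is perpendicular to the local fiber axis; the reported
fiber angle is (φ + 90°) mod 180, so a vertical (craniocaudal) structure
reads 90° and a horizontal one 0°.  Pixels whose gradient magnitude falls
below a validity threshold ε carry no orientation information and are
masked out rather than binned.

Orientations over an ROI are summarized as a 180-bin histogram on 1°
left-closed bins, normalized to percent of the analyzable pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyRoiError, ParameterError
from .image_io import ChannelImage, RegionLabelMap, TissueClass

__all__ = [
    "SOBEL_GX",
    "SOBEL_GY",
    "GradientField",
    "OrientationHistogram",
    "sobel_gradients",
    "fibre_angle_map",
    "orientation_histogram",
]

SOBEL_GX = np.array([[+1, 0, -1], [+2, 0, -2], [+1, 0, -1]], dtype=float)
SOBEL_GY = np.array([[+1, +2, +1], [0, 0, 0], [-1, -2, -1]], dtype=float)


@dataclass
class GradientField:
    """Signed Sobel responses and their magnitude, same shape as the input."""

    gx: np.ndarray
    gy: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.gx, self.gy)


@dataclass
class OrientationHistogram:
    """Percentage of analyzable ROI pixels per 1° orientation bin on [0,180).

    ``counts_pct`` sums to 100 whenever ``n_analyzable`` > 0.
    """

    bin_centers: np.ndarray  # 0.5, 1.5, ..., 179.5 degrees
    counts_pct: np.ndarray
    n_analyzable: int
    roi_classes: frozenset = frozenset()
    polarization: str = ""

    def mode_bin_center(self) -> float:
        """Centre of the most-populated bin."""
        return float(self.bin_centers[int(np.argmax(self.counts_pct))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center_deg": self.bin_centers, "counts_pct": self.counts_pct}
        )


def _correlate3(pixels: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Cross-correlation with a 3×3 kernel, symmetric (reflect) padding.

    Accumulates the nine kernel terms sequentially in row-major order, so
    the result is bit-identical to an explicit per-pixel double loop using
    the same order.
    """
    pad = np.pad(pixels, 1, mode="symmetric")
    h, w = pixels.shape
    out = np.zeros((h, w), dtype=float)
    for i in range(3):
        for j in range(3):
            out += kernel[i, j] * pad[i : i + h, j : j + w]
    return out


def sobel_gradients(image) -> GradientField:
    """Cross-correlate the image with the Sobel kernels (reflect padding).

    Accepts a :class:`ChannelImage` or a bare 2-D array of at least 3×3.
    """
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    if pixels.ndim != 2 or min(pixels.shape) < 3:
        raise ParameterError("image must be 2-D and at least 3x3")
    pixels = pixels.astype(float)
    # G_y = G_x^T, so gy is the transposed G_x correlation of the transposed
    # image; this traversal also cancels +k/-k pairs exactly, making both
    # responses identically zero on constant images.
    return GradientField(
        gx=_correlate3(pixels, SOBEL_GX),
        gy=_correlate3(pixels.T, SOBEL_GX).T,
    )


def fibre_angle_map(
    grad: GradientField, eps: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel fiber angle in [0, 180) plus a validity mask.

    Parameters
    ----------
    grad
        Sobel gradient field.
    eps
        Validity gate on the gradient magnitude; pixels below it are flagged
        invalid (their angle is reported as 0 but must not be used).
        Defaults to 1e-6 × max magnitude, i.e. effectively every pixel with
        any gradient counts.

    Notes
    -----
    The full-quadrant arctangent of (Gy, Gx) is used instead of the raw
    ratio arctan(Gy/Gx); after folding to [0, 180) the two agree wherever
    the ratio is defined, but atan2 has no division-by-zero pole.  The +90°
    shift converts the gradient direction into the fiber axis direction.
    """
    mag = grad.magnitude
    if eps is None:
        eps = 1e-6 * float(mag.max()) if mag.size else 0.0
    phi = np.degrees(np.arctan2(grad.gy, grad.gx))
    angles = np.mod(np.mod(phi, 180.0) + 90.0, 180.0)
    valid = mag >= eps if eps > 0 else mag > 0
    angles = np.where(valid, angles, 0.0)
    return angles, valid


def orientation_histogram(
    angles: np.ndarray,
    valid: np.ndarray,
    labels: RegionLabelMap | None = None,
    classes=None,
    polarization: str = "",
) -> OrientationHistogram:
    """Histogram valid ROI pixel angles into 1° bins, in percent.

    Bins are left-closed, right-open and partition [0, 180): no angle is
    dropped or double-counted.  ``labels``/``classes`` restrict the ROI; if
    omitted, all valid pixels are used.

    Raises
    ------
    EmptyRoiError
        If no valid pixel falls inside the ROI.
    """
    angles = np.asarray(angles, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if angles.shape != valid.shape:
        raise ParameterError("angles and validity mask shapes differ")
    sel = valid.copy()
    roi_classes = frozenset()
    if labels is not None and classes is not None:
        if labels.shape != angles.shape:
            raise ParameterError("label map shape differs from angle map")
        roi_classes = frozenset(TissueClass(c) for c in classes)
        sel &= labels.mask(roi_classes)
    picked = angles[sel]
    n = picked.size
    if n == 0:
        raise EmptyRoiError("no analyzable pixels in the selected ROI")
    edges = np.arange(181, dtype=float)
    counts, _ = np.histogram(np.mod(picked, 180.0), bins=edges)
    return OrientationHistogram(
        bin_centers=edges[:-1] + 0.5,
        counts_pct=100.0 * counts / n,
        n_analyzable=int(n),
        roi_classes=roi_classes,
        polarization=polarization,
    )
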