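"""ROI-restricted intensity statistics.

Collagen content is read out as the average *raw* SHG pixel intensity over a
tissue-class ROI (no rescaling, no background subtraction): SHG scales
linearly with the density of scatterers, so the ROI mean tracks mean
collagen density independent of compartment size.  Bone-vs-marrow
composition is the ratio of the mean SRS intensity in mineralized bone
(cortical ∪ trabecular) to the mean in marrow, with growth plate and
background excluded from both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateError, EmptyRoiError, ParameterError
from .image_io import BONE_CLASSES, ChannelImage, Channel, RegionLabelMap, TissueClass

__all__ = [
    "RoiIntensityResult",
    "CompartmentRatio",
    "roi_mean_intensity",
    "bone_marrow_ratio",
    "results_to_frame",
]


@dataclass
class RoiIntensityResult:
    """Mean/sd/SEM of raw intensities over one ROI class set."""

    sample_id: str
    channel_id: Channel
    roi_classes: frozenset
    n_pixels: int
    mean_intensity: float
    sd: float
    sem: float

    def as_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "channel": self.channel_id.value,
            "roi_classes": "+".join(sorted(c.name.lower() for c in self.roi_classes)),
            "n_pixels": self.n_pixels,
            "mean_intensity": self.mean_intensity,
            "sd": self.sd,
            "sem": self.sem,
        }


@dataclass
class CompartmentRatio:
    """Bone mean over marrow mean for one channel of one sample."""

    sample_id: str
    channel_id: Channel
    bone_mean: float
    marrow_mean: float
    ratio: float

    def as_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "channel": self.channel_id.value,
            "bone_mean": self.bone_mean,
            "marrow_mean": self.marrow_mean,
            "ratio": self.ratio,
        }


def roi_mean_intensity(
    image: ChannelImage, labels: RegionLabelMap, classes, sample_id: str = ""
) -> RoiIntensityResult:
    """Mean, sd and SEM of raw pixel intensity over the selected classes.

    The sd uses the n−1 (sample) denominator and SEM = sd/√n, matching the
    mean ± SEM reporting convention.  A single-pixel ROI reports sd = sem = 0.

    Raises
    ------
    EmptyRoiError
        If no pixel carries any of the selected labels.
    """
    if labels.shape != image.shape:
        raise ParameterError("label map and image shapes differ")
    classes = frozenset(TissueClass(c) for c in classes)
    if not classes:
        raise ParameterError("at least one ROI class required")
    mask = labels.mask(classes)
    n = int(mask.sum())
    if n == 0:
        raise EmptyRoiError(f"no pixels labelled {sorted(c.name for c in classes)}")
    vals = image.pixels[mask].astype(float)
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return RoiIntensityResult(
        sample_id=sample_id,
        channel_id=image.channel_id,
        roi_classes=classes,
        n_pixels=n,
        mean_intensity=float(vals.mean()),
        sd=sd,
        sem=sd / np.sqrt(n),
    )


def bone_marrow_ratio(
    image: ChannelImage, labels: RegionLabelMap, sample_id: str = ""
) -> CompartmentRatio:
    """Mean intensity in mineralized bone normalized over the marrow mean.

    Growth plate and background contribute to neither compartment.

    Raises
    ------
    EmptyRoiError
        If either compartment is absent from the label map.
    DegenerateError
        If the marrow mean is not strictly positive.
    """
    bone = roi_mean_intensity(image, labels, BONE_CLASSES, sample_id)
    marrow = roi_mean_intensity(image, labels, {TissueClass.MARROW}, sample_id)
    if marrow.mean_intensity <= 0:
        raise DegenerateError("marrow mean intensity is <= 0; ratio undefined")
    return CompartmentRatio(
        sample_id=sample_id,
        channel_id=image.channel_id,
        bone_mean=bone.mean_intensity,
        marrow_mean=marrow.mean_intensity,
        ratio=bone.mean_intensity / marrow.mean_intensity,
    )


def results_to_frame(results) -> pd.DataFrame:
    """Collect RoiIntensityResult/CompartmentRatio objects into a DataFrame."""
    return pd.DataFrame([r.as_row() for r in results])
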