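"""Reading and writing multichannel microscopy stacks, label maps and configs.

Storage dialect
---------------
A multimodal stack is one multipage grayscale TIFF.  Page order follows the
:class:`Channel` enum; each page's ImageDescription is a JSON object with the
channel name, and page 0 additionally carries the stack metadata (sample id,
genotype, polarization, pixel size).  Tissue label maps are single-page 8-bit
TIFFs using the fixed code table of :class:`TissueClass` (0=background,
1=cortical, 2=trabecular, 3=marrow, 4=growth_plate).

Coordinates are row-major, origin top-left, 0-based; the row index increases
caudally, so the vertical image axis is the craniocaudal anatomical axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum, IntEnum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import FormatError, ParameterError

__all__ = [
    "Channel",
    "TissueClass",
    "ChannelImage",
    "MultimodalStack",
    "RegionLabelMap",
    "BONE_CLASSES",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "export_composite",
    "load_config",
    "save_config",
]


class Channel(str, Enum):
    """Acquisition modality of one grayscale channel."""

    BF = "BF"
    TPEF = "TPEF"
    SHG_PAR = "SHG_PAR"
    SHG_PERP = "SHG_PERP"
    SRS_2850 = "SRS_2850"
    SRS_2920 = "SRS_2920"


#: canonical page order inside a stack TIFF
CHANNEL_ORDER = list(Channel)


class TissueClass(IntEnum):
    """Per-pixel tissue label code (fixed on-disk table)."""

    BACKGROUND = 0
    CORTICAL = 1
    TRABECULAR = 2
    MARROW = 3
    GROWTH_PLATE = 4


#: mineralized bone = cortical ∪ trabecular compartments
BONE_CLASSES = frozenset({TissueClass.CORTICAL, TissueClass.TRABECULAR})


@dataclass
class ChannelImage:
    """One 2-D nonnegative intensity grid with channel identity.

    Parameters
    ----------
    pixels
        2-D array of finite, nonnegative intensities.
    channel_id
        Which acquisition modality produced the image.
    pixel_size
        Edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    channel_id: Channel
    pixel_size: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError("ChannelImage requires a 2-D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("ChannelImage intensities must be finite")
        if np.any(self.pixels < 0):
            raise ParameterError("ChannelImage intensities must be >= 0")
        self.channel_id = Channel(self.channel_id)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MultimodalStack:
    """A set of co-registered channel images sharing one pixel grid."""

    channels: dict[Channel, ChannelImage]
    sample_id: str = ""
    genotype: str = ""
    polarization: str = ""

    def __post_init__(self):
        if not self.channels:
            raise ParameterError("stack needs at least one channel")
        shapes = {img.shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ParameterError(f"channel shapes differ: {shapes}")
        for cid, img in self.channels.items():
            if Channel(cid) != img.channel_id:
                raise ParameterError("channel key does not match image channel_id")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_size(self) -> float:
        return next(iter(self.channels.values())).pixel_size

    def __getitem__(self, channel: Channel) -> ChannelImage:
        return self.channels[Channel(channel)]


@dataclass
class RegionLabelMap:
    """Per-pixel tissue class map used to form ROIs and exclusions."""

    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ParameterError("label map must be 2-D")
        valid = {int(c) for c in TissueClass}
        present = set(np.unique(self.codes).tolist())
        if not present <= valid:
            raise FormatError(f"unknown label codes: {sorted(present - valid)}")
        self.codes = self.codes.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def mask(self, classes) -> np.ndarray:
        """Boolean mask of pixels whose label is in ``classes``."""
        classes = {TissueClass(c) for c in classes}
        return np.isin(self.codes, [int(c) for c in classes])


def write_stack(stack: MultimodalStack, path) -> None:
    """Write a stack as a multipage grayscale TIFF, one page per channel.

    Page order follows the channel enum; pixel values are stored verbatim
    (8/16-bit integer and 32/64-bit float round-trip bit-exactly).
    """
    path = Path(path)
    ordered = [c for c in CHANNEL_ORDER if c in stack.channels]
    with tifffile.TiffWriter(path) as tif:
        for i, cid in enumerate(ordered):
            desc = {"channel": cid.value}
            if i == 0:
                desc["meta"] = {
                    "sample_id": stack.sample_id,
                    "genotype": stack.genotype,
                    "polarization": stack.polarization,
                    "pixel_size": stack.pixel_size,
                }
            tif.write(
                stack.channels[cid].pixels,
                description=json.dumps(desc),
                metadata=None,
            )


def read_stack(path) -> MultimodalStack:
    """Read a multipage TIFF written by :func:`write_stack`.

    Raises
    ------
    FormatError
        If pages disagree in shape or a page carries an unknown channel tag.
    """
    path = Path(path)
    channels: dict[Channel, ChannelImage] = {}
    meta = {"sample_id": "", "genotype": "", "polarization": "", "pixel_size": 1.0}
    with tifffile.TiffFile(path) as tif:
        pages = list(tif.pages)
        if not pages:
            raise FormatError(f"{path}: empty TIFF")
        shape0 = pages[0].shape
        for i, page in enumerate(pages):
            if page.shape != shape0:
                raise FormatError(
                    f"{path}: page {i} shape {page.shape} != page 0 shape {shape0}"
                )
            try:
                desc = json.loads(page.description)
                cid = Channel(desc["channel"])
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                raise FormatError(f"{path}: page {i} has no valid channel tag") from exc
            if i == 0 and "meta" in desc:
                meta.update(desc["meta"])
            if cid in channels:
                raise FormatError(f"{path}: duplicate channel {cid.value}")
            channels[cid] = ChannelImage(
                page.asarray(), cid, pixel_size=float(meta["pixel_size"])
            )
    return MultimodalStack(
        channels,
        sample_id=str(meta["sample_id"]),
        genotype=str(meta["genotype"]),
        polarization=str(meta["polarization"]),
    )


def write_labels(labels: RegionLabelMap, path) -> None:
    """Write a label map as a single-page 8-bit TIFF."""
    tifffile.imwrite(Path(path), labels.codes.astype(np.uint8))


def read_labels(path) -> RegionLabelMap:
    """Read a single-page 8-bit label TIFF; unknown codes raise FormatError."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: label map must be single-page 2-D")
    return RegionLabelMap(arr)


def export_composite(stack: MultimodalStack, color_map: dict, path) -> np.ndarray:
    """Blend selected channels into an RGB image file.

    Each selected channel is min–max scaled to [0, 1], multiplied by its RGB
    color, and summed; the blend is clipped to the display range.  The stack
    itself is never modified (pure read).

    Parameters
    ----------
    color_map
        Mapping ``channel -> (r, g, b)`` with components in [0, 1].

    Returns
    -------
    The blended float RGB array (also written to ``path`` as 8-bit).
    """
    if not color_map:
        raise ParameterError("export_composite needs at least one channel")
    h, w = stack.shape
    rgb = np.zeros((h, w, 3), dtype=float)
    for cid, color in color_map.items():
        img = stack[Channel(cid)].pixels.astype(float)
        lo, hi = img.min(), img.max()
        scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        rgb += scaled[:, :, None] * np.asarray(color, dtype=float)[None, None, :]
    rgb = np.clip(rgb, 0.0, 1.0)
    iio.imwrite(Path(path), (rgb * 255).round().astype(np.uint8))
    return rgb


def save_config(config: dict, path) -> None:
    """Serialize a flat key/value configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return out
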