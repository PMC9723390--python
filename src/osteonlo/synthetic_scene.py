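"""Synthetic vertebra scenes with known ground truth.

Generates multichannel images that emulate a transverse/longitudinal section
of a murine vertebra: a cortical shell enclosing trabecular struts and
marrow, capped by growth-plate bands, surrounded by background.  The SHG
channels are rendered as collagen-like line-segment fibres whose axial
orientations follow a mixture of a wrapped Gaussian (the aligned component,
centred on the craniocaudal axis by default) and a uniform component
(randomly oriented fibres).  Fibre brightness follows the polarization
response of second-harmonic generation: the radiated power of a fibre at
angle θ under excitation polarized at angle p scales with cos⁴(θ − p), so
fibres parallel to the polarization are brightest and perpendicular fibres
are dark (up to a configurable floor).  The SRS and TPEF channels are
piecewise-constant per tissue class with a prescribed bone:marrow mean
ratio.  All channels receive additive Gaussian noise clipped at zero.

Angles are axial, in degrees on [0, 180), measured from the horizontal
image axis; 90° is the vertical (craniocaudal) axis.  ``sigma_true`` is
expressed in the same parameterization as the orientation-peak model fitted
downstream, f(θ) = B + A·exp(−((θ−θ0)/(2σ))²), whose shape is a Gaussian
with standard deviation σ√2; the wrapped normal sampled here therefore has
standard deviation √2·sigma_true so that a fit to the resulting histogram
recovers sigma_true itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .errors import ParameterError
from .image_io import (
    BONE_CLASSES,
    Channel,
    ChannelImage,
    MultimodalStack,
    RegionLabelMap,
    TissueClass,
)

__all__ = [
    "LabelGeometry",
    "SceneSpec",
    "SceneTruth",
    "make_region_labels",
    "render_shg_channel",
    "render_intensity_channel",
    "make_scene",
    "mixture_cdf",
]

#: mean marrow intensity all piecewise-constant channels are anchored to
MARROW_LEVEL = 100.0
GROWTH_PLATE_LEVEL = 80.0
BACKGROUND_LEVEL = 5.0


@dataclass
class LabelGeometry:
    """Geometry of the synthetic vertebra label map (all sizes in pixels)."""

    background_margin: int = 20
    growth_plate_rows: int = 30
    cortical_thickness: int = 48
    n_struts: int = 4
    strut_width: int = 28


@dataclass
class SceneSpec:
    """Full parameterization of a synthetic scene, retained as ground truth.

    Attributes
    ----------
    aligned_fraction
        Fraction of fibres drawn from the peaked (wrapped Gaussian)
        orientation component; the remainder are uniform on [0, 180).
    theta0_true, sigma_true
        Centre and width of the aligned component, in the peak-model
        parameterization (see module docstring).  Degrees.
    polarization_angle
        Excitation polarization; 0 = horizontal image axis, 90 =
        craniocaudal/vertical.
    polarization_floor
        Fraction in [0, 1] added to the cos⁴ response so fibres
        perpendicular to the polarization are not fully dark.
    srs_bone_marrow_ratio_lipid, srs_bone_marrow_ratio_protein
        Target (bone mean)/(marrow mean) for the SRS 2850 and 2920 cm⁻¹
        channels, before noise.
    noise_sd
        Standard deviation of the additive Gaussian noise, intensity units.
    """

    image_height: int = 512
    image_width: int = 512
    pixel_size: float = 1.0
    geometry: LabelGeometry = field(default_factory=LabelGeometry)
    n_fibres: int = 800
    fibre_length_range: tuple[float, float] = (20.0, 60.0)
    fibre_width: float = 1.5
    fibre_amplitude: float = 100.0
    aligned_fraction: float = 0.7
    theta0_true: float = 90.0
    sigma_true: float = 25.0
    polarization_angle: float = 90.0
    polarization_floor: float = 0.75
    srs_bone_marrow_ratio_lipid: float = 1.5
    srs_bone_marrow_ratio_protein: float = 1.3
    tpef_bone_marrow_ratio: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.geometry, dict):
            self.geometry = LabelGeometry(**self.geometry)
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ParameterError("aligned_fraction must lie in [0, 1]")
        if self.sigma_true <= 0:
            raise ParameterError("sigma_true must be > 0")
        if not 0.0 <= self.polarization_floor <= 1.0:
            raise ParameterError("polarization_floor must lie in [0, 1]")
        for name in (
            "srs_bone_marrow_ratio_lipid",
            "srs_bone_marrow_ratio_protein",
            "tpef_bone_marrow_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.fibre_length_range[0] > self.fibre_length_range[1] or (
            self.fibre_length_range[0] <= 0
        ):
            raise ParameterError("fibre_length_range must be 0 < lo <= hi")
        _validate_geometry(self)

    def to_config(self) -> dict:
        """Flat key/value representation (for YAML sidecar files)."""
        cfg = asdict(self)
        geo = cfg.pop("geometry")
        cfg.update({f"geometry_{k}": v for k, v in geo.items()})
        cfg["fibre_length_range"] = list(self.fibre_length_range)
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "SceneSpec":
        cfg = dict(cfg)
        geo = {
            k[len("geometry_"):]: cfg.pop(k)
            for k in list(cfg)
            if k.startswith("geometry_")
        }
        if "fibre_length_range" in cfg:
            cfg["fibre_length_range"] = tuple(cfg["fibre_length_range"])
        return cls(geometry=LabelGeometry(**geo) if geo else LabelGeometry(), **cfg)


@dataclass
class SceneTruth:
    """Ground truth retained alongside a rendered scene."""

    spec: SceneSpec
    fibre_orientations: np.ndarray  # degrees in [0, 180), one per fibre
    class_means: dict  # channel -> {TissueClass: realized mean intensity}


def _validate_geometry(spec: SceneSpec) -> None:
    g = spec.geometry
    for name in (
        "background_margin",
        "growth_plate_rows",
        "cortical_thickness",
        "strut_width",
    ):
        if getattr(g, name) < 0:
            raise ParameterError(f"geometry.{name} must be >= 0")
    if g.n_struts < 0:
        raise ParameterError("geometry.n_struts must be >= 0")
    interior_h = spec.image_height - 2 * (
        g.background_margin + g.growth_plate_rows + g.cortical_thickness
    )
    interior_w = spec.image_width - 2 * (g.background_margin + g.cortical_thickness)
    if interior_h <= 0 or interior_w <= 0:
        raise ParameterError("geometry does not fit inside the image")
    if g.n_struts > 0 and g.n_struts * g.strut_width > interior_w:
        raise ParameterError("trabecular struts do not fit in the interior")


def make_region_labels(spec: SceneSpec) -> RegionLabelMap:
    """Rasterize the vertebra geometry into a tissue label map.

    The layout (outside in): background margin, growth-plate bands at the
    cranial and caudal ends, a connected cortical frame, and an interior of
    marrow crossed by evenly spaced vertical trabecular struts.  Every pixel
    receives exactly one class.
    """
    _validate_geometry(spec)
    g = spec.geometry
    h, w = spec.image_height, spec.image_width
    codes = np.full((h, w), int(TissueClass.BACKGROUND), dtype=np.uint8)

    m = g.background_margin
    body = np.s_[m : h - m, m : w - m]
    codes[body] = int(TissueClass.GROWTH_PLATE)

    # central (non-growth-plate) part of the body holds the bone proper
    r0, r1 = m + g.growth_plate_rows, h - m - g.growth_plate_rows
    c0, c1 = m, w - m
    codes[r0:r1, c0:c1] = int(TissueClass.CORTICAL)

    t = g.cortical_thickness
    ir0, ir1 = r0 + t, r1 - t
    ic0, ic1 = c0 + t, c1 - t
    codes[ir0:ir1, ic0:ic1] = int(TissueClass.MARROW)

    if g.n_struts > 0:
        pitch = (ic1 - ic0) / g.n_struts
        for k in range(g.n_struts):
            centre = ic0 + (k + 0.5) * pitch
            s0 = int(round(centre - g.strut_width / 2))
            s1 = s0 + g.strut_width
            codes[ir0:ir1, max(s0, ic0) : min(s1, ic1)] = int(TissueClass.TRABECULAR)

    return RegionLabelMap(codes)


def _sample_orientations(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw fibre orientations from the aligned/uniform axial mixture."""
    n = spec.n_fibres
    aligned = rng.random(n) < spec.aligned_fraction
    theta = rng.uniform(0.0, 180.0, size=n)
    n_aligned = int(aligned.sum())
    if n_aligned:
        s = np.sqrt(2.0) * spec.sigma_true
        theta[aligned] = np.mod(
            spec.theta0_true + s * rng.standard_normal(n_aligned), 180.0
        )
    return theta


def polarization_response(theta: np.ndarray, polarization_angle: float,
                          floor: float) -> np.ndarray:
    """SHG brightness factor floor + (1-floor)·cos⁴(θ − p) of a fibre."""
    delta = np.deg2rad(np.asarray(theta, dtype=float) - polarization_angle)
    return floor + (1.0 - floor) * np.cos(delta) ** 4


def mixture_cdf(theta, spec: SceneSpec) -> np.ndarray:
    """CDF of the fibre-orientation mixture on [0, 180), for GOF testing.

    The wrapped-normal component folds a normal with standard deviation
    √2·sigma_true onto [0, 180) by summing over integer wraps.
    """
    theta = np.asarray(theta, dtype=float)
    s = np.sqrt(2.0) * spec.sigma_true
    wrapped = np.zeros_like(theta)
    for k in range(-8, 9):
        lo = (180.0 * k - spec.theta0_true) / s
        hi = (theta + 180.0 * k - spec.theta0_true) / s
        wrapped += norm.cdf(hi) - norm.cdf(lo)
    af = spec.aligned_fraction
    return af * wrapped + (1.0 - af) * theta / 180.0


def _draw_fibre(canvas: np.ndarray, r: float, c: float, theta: float,
                length: float, width: float, amplitude: float) -> None:
    """Accumulate one smooth anti-aliased line segment of the given angle.

    The direction vector is (Δrow, Δcol) = (sin θ, cos θ): with rows
    increasing downward this makes θ=90° a vertical segment, matching the
    craniocaudal convention of the analysis chain.

    The stroke has a constant-width Gaussian cross-section,
    amp·exp(−(d/width)²) with d the distance to the segment.  A smooth
    profile (rather than a hard rasterized line) keeps image gradients
    perpendicular to the fibre axis everywhere along its flanks, so the
    Sobel stage reads the fibre's true angle instead of snapping to the
    0°/45°/90°/135° directions a discrete line raster favours.
    """
    h, w = canvas.shape
    dr, dc = np.sin(np.deg2rad(theta)), np.cos(np.deg2rad(theta))
    half = length / 2.0
    pad = int(np.ceil(3 * width)) + 1
    r0 = int(max(0, np.floor(min(r - half * dr, r + half * dr) - pad)))
    r1 = int(min(h, np.ceil(max(r - half * dr, r + half * dr) + pad + 1)))
    c0 = int(max(0, np.floor(min(c - half * dc, c + half * dc) - pad)))
    c1 = int(min(w, np.ceil(max(c - half * dc, c + half * dc) + pad + 1)))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(
        np.arange(r0, r1, dtype=float),
        np.arange(c0, c1, dtype=float),
        indexing="ij",
    )
    pr, pc = rr - r, cc - c
    t = np.clip(pr * dr + pc * dc, -half, half)
    d2 = (pr - t * dr) ** 2 + (pc - t * dc) ** 2
    canvas[r0:r1, c0:c1] += amplitude * np.exp(-d2 / width**2)


def render_shg_channel(
    spec: SceneSpec,
    labels: RegionLabelMap,
    polarization_angle: float | None = None,
    channel: Channel = Channel.SHG_PAR,
) -> tuple[ChannelImage, SceneTruth]:
    """Render collagen-like fibres into an SHG channel.

    Fibres are line segments confined to the bone classes; each fibre's
    orientation is drawn from the spec's axial mixture and its amplitude is
    modulated by the cos⁴ polarization response.  Additive Gaussian noise is
    applied and the image is clipped at zero.  Identical specs (including
    seed) give bit-identical images; the polarization angle only rescales
    amplitudes, never changes the fibre draws.
    """
    if polarization_angle is None:
        polarization_angle = spec.polarization_angle
    rng = np.random.default_rng([spec.seed, 2])
    h, w = spec.image_height, spec.image_width
    if labels.shape != (h, w):
        raise ParameterError("label map shape does not match spec")

    theta = _sample_orientations(spec, rng)
    bone_mask = labels.mask(BONE_CLASSES)
    bone_rc = np.argwhere(bone_mask)
    canvas = np.zeros((h, w), dtype=float)
    if bone_rc.size and spec.n_fibres:
        idx = rng.integers(0, len(bone_rc), size=spec.n_fibres)
        lengths = rng.uniform(*spec.fibre_length_range, size=spec.n_fibres)
        amps = spec.fibre_amplitude * polarization_response(
            theta, polarization_angle, spec.polarization_floor
        )
        for i in range(spec.n_fibres):
            r, c = bone_rc[idx[i]]
            _draw_fibre(canvas, r, c, theta[i], lengths[i],
                        spec.fibre_width, amps[i])
    canvas[~bone_mask] = 0.0
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, None)

    image = ChannelImage(canvas, channel, pixel_size=spec.pixel_size)
    truth = SceneTruth(
        spec=spec,
        fibre_orientations=theta,
        class_means={channel: _class_means(canvas, labels)},
    )
    return image, truth


def _class_means(pixels: np.ndarray, labels: RegionLabelMap) -> dict:
    out = {}
    for cls in TissueClass:
        m = labels.codes == int(cls)
        if m.any():
            out[cls] = float(pixels[m].mean())
    return out


_CHANNEL_RATIO_FIELD = {
    Channel.SRS_2850: "srs_bone_marrow_ratio_lipid",
    Channel.SRS_2920: "srs_bone_marrow_ratio_protein",
    Channel.TPEF: "tpef_bone_marrow_ratio",
}


def render_intensity_channel(
    spec: SceneSpec, labels: RegionLabelMap, channel: Channel
) -> ChannelImage:
    """Render a piecewise-constant concentration channel (SRS or TPEF).

    Before noise, bone pixels (cortical and trabecular alike) sit at
    ratio×marrow level, so the bone:marrow mean-intensity ratio equals the
    spec's value for the channel exactly.  Growth plate and background get
    fixed intermediate/low levels.
    """
    channel = Channel(channel)
    if channel not in _CHANNEL_RATIO_FIELD:
        raise ParameterError(f"{channel.value} is not an intensity-ratio channel")
    ratio = getattr(spec, _CHANNEL_RATIO_FIELD[channel])
    if ratio <= 0:
        raise ParameterError("bone:marrow ratio must be > 0")
    levels = {
        TissueClass.BACKGROUND: BACKGROUND_LEVEL,
        TissueClass.GROWTH_PLATE: GROWTH_PLATE_LEVEL,
        TissueClass.MARROW: MARROW_LEVEL,
        TissueClass.CORTICAL: ratio * MARROW_LEVEL,
        TissueClass.TRABECULAR: ratio * MARROW_LEVEL,
    }
    lut = np.zeros(max(int(c) for c in TissueClass) + 1)
    for cls, lvl in levels.items():
        lut[int(cls)] = lvl
    pixels = lut[labels.codes]
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 10 + list(Channel).index(channel)])
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    return ChannelImage(np.clip(pixels, 0.0, None), channel,
                        pixel_size=spec.pixel_size)


def _render_brightfield(spec: SceneSpec, labels: RegionLabelMap) -> ChannelImage:
    """Transmission-like channel: dense (bone) regions attenuate the beam."""
    levels = {
        TissueClass.BACKGROUND: 200.0,
        TissueClass.GROWTH_PLATE: 120.0,
        TissueClass.MARROW: 150.0,
        TissueClass.CORTICAL: 80.0,
        TissueClass.TRABECULAR: 80.0,
    }
    lut = np.zeros(max(int(c) for c in TissueClass) + 1)
    for cls, lvl in levels.items():
        lut[int(cls)] = lvl
    pixels = lut[labels.codes]
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 20])
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    return ChannelImage(np.clip(pixels, 0.0, None), Channel.BF,
                        pixel_size=spec.pixel_size)


def make_scene(
    spec: SceneSpec, sample_id: str = "synthetic", genotype: str = ""
) -> tuple[MultimodalStack, RegionLabelMap, SceneTruth]:
    """Generate the full six-channel stack for one synthetic vertebra.

    The two SHG channels share identical fibre geometry (the same section
    imaged under two polarizations): SHG_PAR uses ``spec.polarization_angle``
    and SHG_PERP the orthogonal polarization.
    """
    labels = make_region_labels(spec)
    shg_par, truth = render_shg_channel(
        spec, labels, spec.polarization_angle, channel=Channel.SHG_PAR
    )
    shg_perp, _ = render_shg_channel(
        spec, labels, (spec.polarization_angle + 90.0) % 180.0,
        channel=Channel.SHG_PERP,
    )
    channels = {
        Channel.BF: _render_brightfield(spec, labels),
        Channel.TPEF: render_intensity_channel(spec, labels, Channel.TPEF),
        Channel.SHG_PAR: shg_par,
        Channel.SHG_PERP: shg_perp,
        Channel.SRS_2850: render_intensity_channel(spec, labels, Channel.SRS_2850),
        Channel.SRS_2920: render_intensity_channel(spec, labels, Channel.SRS_2920),
    }
    for ch, img in channels.items():
        truth.class_means[ch] = _class_means(img.pixels, labels)
    stack = MultimodalStack(channels, sample_id=sample_id, genotype=genotype)
    return stack, labels, truth
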