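"""Synthetic layered B-scan phantoms with multiplicative speckle.

The generator emulates the geometry of retinal/dental cross-sections: a dark
background above the tissue surface, a stack of bright horizontal layers
whose boundaries undulate smoothly across the scan, a mild axial intensity
gradient inside each layer (depth attenuation), fully-developed multiplicative
speckle (per-pixel gamma noise with mean 1 and variance 1/k, where k is the
number of looks), optional additive detector noise, and occasional
full-width horizontal stripe artifacts.

Everything is a pure function of (spec, model, seed): the same inputs yield
bit-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import ROI, ROIPair

__all__ = [
    "PhantomSpec", "SpeckleModel", "InvalidSpecError", "InfeasibleROIError",
    "generate_clean_phantom", "apply_noise", "speckle_field", "default_rois",
    "random_spec", "generate_pairs", "write_pair",
]


class InvalidSpecError(ValueError):
    """Phantom geometry or noise parameters are inconsistent."""


class InfeasibleROIError(ValueError):
    """No region is large enough to host the requested ROI box."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a clean layered phantom.

    ``layer_boundaries`` are the nominal top rows of each layer (strictly
    increasing); layer ``i`` spans from boundary ``i`` to boundary ``i+1``
    (the last layer extends to the bottom).  ``boundary_jitter`` is the
    amplitude in pixels of a smooth seeded sinusoidal undulation applied to
    every boundary.  ``layer_gradient`` is the fractional intensity drop from
    the top to the bottom of each layer, mimicking depth attenuation.
    ``texture_amplitude`` adds a smooth seeded low-frequency reflectivity
    modulation inside the tissue (real tissue is not optically uniform); it
    keeps clean-image ROI statistics non-degenerate, so the CNR/ENL of the
    clean references are finite and attainable.
    """
    height: int = 64
    width: int = 64
    layer_intensities: Sequence[float] = (0.8, 0.5)
    layer_boundaries: Sequence[int] = (22, 42)
    boundary_jitter: float = 2.0
    background_level: float = 0.02
    layer_gradient: float = 0.04
    texture_amplitude: float = 0.05
    seed: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.layer_boundaries)

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise InvalidSpecError("phantom must be at least 8x8")
        b = list(self.layer_boundaries)
        if len(b) < 1:
            raise InvalidSpecError("need at least one layer boundary")
        if len(self.layer_intensities) != len(b):
            raise InvalidSpecError(
                "one intensity per layer is required "
                f"({len(self.layer_intensities)} intensities, {len(b)} boundaries)")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise InvalidSpecError(f"boundaries must be strictly increasing: {b}")
        if b[0] < 0 or b[-1] >= self.height:
            raise InvalidSpecError(f"boundaries must lie in [0, {self.height}): {b}")
        if not all(0.0 < i <= 1.0 for i in self.layer_intensities):
            raise InvalidSpecError("layer intensities must lie in (0, 1]")
        if not 0.0 <= self.background_level <= 0.05:
            raise InvalidSpecError("background level must lie in [0, 0.05]")
        if self.boundary_jitter < 0:
            raise InvalidSpecError("boundary jitter must be >= 0")


@dataclass(frozen=True)
class SpeckleModel:
    """Noise applied to a clean phantom.

    ``looks_k`` parameterizes fully-developed speckle as i.i.d. per-pixel
    gamma multipliers with shape k and scale 1/k (mean 1, variance 1/k); a
    larger k means less speckle.  ``additive_sigma`` is the std of zero-mean
    gaussian read-out noise in gray levels.  ``n_stripe_artifacts`` bright or
    dark full-width single-row offsets of height ``stripe_amplitude`` are
    placed at seeded rows.
    """
    looks_k: float = 4.0
    additive_sigma: float = 0.02
    n_stripe_artifacts: int = 0
    stripe_amplitude: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.looks_k <= 0:
            raise InvalidSpecError("looks_k must be positive")
        if self.additive_sigma < 0:
            raise InvalidSpecError("additive_sigma must be >= 0")
        if self.n_stripe_artifacts < 0:
            raise InvalidSpecError("n_stripe_artifacts must be >= 0")


def _boundary_curves(spec: PhantomSpec) -> np.ndarray:
    """Per-column boundary rows, shape (n_layers, width), monotone in layer."""
    rng = np.random.default_rng(spec.seed)
    cols = np.arange(spec.width)
    curves = np.empty((spec.n_layers, spec.width))
    for i, b in enumerate(spec.layer_boundaries):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        cycles = rng.uniform(0.5, 1.5)
        curves[i] = b + spec.boundary_jitter * np.sin(
            2.0 * np.pi * cycles * cols / spec.width + phase)
    # jitter must never re-order boundaries; enforce a 1-px separation
    for i in range(1, spec.n_layers):
        curves[i] = np.maximum(curves[i], curves[i - 1] + 1.0)
    return np.clip(curves, 0.0, spec.height - 1.0)


def _texture_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth multiplicative reflectivity modulation in [1-a, 1+a]."""
    if spec.texture_amplitude == 0:
        return np.ones((spec.height, spec.width))
    rng = np.random.default_rng(spec.seed + 1)
    rr = np.arange(spec.height)[:, None] / spec.height
    cc = np.arange(spec.width)[None, :] / spec.width
    f = np.zeros((spec.height, spec.width))
    for _ in range(3):
        kr, kc = rng.uniform(3.0, 8.0, size=2)
        pr, pc = rng.uniform(0.0, 2.0 * np.pi, size=2)
        f += np.sin(2 * np.pi * kr * rr + pr) * np.sin(2 * np.pi * kc * cc + pc)
    f /= np.max(np.abs(f))
    return 1.0 + spec.texture_amplitude * f


def generate_clean_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the noiseless phantom defined by ``spec`` (float64 in [0,1])."""
    spec.validate()
    curves = _boundary_curves(spec)
    rows = np.arange(spec.height)[:, None]          # (H, 1)
    img = np.full((spec.height, spec.width), spec.background_level)
    bottoms = np.vstack([curves[1:], np.full((1, spec.width), float(spec.height))])
    texture = _texture_field(spec)
    for i in range(spec.n_layers):
        top, bot = curves[i], bottoms[i]            # (W,), (W,)
        inside = (rows >= np.ceil(top)) & (rows < bot)
        # fractional depth inside the layer drives the attenuation ramp
        depth = np.clip((rows - top) / np.maximum(bot - top, 1.0), 0.0, 1.0)
        shade = spec.layer_intensities[i] * (1.0 - spec.layer_gradient * depth) \
            * texture
        img = np.where(inside, shade, img)
    return np.clip(img, 0.0, 1.0)


def speckle_field(model: SpeckleModel, shape: tuple[int, int]) -> np.ndarray:
    """The raw multiplicative speckle field G: i.i.d. gamma(k, 1/k) samples
    with mean 1 and variance 1/k (no clipping, no additive noise).  Exposed
    so the noise statistics can be verified independently of the [0, 1]
    clipping that :func:`apply_noise` performs."""
    model.validate()
    rng = np.random.default_rng(model.seed)
    return rng.gamma(shape=model.looks_k, scale=1.0 / model.looks_k,
                     size=shape)


def apply_noise(clean: np.ndarray, model: SpeckleModel) -> np.ndarray:
    """Corrupt a clean image: ``clip(clean * G + eps + stripes, 0, 1)``.

    Stripe artifacts are bright full-width single-row offsets at seeded
    rows.  Note the clipping truncates the upper speckle tail, so the mean
    of a noisy mid-gray image sits slightly below the clean value.
    """
    model.validate()
    clean = np.asarray(clean, dtype=np.float64)
    if clean.min() < 0 or clean.max() > 1:
        raise ValueError("clean image must lie in [0, 1]")
    rng = np.random.default_rng(model.seed)
    g = rng.gamma(shape=model.looks_k, scale=1.0 / model.looks_k,
                  size=clean.shape)
    noisy = clean * g
    if model.additive_sigma > 0:
        noisy = noisy + rng.normal(0.0, model.additive_sigma, size=clean.shape)
    if model.n_stripe_artifacts > 0:
        rows = rng.choice(clean.shape[0], size=model.n_stripe_artifacts,
                          replace=False)
        noisy[rows, :] += model.stripe_amplitude
    return np.clip(noisy, 0.0, 1.0)


def default_rois(spec: PhantomSpec, box_size: int = 12) -> ROIPair:
    """Place a background box above the first boundary and a signal box
    inside the brightest layer, clear of any undulating boundary."""
    spec.validate()
    margin = int(np.ceil(spec.boundary_jitter)) + 1
    b = list(spec.layer_boundaries)
    bg_bottom = b[0] - margin
    if bg_bottom < box_size:
        raise InfeasibleROIError(
            f"background region ({bg_bottom} safe rows) cannot host a "
            f"{box_size}-px box")
    brightest = int(np.argmax(spec.layer_intensities))
    top = b[brightest] + margin
    bottom = (b[brightest + 1] if brightest + 1 < len(b) else spec.height) - margin
    if bottom - top < box_size:
        raise InfeasibleROIError(
            f"brightest layer ({bottom - top} safe rows) cannot host a "
            f"{box_size}-px box")
    col = (spec.width - box_size) // 2
    bg_row = (bg_bottom - box_size) // 2
    sig_row = top + (bottom - top - box_size) // 2
    return ROIPair(signal=ROI(int(sig_row), col, box_size, box_size),
                   background=ROI(int(bg_row), col, box_size, box_size))


# -- study-condition dataset ----------------------------------------------


def random_spec(rng: np.random.Generator, height: int = 64,
                width: int = 64) -> PhantomSpec:
    """Draw a random two-layer geometry (at 64 px: surface at rows 18-24, a
    19-22 px bright upper layer, dimmer tissue below); proportions scale
    with the image height, and always admit height/5-px ROI boxes."""
    s = height / 64.0
    b0 = int(rng.integers(round(18 * s), round(25 * s)))
    b1 = b0 + int(rng.integers(round(19 * s), round(23 * s)))
    return PhantomSpec(
        height=height, width=width,
        layer_intensities=(float(rng.uniform(0.55, 0.9)),
                           float(rng.uniform(0.35, 0.55))),
        layer_boundaries=(b0, b1),
        boundary_jitter=float(rng.uniform(1.0, 2.0) * s),
        background_level=float(rng.uniform(0.0, 0.04)),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def generate_pairs(n: int, seed: int, height: int = 64, width: int = 64,
                   looks_k: float = 4.0, additive_sigma: float = 0.02,
                   stripe_prob: float = 0.3, box_size: int | None = None):
    """Generate ``n`` noisy/clean phantom pairs with default ROIs.

    Returns a list of ``dataio.NoisyCleanPair``.  Each phantom gets its own
    random geometry; a stripe artifact is present with probability
    ``stripe_prob``.  ``box_size`` defaults to height // 5 (12 px at the
    standard 64-px height), which the random geometry always admits.
    """
    if box_size is None:
        box_size = max(height // 5, 4)
    from .dataio import ImageRecord, NoisyCleanPair

    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        spec = random_spec(rng, height=height, width=width)
        model = SpeckleModel(
            looks_k=looks_k, additive_sigma=additive_sigma,
            n_stripe_artifacts=int(rng.random() < stripe_prob),
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        clean = generate_clean_phantom(spec)
        noisy = apply_noise(clean, model)
        rois = default_rois(spec, box_size=box_size)
        pairs.append(NoisyCleanPair(
            noisy=ImageRecord(id=f"phantom{i:04d}_noisy", pixels=noisy),
            clean=ImageRecord(id=f"phantom{i:04d}_clean", pixels=clean),
            rois=rois))
    return pairs


def write_pair(pair, out_dir: str | Path) -> None:
    """Write ``<stem>_clean.png`` / ``<stem>_noisy.png`` (16-bit grayscale)
    plus ``<stem>_roi.json`` next to them."""
    from .dataio import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = pair.clean.id.rsplit("_", 1)[0]
    write_image(pair.clean.pixels, out / f"{stem}_clean.png")
    write_image(pair.noisy.pixels, out / f"{stem}_noisy.png")
    if pair.rois is not None:
        (out / f"{stem}_roi.json").write_text(
            json.dumps(pair.rois.to_dict(), indent=2))
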