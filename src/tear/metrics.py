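"""ROI-based OCT image-quality metrics and classification-report ratios.

Conventions
-----------
Images are 2-D float arrays in [0, 1]; the PSNR/SSIM dynamic range ``L`` is
therefore 1.0.  All logarithms in the dB metrics are base 10.  Region
statistics use the population form (divisor ``n``).  ROIs are 0-based,
half-open ``{row, col, height, width}`` boxes; by convention the *signal* box
sits inside bright tissue and the *background* box inside the dark region
above it.

The equivalent number of looks follows the reported form ``mu_b^2 /
sigma_s^2`` (background mean over signal variance); the textbook
single-region form ``mu^2 / sigma^2`` over the background box is available
via ``enl_convention="homogeneous"``.

Degenerate inputs (perfect reconstruction, perfectly flat ROIs) return
``math.inf`` sentinels rather than raising, so evaluating a batch never
aborts on one flat image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROI", "ROIPair", "MetricReport", "ConfusionCounts",
    "roi_stats", "psnr", "ssim", "cnr", "enl",
    "classification_metrics", "metric_report",
    "DegenerateContrastError",
]


class DegenerateContrastError(ValueError):
    """Raised when CNR is undefined (signal mean <= background mean, or
    both ROI standard deviations are zero)."""


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open."""
    row: int
    col: int
    height: int
    width: int

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI must have positive height and width")
        if self.height * self.width < 4:
            raise ValueError("ROI area must be at least 4 pixels")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI origin must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.height),
                slice(self.col, self.col + self.width))

    def check_inside(self, shape: tuple[int, ...]) -> None:
        h, w = shape[-2], shape[-1]
        if self.row + self.height > h or self.col + self.width > w:
            raise IndexError(
                f"ROI {self} does not fit inside image of shape {(h, w)}")

    def overlaps(self, other: "ROI") -> bool:
        return not (self.row + self.height <= other.row
                    or other.row + other.height <= self.row
                    or self.col + self.width <= other.col
                    or other.col + other.width <= self.col)

    def to_dict(self) -> dict:
        return {"row": self.row, "col": self.col,
                "height": self.height, "width": self.width}

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        return cls(int(d["row"]), int(d["col"]),
                   int(d["height"]), int(d["width"]))


@dataclass(frozen=True)
class ROIPair:
    """A signal box and a background box driving CNR/ENL and the loss."""
    signal: ROI
    background: ROI

    def __post_init__(self):
        if self.signal.overlaps(self.background):
            raise ValueError("signal and background ROIs must not overlap")

    def to_dict(self) -> dict:
        return {"signal": self.signal.to_dict(),
                "background": self.background.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "ROIPair":
        return cls(ROI.from_dict(d["signal"]), ROI.from_dict(d["background"]))


@dataclass
class MetricReport:
    """One row of the standard SSIM / PSNR / CNR / ENL evaluation table."""
    psnr: float
    ssim: float
    cnr: float
    enl: float

    @property
    def degenerate(self) -> bool:
        return not all(math.isfinite(v)
                       for v in (self.psnr, self.ssim, self.cnr, self.enl))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts must not all be zero")


def _as_image(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    return a


def roi_stats(image, rois: ROIPair) -> tuple[float, float, float, float]:
    """Population mean and standard deviation over the signal and background
    boxes: returns ``(mu_s, sigma_s, mu_b, sigma_b)``."""
    img = _as_image(image)
    rois.signal.check_inside(img.shape)
    rois.background.check_inside(img.shape)
    sig = img[rois.signal.slices()]
    bg = img[rois.background.slices()]
    return (float(sig.mean()), float(sig.std()),
            float(bg.mean()), float(bg.std()))


def psnr(pred, ref, dynamic_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(L^2 / MSE)`` in dB.

    Identical images have MSE 0 and return ``inf``.
    """
    p, r = _as_image(pred), _as_image(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    mse = float(np.mean((p - r) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(dynamic_range ** 2 / mse)


def ssim(pred, ref, dynamic_range: float = 1.0) -> float:
    """Global-statistics structural similarity (single window covering the
    whole image), with the usual stabilizers c1=(0.01 L)^2, c2=(0.03 L)^2.

    The global form returns one scalar per image from the five raw moments;
    it is what both the evaluation reports and the training loss use.
    """
    p, r = _as_image(pred), _as_image(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    mu_p, mu_r = p.mean(), r.mean()
    var_p, var_r = p.var(), r.var()
    cov = ((p - mu_p) * (r - mu_r)).mean()
    num = (2 * mu_p * mu_r + c1) * (2 * cov + c2)
    den = (mu_p ** 2 + mu_r ** 2 + c1) * (var_p + var_r + c2)
    return float(num / den)


def windowed_ssim(pred, ref, dynamic_range: float = 1.0) -> float:
    """Mean local SSIM (7x7 uniform windows) via scikit-image, offered as an
    alternative convention; reports and the loss use the global form."""
    from skimage.metrics import structural_similarity

    return float(structural_similarity(
        _as_image(pred), _as_image(ref), data_range=dynamic_range))


def cnr(image, rois: ROIPair) -> float:
    """Contrast-to-noise ratio ``10 log10((mu_s - mu_b)/sqrt(sig_b^2 + sig_s^2))``."""
    mu_s, sig_s, mu_b, sig_b = roi_stats(image, rois)
    if mu_s <= mu_b:
        raise DegenerateContrastError(
            f"signal mean ({mu_s:.4g}) must exceed background mean "
            f"({mu_b:.4g}) for CNR")
    pooled = math.sqrt(sig_s ** 2 + sig_b ** 2)
    if pooled == 0.0:
        raise DegenerateContrastError(
            "both ROI standard deviations are zero; CNR undefined")
    return 10.0 * math.log10((mu_s - mu_b) / pooled)


def enl(image, rois: ROIPair, convention: str = "paper") -> float:
    """Equivalent number of looks.

    ``convention="paper"`` (default): ``mu_b^2 / sigma_s^2`` — background
    mean squared over signal variance, the reported form.
    ``convention="homogeneous"``: ``mu_b^2 / sigma_b^2`` over the background
    box alone, the textbook speckle form.  A perfectly flat divisor region
    returns the ``inf`` sentinel.
    """
    mu_s, sig_s, mu_b, sig_b = roi_stats(image, rois)
    if convention == "paper":
        num, den = mu_b ** 2, sig_s ** 2
    elif convention == "homogeneous":
        num, den = mu_b ** 2, sig_b ** 2
    else:
        raise ValueError(f"unknown ENL convention: {convention!r}")
    if den == 0.0:
        return math.inf
    return float(num / den)


def metric_report(pred, ref, rois: ROIPair,
                  enl_convention: str = "paper") -> MetricReport:
    """Evaluate the four quality metrics of one image against a reference.

    CNR/ENL are measured on ``pred`` (they are no-reference metrics); a
    degenerate CNR is reported as ``-inf`` rather than raising.
    """
    try:
        cnr_val = cnr(pred, rois)
    except DegenerateContrastError:
        cnr_val = -math.inf
    return MetricReport(psnr=psnr(pred, ref), ssim=ssim(pred, ref),
                        cnr=cnr_val,
                        enl=enl(pred, rois, convention=enl_convention))


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, specificity, sensitivity, precision and F1 from a binary
    confusion matrix.  A metric whose denominator is zero is ``nan``."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    accuracy = ratio(c.tn + c.tp, c.tn + c.fp + c.tp + c.fn)
    specificity = ratio(c.tn, c.tn + c.fp)
    sensitivity = ratio(c.tp, c.tp + c.fn)
    precision = ratio(c.tp, c.fp + c.tp)
    if math.isnan(precision) or math.isnan(sensitivity) \
            or precision + sensitivity == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {"accuracy": accuracy, "specificity": specificity,
            "sensitivity": sensitivity, "precision": precision, "f1": f1}
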