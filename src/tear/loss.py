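"""Composite quality-aware training loss and its single-term alternatives.

The composite loss is the sum of four terms, each non-negative and zero for
a perfect reconstruction:

* ``l_mse``  — mean squared pixel error;
* ``l_diff`` — structural dissimilarity, ``1 - SSIM(pred, clean)`` with the
  same global-statistics SSIM the metrics module reports;
* ``l_cnr``  — the normalized contrast gap ``clip(|CNR(clean) - CNR(pred)| /
  gap_scale, 0, 1)`` measured on the pair's ROI boxes;
* ``l_psnr`` — the normalized fidelity gap to a PSNR ceiling,
  ``clip((ceiling - PSNR(pred, clean)) / gap_scale, 0, 1)``.

As printed, the contrast and fidelity terms of the source formulation read
``1 - gap/100``, which evaluates to 1 (their maximum is at equality); here
they are implemented as the clipped absolute gap, which is 0 at equality and
matches their description as normalized coefficients in (0, 1).  The printed
form remains available through ``literal_paper_form`` for auditability.

PSNR of a perfect reconstruction is infinite; a configurable 50 dB ceiling
caps the reference so the term stays bounded and differentiable.

Ablation variants: plain MSE, MAE, and binary cross-entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .metrics import DegenerateContrastError, ROIPair
from .metrics import cnr as _cnr_np

__all__ = ["LossComponents", "LossConfig", "composite_loss", "variant_loss",
           "composite_terms", "variant_term", "training_loss"]

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


@dataclass
class LossComponents:
    """The four normalized loss terms and their sum."""
    l_mse: float
    l_diff: float
    l_cnr: float
    l_psnr: float
    total: float


@dataclass(frozen=True)
class LossConfig:
    variant: str = "composite"            # composite | mse | mae | bce
    gap_scale: float = 100.0              # normalizing denominator of the
    #                                       CNR/PSNR gap terms
    psnr_ceiling: float = 50.0            # dB cap standing in for the
    #                                       infinite PSNR of a perfect output
    literal_paper_form: bool = False      # audit switch: 1 - gap/scale

    def __post_init__(self):
        if self.gap_scale <= 0:
            raise ValueError("gap_scale must be positive")
        if self.variant not in ("composite", "mse", "mae", "bce"):
            raise ValueError(f"unknown loss variant {self.variant!r}")


def _ssim_t(pred: Tensor, clean: np.ndarray, dynamic_range: float = 1.0) -> Tensor:
    """Differentiable global-statistics SSIM of a predicted image against a
    fixed clean reference (same form as :func:`tear.metrics.ssim`)."""
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    mu_p = pred.mean()
    mu_c = float(clean.mean())
    var_c = float(clean.var())
    dp = pred - mu_p
    var_p = (dp * dp).mean()
    cov = (dp * (clean - mu_c)).mean()
    num = (2.0 * mu_p * mu_c + c1) * (2.0 * cov + c2)
    den = (mu_p * mu_p + mu_c ** 2 + c1) * (var_p + var_c + c2)
    return num / den


def _roi_moments_t(pred: Tensor, rois: ROIPair) -> tuple[Tensor, ...]:
    stats = []
    for roi in (rois.signal, rois.background):
        box = pred[roi.slices()]
        mu = box.mean()
        d = box - mu
        var = (d * d).mean()
        stats.extend([mu, var])
    return tuple(stats)      # mu_s, var_s, mu_b, var_b


def _cnr_t(pred: Tensor, rois: ROIPair) -> Tensor:
    """Differentiable CNR in dB.  Contrast and pooled std are floored at
    1e-3 (below one 8-bit gray level) so the logarithm stays defined — and
    its gradient bounded — on arbitrary network output; below the floor the
    gradient is released entirely."""
    mu_s, var_s, mu_b, var_b = _roi_moments_t(pred, rois)
    contrast = (mu_s - mu_b).maximum(1e-3)
    pooled = (var_s + var_b + 1e-12).sqrt().maximum(1e-3)
    return (contrast / pooled).log() * (10.0 / _LN10)


def composite_terms(pred: Tensor, clean: np.ndarray, rois: ROIPair | None,
                    cfg: LossConfig) -> dict[str, Tensor]:
    """The four terms as autodiff scalars (the training path).

    ``pred`` must have the same shape as ``clean``.  A missing or degenerate
    ROI disables the contrast term (it becomes the constant 0) with a logged
    warning rather than aborting training.
    """
    if pred.shape != clean.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {clean.shape}")
    diff = pred - clean
    l_mse = (diff * diff).mean()
    l_diff = 1.0 - _ssim_t(pred, clean)

    cnr_clean: float | None = None
    if rois is not None:
        try:
            cnr_clean = _cnr_np(clean, rois)
        except DegenerateContrastError as exc:
            logger.warning("degenerate clean-image ROI, contrast term "
                           "disabled: %s", exc)
    if cnr_clean is None:
        l_cnr = Tensor(0.0)
    else:
        gap = cnr_clean - _cnr_t(pred, rois)
        if cfg.literal_paper_form:
            l_cnr = 1.0 - gap / cfg.gap_scale
        else:
            l_cnr = (gap.abs() * (1.0 / cfg.gap_scale)).clip(0.0, 1.0)

    mse_floor = 10.0 ** (-cfg.psnr_ceiling / 10.0)
    psnr_pred = (1.0 / l_mse.maximum(mse_floor)).log() * (10.0 / _LN10)
    if cfg.literal_paper_form:
        l_psnr = 1.0 - (cfg.psnr_ceiling - psnr_pred) / cfg.gap_scale
    else:
        l_psnr = (((cfg.psnr_ceiling - psnr_pred).abs())
                  * (1.0 / cfg.gap_scale)).clip(0.0, 1.0)

    total = l_mse + l_diff + l_cnr + l_psnr
    return {"l_mse": l_mse, "l_diff": l_diff, "l_cnr": l_cnr,
            "l_psnr": l_psnr, "total": total}


def composite_loss(pred, clean, rois: ROIPair | None,
                   cfg: LossConfig | None = None) -> LossComponents:
    """Evaluate the composite loss on plain arrays (no gradients)."""
    cfg = cfg or LossConfig()
    pred_arr = np.asarray(getattr(pred, "pixels", pred), dtype=np.float64)
    clean_arr = np.asarray(getattr(clean, "pixels", clean), dtype=np.float64)
    terms = composite_terms(Tensor(pred_arr), clean_arr, rois, cfg)
    return LossComponents(**{k: float(v.data) for k, v in terms.items()})


def variant_term(pred: Tensor, clean: np.ndarray, cfg: LossConfig) -> Tensor:
    """One of the single-term ablation losses as an autodiff scalar."""
    if pred.shape != clean.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {clean.shape}")
    if cfg.variant == "mse":
        d = pred - clean
        return (d * d).mean()
    if cfg.variant == "mae":
        return (pred - clean).abs().mean()
    if cfg.variant == "bce":
        if clean.min() < 0 or clean.max() > 1:
            raise ValueError("bce requires targets in [0, 1]")
        p = pred.clip(1e-7, 1.0 - 1e-7)
        return -(clean * p.log() + (1.0 - clean) * (1.0 - p).log()).mean()
    raise ValueError(f"{cfg.variant!r} is not a single-term variant")


def variant_loss(pred, clean, cfg: LossConfig) -> float:
    pred_arr = np.asarray(getattr(pred, "pixels", pred), dtype=np.float64)
    clean_arr = np.asarray(getattr(clean, "pixels", clean), dtype=np.float64)
    return float(variant_term(Tensor(pred_arr), clean_arr, cfg).data)


def training_loss(pred: Tensor, clean: np.ndarray, rois: ROIPair | None,
                  cfg: LossConfig) -> tuple[Tensor, LossComponents]:
    """The scalar the optimizer minimizes, plus the per-term breakdown."""
    if cfg.variant == "composite":
        terms = composite_terms(pred, clean, rois, cfg)
        comps = LossComponents(**{k: float(v.data) for k, v in terms.items()})
        return terms["total"], comps
    t = variant_term(pred, clean, cfg)
    val = float(t.data)
    return t, LossComponents(l_mse=math.nan, l_diff=math.nan, l_cnr=math.nan,
                             l_psnr=math.nan, total=val)
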