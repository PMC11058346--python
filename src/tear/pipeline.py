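"""Training, ablation and evaluation orchestration.

The trainer minimizes the configured loss with Adam/AdamW over seeded
minibatches, tracks per-epoch loss components, keeps the best-on-validation
parameters, and reports ROI-based quality metrics (SSIM/PSNR/CNR/ENL) on
held-out pairs for both the raw noisy images and the denoised outputs.
Everything is single-threaded and a pure function of (config, data, seed).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Adam, AdamW, stack
from .dataio import DatasetSplit, NoisyCleanPair
from .loss import LossComponents, LossConfig, training_loss
from .metrics import metric_report
from .model import TEAR, TEARConfig, ModelState, smoke_config

__all__ = ["RunConfig", "RunReport", "train", "evaluate", "ablate",
           "smoke_run_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    tear: TEARConfig = field(default_factory=TEARConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    use_attention_gate: bool = True
    epochs: int = 200
    batch_size: int = 4
    learning_rate: float = 5e-4
    optimizer: str = "adam"            # adam | adamw
    grad_clip: float = 1.0             # global L2 gradient-norm ceiling
    warmup_steps: int = 60             # linear learning-rate ramp-in
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("adam", "adamw"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def smoke_run_config(seed: int = 0, variant: str = "composite",
                     use_attention_gate: bool = True,
                     epochs: int = 16) -> RunConfig:
    """The scaled-down end-to-end configuration used by tests and the
    acceptance script: 64x64 phantoms, 8-px patches, 32-dim tokens, depth 2,
    batch 4, lr 5e-4."""
    return RunConfig(tear=smoke_config(seed=seed),
                     loss=LossConfig(variant=variant),
                     use_attention_gate=use_attention_gate,
                     epochs=epochs, batch_size=4, learning_rate=5e-4,
                     seed=seed)


@dataclass
class RunReport:
    config: RunConfig
    epoch_losses: list[LossComponents]
    val_losses: list[float]
    best_epoch: int
    test_metrics: pd.DataFrame | None
    wall_time_s: float


def _mean_components(comps: list[LossComponents]) -> LossComponents:
    arr = np.array([[c.l_mse, c.l_diff, c.l_cnr, c.l_psnr, c.total]
                    for c in comps])
    m = arr.mean(axis=0)
    return LossComponents(*m)


def _batch_loss(model: TEAR, batch: list[NoisyCleanPair],
                loss_cfg: LossConfig):
    pred = model.forward_batch([p.noisy.pixels for p in batch])
    totals, comps = [], []
    for i, pair in enumerate(batch):
        t, c = training_loss(pred[i], pair.clean.pixels, pair.rois, loss_cfg)
        totals.append(t)
        comps.append(c)
    mean_total = stack(totals).mean()
    return mean_total, comps


def _val_loss(model: TEAR, pairs: list[NoisyCleanPair],
              loss_cfg: LossConfig, batch_size: int) -> float:
    vals = []
    for start in range(0, len(pairs), batch_size):
        batch = pairs[start:start + batch_size]
        total, _ = _batch_loss(model, batch, loss_cfg)
        vals.append(float(total.data) * len(batch))
    return sum(vals) / len(pairs)


def train(cfg: RunConfig, data: DatasetSplit) -> tuple[ModelState, RunReport]:
    """Seeded minibatch training; returns the best-on-validation model."""
    if not data.train or not data.val:
        raise ValueError("train and validation splits must be non-empty")
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    tear_cfg = replace(cfg.tear, use_attention_gate=cfg.use_attention_gate,
                       seed=int(rng.integers(2 ** 31)))
    model = TEAR(tear_cfg)
    params = model.params
    opt_cls = Adam if cfg.optimizer == "adam" else AdamW
    opt = opt_cls(params.values(), lr=cfg.learning_rate)

    epoch_losses: list[LossComponents] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_epoch = -1
    best_params: dict[str, np.ndarray] = {}
    log_rows = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data.train))
        comps_epoch: list[LossComponents] = []
        for start in range(0, len(order), cfg.batch_size):
            step += 1
            if cfg.warmup_steps:
                opt.lr = cfg.learning_rate * min(1.0, step / cfg.warmup_steps)
            batch = [data.train[i] for i in order[start:start + cfg.batch_size]]
            total, comps = _batch_loss(model, batch, cfg.loss)
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"loss diverged at epoch {epoch}, batch {start // cfg.batch_size}")
            opt.zero_grad()
            total.backward()
            if cfg.grad_clip:
                opt.clip_grad_norm(cfg.grad_clip)
            opt.step()
            comps_epoch.extend(comps)
        mean_comp = _mean_components(comps_epoch) \
            if cfg.loss.variant == "composite" else LossComponents(
                np.nan, np.nan, np.nan, np.nan,
                float(np.mean([c.total for c in comps_epoch])))
        epoch_losses.append(mean_comp)
        vloss = _val_loss(model, data.val, cfg.loss, cfg.batch_size)
        val_losses.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_epoch = epoch
            best_params = {k: p.data.copy() for k, p in params.items()}
        log_rows.append({"epoch": epoch, "l_mse": mean_comp.l_mse,
                         "l_diff": mean_comp.l_diff, "l_cnr": mean_comp.l_cnr,
                         "l_psnr": mean_comp.l_psnr, "total": mean_comp.total,
                         "val": vloss, "variant": cfg.loss.variant})
        logger.info("epoch %d/%d train %.5f val %.5f", epoch + 1, cfg.epochs,
                    mean_comp.total, vloss)
    for k, p in params.items():
        p.data = best_params[k]
    state = ModelState(model=model, train_history=log_rows)

    test_df = evaluate(state, data.test) if data.test else None
    report = RunReport(config=cfg, epoch_losses=epoch_losses,
                       val_losses=val_losses, best_epoch=best_epoch,
                       test_metrics=test_df,
                       wall_time_s=time.perf_counter() - t0)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(log_rows).to_csv(out / "loss_log.csv", index=False)
        if test_df is not None:
            test_df.to_csv(out / "test_metrics.csv", index=True)
    return state, report


def evaluate(state: ModelState, pairs: list[NoisyCleanPair]) -> pd.DataFrame:
    """Per-image and mean SSIM/PSNR/CNR/ENL for noisy and denoised images.

    Pairs without ROIs are skipped with a warning; the returned frame has one
    row per evaluated image plus a ``mean`` row.
    """
    rows = []
    skipped = 0
    for pair in pairs:
        if pair.rois is None:
            skipped += 1
            continue
        den = state.model.forward(pair.noisy.pixels)
        rep_n = metric_report(pair.noisy.pixels, pair.clean.pixels, pair.rois)
        rep_d = metric_report(den, pair.clean.pixels, pair.rois)
        rows.append({
            "id": pair.clean.id,
            "ssim_noisy": rep_n.ssim, "psnr_noisy": rep_n.psnr,
            "cnr_noisy": rep_n.cnr, "enl_noisy": rep_n.enl,
            "ssim_denoised": rep_d.ssim, "psnr_denoised": rep_d.psnr,
            "cnr_denoised": rep_d.cnr, "enl_denoised": rep_d.enl,
        })
    if skipped:
        logger.warning("evaluate: skipped %d pairs without ROIs", skipped)
    df = pd.DataFrame(rows).set_index("id")
    df.loc["mean"] = df.mean(axis=0)
    df.attrs["skipped"] = skipped
    return df


def ablate(base_cfg: RunConfig, data: DatasetSplit,
           loss_variants: tuple[str, ...] = ("composite", "mse", "mae", "bce"),
           gate_settings: tuple[bool, ...] = (True,)) -> pd.DataFrame:
    """One training run per (loss variant, gate) combination on the same
    seed and data; returns a table of mean test metrics shaped like the
    standard SSIM/PSNR/CNR/ENL comparison."""
    rows = []
    for use_gate in gate_settings:
        for variant in loss_variants:
            cfg = replace(base_cfg, loss=replace(base_cfg.loss,
                                                 variant=variant),
                          use_attention_gate=use_gate)
            _, report = train(cfg, data)
            mean = report.test_metrics.loc["mean"]
            rows.append({
                "variant": variant, "attention_gate": use_gate,
                "ssim": mean["ssim_denoised"], "psnr": mean["psnr_denoised"],
                "cnr": mean["cnr_denoised"], "enl": mean["enl_denoised"],
                "wall_time_s": report.wall_time_s,
            })
            logger.info("ablate %s gate=%s: psnr %.2f ssim %.3f",
                        variant, use_gate, rows[-1]["psnr"], rows[-1]["ssim"])
    return pd.DataFrame(rows)
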