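"""Shared fixtures.

The expensive end-to-end study (10 seeds x 4 loss variants of the smoke
training configuration) is computed once per session and shared by the
denoising-improvement and ablation-ordering tests.
"""

import numpy as np
import pytest

from tear.dataio import extract_patches, split_dataset
from tear.phantom import generate_pairs
from tear.pipeline import smoke_run_config, train

SEEDS = tuple(range(10))
VARIANTS = ("composite", "mse", "mae", "bce")


def gate_separation(state, pairs):
    """Mean attention-gate weight over patches inside the signal ROI minus
    the mean over patches inside the background ROI, averaged over pairs."""
    patch = state.config.patch
    diffs = []
    for pair in pairs:
        gated = state.model.embed_image(pair.noisy.pixels)
        rows, cols = gated.grid_shape
        weights = np.asarray(gated.gate_weights).reshape(rows, cols)

        def mean_weight(roi):
            rr = slice(roi.row // patch, -(-(roi.row + roi.height) // patch))
            cc = slice(roi.col // patch, -(-(roi.col + roi.width) // patch))
            return weights[rr, cc].mean()

        diffs.append(mean_weight(pair.rois.signal)
                     - mean_weight(pair.rois.background))
    return float(np.mean(diffs))


@pytest.fixture(scope="session")
def smoke_study():
    """Train the smoke configuration for every (seed, loss variant) pair on
    its own 200-phantom dataset; returns mean test metrics per run plus the
    per-seed signal/background gate separation of the composite runs."""
    metrics = {}
    gate_sep = {}
    for seed in SEEDS:
        pairs = generate_pairs(200, seed=1000 + seed)
        split = split_dataset(pairs, seed=1000 + seed)
        for variant in VARIANTS:
            cfg = smoke_run_config(seed=seed, variant=variant)
            state, report = train(cfg, split)
            metrics[(seed, variant)] = report.test_metrics.loc["mean"]
            if variant == "composite":
                gate_sep[seed] = gate_separation(state, split.test[:5])
    return {"metrics": metrics, "gate_separation": gate_sep}
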