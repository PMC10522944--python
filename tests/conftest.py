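"""Shared fixtures.

The two expensive fixtures train the segmentation network once per
session: a noiseless-rendering experiment (phase intensities exactly
separable) and a default-noise experiment, both training on two phantom
volumes and evaluating on held-out volumes never seen during training.
"""

from __future__ import annotations

import numpy as np
import pytest

import mgscaffold as mg
from mgscaffold.segmentation import TrainingPatchSet, subsample_patches

TRAIN_SEEDS = (1, 2)
NOISELESS_TEST_SEED = 3
NOISY_TEST_SEEDS = (10, 11, 12)
PATCH_SIZE = 32
PATCHES_PER_VOLUME = 125
EPOCHS = 30


def make_phantom(seed: int, **overrides) -> tuple[mg.GreyVolume, mg.LabelVolume]:
    spec = mg.PhantomSpec.scaled_down(seed=seed, **overrides)
    truth = mg.apply_degradation(mg.build_scaffold_geometry(spec), spec)
    return mg.render_grey(truth, spec), truth


def _train(render_overrides: dict) -> mg.SegmentationModel:
    rng = np.random.default_rng(0)
    pairs = []
    for s in TRAIN_SEEDS:
        grey, truth = make_phantom(s, **render_overrides)
        ps = mg.extract_patches(grey, truth, PATCH_SIZE)
        pairs.extend(subsample_patches(ps, PATCHES_PER_VOLUME, rng).pairs)
    patch_set = TrainingPatchSet(pairs, PATCH_SIZE, 0)
    return mg.train_unet(patch_set, mg.UNetSpec(epochs=EPOCHS, seed=0))


@pytest.fixture(scope="session")
def small_spec() -> mg.PhantomSpec:
    return mg.PhantomSpec.scaled_down(seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    truth = mg.apply_degradation(mg.build_scaffold_geometry(small_spec), small_spec)
    grey = mg.render_grey(truth, small_spec)
    return grey, truth


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Train on separable phantoms, evaluate Dice on a held-out one."""
    overrides = dict(noise_sd=0.0, psf_sigma_um=0.0)
    model = _train(overrides)
    grey, truth = make_phantom(NOISELESS_TEST_SEED, **overrides)
    pred = mg.predict_volume(model, grey)
    return {
        "model": model,
        "dice": mg.evaluate_segmentation(pred, truth),
        "pred": pred,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def noisy_experiment():
    """Default-noise training; three held-out evaluation volumes."""
    model = _train({})
    per_volume = []
    for s in NOISY_TEST_SEEDS:
        grey, truth = make_phantom(s)
        pred = mg.predict_volume(model, grey)
        truth_rep = mg.phase_volumes(truth)
        pred_rep = mg.phase_volumes(pred)
        per_volume.append(
            {
                "seed": s,
                "dice": mg.evaluate_segmentation(pred, truth),
                "true_degraded_mm3": truth_rep.volume_degraded_mm3,
                "pred_degraded_mm3": pred_rep.volume_degraded_mm3,
            }
        )
    return {"model": model, "volumes": per_volume}
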