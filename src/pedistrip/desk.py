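"""Desk-scale end-to-end study: train on phantom heads, score held-out ones.

This is the package's small-footprint reference experiment: 8 phantom label
maps on a 48³ grid (1 mm voxels), a 3-level U-Net (base width 8), soft Dice
loss, Adam with batch size 1, at most 600 steps with plateau stopping.
Validation and held-out images are rendered as acquired-like scans (fixed
per-label contrasts plus noise) — unlike the randomized training images — so
the score measures generalization to stable-contrast data, the same role the
validation MRIs play at full scale.
"""

from __future__ import annotations

import time
from typing import Dict, List, Tuple

import numpy as np

from .core import BrainMask, IntensityVolume, LabelMap
from .evaluation import dice_metric
from .losses_training import TrainConfig, TrainResult, train
from .network import UNetConfig, predict_mask
from .phantoms import PhantomSpec, make_phantom_image, make_phantom_labelmap
from .synthesis import SynthConfig
from .targets import derive_brain_mask

DESK_GRID = 48
N_TRAIN_MAPS = 8
# three phantoms at two contrasts each: six validation images, close to the
# seven real validation scans of the full-scale setup
N_VAL_PHANTOMS = 3
N_HELDOUT_PHANTOMS = 2
NOISE_SD = 4.0


def desk_unet_config() -> UNetConfig:
    # 1x1x1 post-upsampling convs: the two 3^3 convs per level stay, and the
    # decoder's full-resolution cost drops substantially
    return UNetConfig(
        n_levels=3, base_channels=8, output_mode="softmax_2ch", up_kernel=1
    )


def desk_train_config(seed: int, max_steps: int = 600) -> TrainConfig:
    return TrainConfig(
        learning_rate=1e-3,
        max_steps=max_steps,
        validation_interval=20,
        # a 600-step budget is entirely pre-plateau; stopping is left to the
        # step cap (the plateau mechanism matters for full-scale runs)
        plateau_patience=30,
        plateau_min_delta=1e-4,
        loss_mode="dice",
        lr_schedule="cosine",
        warmup_steps=50,
        tail_average_from=0.6,
        max_restarts=2,
        restart_patience=4,
        grad_clip=1.0,
        seed=seed,
    )


def _phantom(seed: int) -> LabelMap:
    return make_phantom_labelmap(PhantomSpec(grid_size=DESK_GRID, seed=seed))


def desk_training_maps(seed: int) -> List[LabelMap]:
    return [_phantom(seed * 1000 + i) for i in range(N_TRAIN_MAPS)]


def _image_mask_pairs(seed0: int, n: int) -> List[Tuple[IntensityVolume, BrainMask]]:
    pairs = []
    for k in range(n):
        lm = _phantom(seed0 + k)
        ref = derive_brain_mask(lm)
        for contrast in ("t1_like", "t2_like"):
            img = make_phantom_image(lm, contrast, noise_sd=NOISE_SD, seed=seed0 + k)
            pairs.append((img, ref))
    return pairs


def desk_validation_pairs(seed: int) -> List[Tuple[IntensityVolume, BrainMask]]:
    return _image_mask_pairs(seed * 1000 + 500, N_VAL_PHANTOMS)


def desk_heldout_pairs(seed: int) -> List[Tuple[IntensityVolume, BrainMask]]:
    return _image_mask_pairs(seed * 1000 + 800, N_HELDOUT_PHANTOMS)


def run_desk_training(seed: int, max_steps: int = 600) -> Dict:
    """Train one desk-scale model and return its metrics.

    Returns a dict with the trained result plus: best/initial validation
    loss, fractional validation-loss reduction, held-out Dice per case and
    mean, and steps run.
    """
    t0 = time.time()
    maps = desk_training_maps(seed)
    val = desk_validation_pairs(seed)
    synth = SynthConfig.desk_scale(float(DESK_GRID), seed=seed)
    tc = desk_train_config(seed, max_steps=max_steps)
    result: TrainResult = train(maps, val, synth, tc, unet_config=desk_unet_config())

    heldout = desk_heldout_pairs(seed)
    dice = [dice_metric(predict_mask(result.unet, img), ref) for img, ref in heldout]
    return {
        "result": result,
        "initial_val": result.initial_val,
        "best_val": result.best_val,
        "val_reduction": result.val_reduction,
        "heldout_dice": dice,
        "heldout_dice_mean": float(np.mean(dice)),
        "steps_run": result.steps_run,
        "runtime_s": time.time() - t0,
    }
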