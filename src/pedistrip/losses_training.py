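"""Segmentation losses and the synthesis-driven training loop.

Two loss families drive the optimization:

* a soft Dice loss over the two softmax channels (brain, background): per
  channel ``D_c = 2 Σ y_c p_c / (Σ y_c² + Σ p_c²)``, loss ``−(D_j + D_k)/2``,
  range [−1, 0], minimized at −1 for a perfect prediction;
* a (optionally band-weighted) mean-squared error on a predicted signed
  distance transform: voxels within ``h`` mm of the brain boundary get
  weight 1, voxels farther away weight ``b`` — focusing the gradients on the
  boundary where segmentation accuracy is decided. ``usdt`` mode is the
  unweighted variant (w = 1 everywhere).

Training draws one label map per step, synthesizes an (image, label map)
pair, derives the target on the fly, and takes one Adam step (batch size 1).
Validation on held-out real-style image/mask pairs runs every
``validation_interval`` steps; optimization stops when the validation loss
stops improving (plateau) or at ``max_steps``. Validation always scores
1 − Dice of the thresholded prediction, whatever the training loss, so runs
with different losses are comparable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .core import BrainMask, IntensityVolume, LabelMap
from .evaluation import dice_metric
from .network import UNet, UNetConfig, build_unet, predict_mask, softmax_channels
from .synthesis import SynthConfig, generate_training_pair
from .targets import compute_sdt, derive_brain_mask

LOSS_MODES = ("dice", "usdt", "wsdt")
_EPS = 1e-6


class TrainingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# losses


def _check_two_channel(target: np.ndarray, pred: np.ndarray) -> None:
    if target.shape != pred.shape:
        raise ValueError(f"shape mismatch: target {target.shape} vs pred {pred.shape}")
    if target.ndim != 4 or target.shape[-1] != 2:
        raise ValueError(f"expected (D, H, W, 2) arrays, got {target.shape}")


def one_hot_mask(mask: np.ndarray) -> np.ndarray:
    """Binary mask -> two channels (brain, background), channels last."""
    m = np.asarray(mask, dtype=np.float32)
    return np.stack([m, 1.0 - m], axis=-1)


def dice_loss(target: np.ndarray, pred: np.ndarray) -> float:
    """Soft Dice loss, averaged over the brain and background channels."""
    _check_two_channel(target, pred)
    t = target.reshape(-1, 2).astype(np.float64)
    p = pred.reshape(-1, 2).astype(np.float64)
    num = 2.0 * (t * p).sum(axis=0) + _EPS
    den = (t**2).sum(axis=0) + (p**2).sum(axis=0) + _EPS
    return float(-(num / den).mean())


def dice_loss_grad(target: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """d(dice_loss)/d(pred), same shape as pred."""
    _check_two_channel(target, pred)
    t = target.astype(np.float64)
    p = pred.astype(np.float64)
    num = 2.0 * (t * p).sum(axis=(0, 1, 2)) + _EPS  # (2,)
    den = (t**2).sum(axis=(0, 1, 2)) + (p**2).sum(axis=(0, 1, 2)) + _EPS
    # D_c = num/den; dD/dp = (2 t den - num * 2 p) / den^2; loss = -mean_c D_c
    grad = -(0.5) * (2.0 * t * den - num * 2.0 * p) / den**2
    return grad.astype(np.float32)


def sdt_weights(target_sdt: np.ndarray, b: float, h: float, mode: str = "wsdt") -> np.ndarray:
    if mode == "usdt":
        return np.ones_like(target_sdt, dtype=np.float64)
    w = np.where(np.abs(target_sdt) <= h, 1.0, float(b))
    return w.astype(np.float64)


def sdt_loss(
    target_sdt: np.ndarray,
    pred_sdt: np.ndarray,
    b: float = 1e-3,
    h: float = 4.0,
    mode: str = "wsdt",
) -> float:
    """Band-weighted MSE between predicted and target signed distances."""
    if target_sdt.shape != pred_sdt.shape:
        raise ValueError(
            f"shape mismatch: target {target_sdt.shape} vs pred {pred_sdt.shape}"
        )
    if not 0.0 <= b <= 1.0 or h < 0:
        raise ValueError("need b in [0, 1] and h >= 0")
    w = sdt_weights(np.asarray(target_sdt, dtype=np.float64), b, h, mode)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("degenerate weight band: b = 0 and no voxel within h of the boundary")
    diff = np.asarray(pred_sdt, dtype=np.float64) - np.asarray(target_sdt, dtype=np.float64)
    return float((w * diff**2).sum() / wsum)


def sdt_loss_grad(
    target_sdt: np.ndarray,
    pred_sdt: np.ndarray,
    b: float = 1e-3,
    h: float = 4.0,
    mode: str = "wsdt",
) -> np.ndarray:
    w = sdt_weights(np.asarray(target_sdt, dtype=np.float64), b, h, mode)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("degenerate weight band: b = 0 and no voxel within h of the boundary")
    diff = np.asarray(pred_sdt, dtype=np.float64) - np.asarray(target_sdt, dtype=np.float64)
    return (2.0 * w * diff / wsum).astype(np.float32)


def softmax_grad_to_logits(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Chain a gradient w.r.t. softmax outputs back to the logits."""
    inner = (dprobs * probs).sum(axis=-1, keepdims=True)
    return (probs * (dprobs - inner)).astype(np.float32)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32, copy=False)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 1
    max_steps: int = 1000
    validation_interval: int = 25
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-4
    loss_mode: str = "dice"
    b: float = 1e-3  # far-from-boundary down-weight factor (wsdt)
    h: float = 4.0  # boundary band half-width, mm (wsdt)
    closing_iterations: int = 10  # target-mask closing iterations
    grad_clip: float = 1.0  # global gradient-norm clip; 0 disables
    plateau_lr_decay: float = 1.0  # lr multiplier per non-improving validation; 1 disables
    lr_schedule: str = "constant"  # or "cosine": decay to 10% of lr over max_steps
    warmup_steps: int = 0  # linear lr ramp-up before the schedule proper
    corruption_rampup_steps: int = 0  # scale corruption probs 0 -> configured
    tail_average_from: float = 0.0  # >0: average weights over steps beyond this
    # fraction of max_steps; the averaged model competes with the best
    # checkpoint on validation score
    max_restarts: int = 0  # reinitialize on early stagnation (failed basin)
    restart_patience: int = 6  # stagnant validations before a restart
    restart_val_floor: float = 0.25  # only restart while the best loss is above this
    seed: int = 0

    def __post_init__(self):
        if self.batch_size != 1:
            raise ValueError("training uses a batch size of 1")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must lie in [0, 1]")
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if not 0.0 < self.plateau_lr_decay <= 1.0:
            raise ValueError("plateau_lr_decay must lie in (0, 1]")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        if not 0.0 <= self.tail_average_from < 1.0:
            raise ValueError("tail_average_from must lie in [0, 1)")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "TrainConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text) as fh:
                    d = yaml.safe_load(fh)
            else:
                d = yaml.safe_load(text)
        return cls(**d)


@dataclass
class TrainResult:
    """Best-validation parameters plus the full optimization trace."""

    unet: UNet
    history: List[dict] = field(default_factory=list)  # step, loss, val_loss, seed
    best_val: float = np.inf
    initial_val: float = np.inf
    best_step: int = 0
    steps_run: int = 0

    @property
    def val_reduction(self) -> float:
        """Fractional validation-loss reduction from step 0 to the best checkpoint."""
        if self.initial_val <= 0:
            return 0.0
        return 1.0 - self.best_val / self.initial_val

    def log_lines(self) -> str:
        import json

        return "\n".join(json.dumps(rec) for rec in self.history)


def _step_loss_and_grad(unet: UNet, image: IntensityVolume, target_mask: BrainMask,
                        tc: TrainConfig):
    """One forward/backward pass; returns (loss, dlogits, sdt_target_or_None)."""
    from .network import _normalize  # same normalization as inference

    logits = unet.forward(_normalize(np.asarray(image.data, dtype=np.float32)))
    if tc.loss_mode == "dice":
        target = one_hot_mask(target_mask.data)
        probs = softmax_channels(logits)
        loss = dice_loss(target, probs)
        dlogits = softmax_grad_to_logits(probs, dice_loss_grad(target, probs))
    else:
        sdt = compute_sdt(target_mask).data
        pred = logits[..., 0]
        loss = sdt_loss(sdt, pred, b=tc.b, h=tc.h, mode=tc.loss_mode)
        dlogits = sdt_loss_grad(sdt, pred, b=tc.b, h=tc.h, mode=tc.loss_mode)[..., None]
    return loss, dlogits


def validation_loss(unet: UNet, val_pairs: Sequence[Tuple[IntensityVolume, BrainMask]]) -> float:
    """Mean (1 − Dice) of thresholded predictions over the validation pairs."""
    scores = [
        1.0 - dice_metric(predict_mask(unet, img), ref) for img, ref in val_pairs
    ]
    return float(np.mean(scores))


def train(
    labelmaps: Sequence[LabelMap],
    val_pairs: Sequence[Tuple[IntensityVolume, BrainMask]],
    synth: SynthConfig,
    tc: TrainConfig,
    unet_config: Optional[UNetConfig] = None,
    unet: Optional[UNet] = None,
) -> TrainResult:
    """Synthesis-driven training with plateau stopping.

    Per step: draw one label map uniformly, generate a synthetic training
    pair, derive the target mask (and SDT if needed) from the augmented
    labels, take one Adam step. Returns the parameters of the best
    validation checkpoint.
    """
    if not labelmaps:
        raise ValueError("need at least one training label map")
    if not val_pairs:
        raise ValueError("need at least one validation pair")
    if unet is None:
        if unet_config is None:
            mode = "softmax_2ch" if tc.loss_mode == "dice" else "sdt_1ch"
            unet_config = UNetConfig(n_levels=3, base_channels=8, output_mode=mode)
        unet = build_unet(unet_config, seed=tc.seed)
    if tc.loss_mode == "dice" and unet.config.output_mode != "softmax_2ch":
        raise ValueError("dice loss requires a softmax_2ch network")
    if tc.loss_mode in ("usdt", "wsdt") and unet.config.output_mode != "sdt_1ch":
        raise ValueError("SDT losses require an sdt_1ch network")

    rng = np.random.default_rng(np.random.SeedSequence([int(tc.seed), 424242]))
    adam = Adam(unet.params, lr=tc.learning_rate)

    result = TrainResult(unet=unet)
    val0 = validation_loss(unet, val_pairs)
    result.initial_val = val0
    result.best_val = val0
    best_params = {k: v.copy() for k, v in unet.params.items()}
    result.history.append(
        {"step": 0, "loss": None, "val_loss": val0, "seed": int(tc.seed)}
    )
    bad_validations = 0
    tail_start = (
        int(tc.tail_average_from * tc.max_steps) if tc.tail_average_from > 0 else None
    )
    avg_params, avg_n = None, 0
    # restart bookkeeping: a "segment" is the current initialization's run
    restarts_done = 0
    segment_start = 0
    segment_best = val0
    segment_bad = 0

    lr0 = tc.learning_rate
    for step in range(1, tc.max_steps + 1):
        s_eff = step - segment_start  # schedule restarts with the segment
        seg_len = tc.max_steps - segment_start
        if tc.warmup_steps > 0 and s_eff <= tc.warmup_steps:
            adam.lr = lr0 * s_eff / tc.warmup_steps
        elif tc.lr_schedule == "cosine":
            frac = (s_eff - tc.warmup_steps) / max(seg_len - tc.warmup_steps, 1)
            adam.lr = 0.1 * lr0 + 0.45 * lr0 * (1.0 + np.cos(np.pi * frac))
        i = int(rng.integers(len(labelmaps)))
        step_seed = int(rng.integers(2**31))
        synth_step = synth
        if tc.corruption_rampup_steps > 0 and step < tc.corruption_rampup_steps:
            # curriculum: learn geometry on clean renders first, then robustify
            f = step / tc.corruption_rampup_steps
            synth_step = dataclasses.replace(
                synth,
                bias_prob=synth.bias_prob * f,
                gamma_prob=synth.gamma_prob * f,
                crop_prob=synth.crop_prob * f,
                downsample_prob=synth.downsample_prob * f,
                blur_prob=synth.blur_prob * f,
            )
        image, warped = generate_training_pair(labelmaps[i], synth_step, step_seed)
        target_mask = derive_brain_mask(warped, iterations=tc.closing_iterations)
        loss, dlogits = _step_loss_and_grad(unet, image, target_mask, tc)
        if not np.isfinite(loss):
            raise TrainingError(
                f"non-finite loss at step {step} (step_seed={step_seed}, "
                f"config seed={tc.seed}); rerun with these seeds to replay"
            )
        grads = unet.backward(dlogits)
        if tc.grad_clip > 0:
            gnorm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values()))
            if gnorm > tc.grad_clip:
                scale = np.float32(tc.grad_clip / gnorm)
                grads = {k: g * scale for k, g in grads.items()}
        adam.step(unet.params, grads)
        result.steps_run = step
        if tail_start is not None and s_eff > tc.tail_average_from * seg_len:
            if avg_params is None:
                avg_params = {k: v.astype(np.float64) for k, v in unet.params.items()}
            else:
                for k, v in unet.params.items():
                    avg_params[k] += v
            avg_n += 1

        record = {"step": step, "loss": float(loss), "val_loss": None, "seed": step_seed}
        if step % tc.validation_interval == 0 or step == tc.max_steps:
            val = validation_loss(unet, val_pairs)
            record["val_loss"] = val
            if val < result.best_val - tc.plateau_min_delta:
                result.best_val = val
                result.best_step = step
                best_params = {k: v.copy() for k, v in unet.params.items()}
                bad_validations = 0
            else:
                bad_validations += 1
                adam.lr *= tc.plateau_lr_decay
            if val < segment_best - tc.plateau_min_delta:
                segment_best = val
                segment_bad = 0
            else:
                segment_bad += 1
            if (
                restarts_done < tc.max_restarts
                and segment_bad >= tc.restart_patience
                and segment_best > tc.restart_val_floor
            ):
                # failed basin: reinitialize and restart the schedule
                restarts_done += 1
                fresh = build_unet(unet.config, seed=int(tc.seed) + 7777 * restarts_done)
                unet.params = fresh.params
                adam = Adam(unet.params, lr=tc.learning_rate)
                segment_start = step
                segment_best = np.inf
                segment_bad = 0
                bad_validations = 0
                avg_params, avg_n = None, 0  # averaging restarts with the segment
                record["restart"] = restarts_done
            elif bad_validations >= tc.plateau_patience:
                result.history.append(record)
                break
        result.history.append(record)

    unet.params = best_params
    if avg_params is not None and avg_n > 0:
        # tail-averaged weights compete with the best checkpoint on validation
        averaged = {k: (v / avg_n).astype(np.float32) for k, v in avg_params.items()}
        unet.params = averaged
        avg_val = validation_loss(unet, val_pairs)
        result.history.append(
            {"step": result.steps_run, "loss": None, "val_loss": avg_val,
             "seed": int(tc.seed), "tail_average": True}
        )
        if avg_val <= result.best_val:
            result.best_val = avg_val
        else:
            unet.params = best_params
    return result
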