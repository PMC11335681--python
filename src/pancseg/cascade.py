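"""Two-stage cascade: pancreas segmentation -> crop -> tumor segmentation.

Stage 1 segments the pancreas on the full slice with the multi-scale
U-Net.  Its probability map P is binarized (threshold 0.5), the minimal
box containing all foreground pixels is expanded by a K-pixel margin and
clamped, and the crop feeds stage 2.  The salient-change coupling
multiplies the cropped image by ``eps + (1 - eps) * P`` so stage-1
confidence re-weights intensities and gradients from stage-2 losses reach
stage-1 parameters.  Stage 2 runs its own multi-scale U-Net as a feature
extractor, reduces the five decoder levels with 1x1 convolutions, applies
the non-local localization module at the coarsest level and four focusing
modules towards full crop resolution, emitting five predictions
(coarse -> fine, all upsampled to the crop size for supervision).

Training follows the three-step schedule:
  S — saliency coupling off, ground-truth pancreas boxes, the two stages
      optimized by their own losses (no stage-2 gradient reaches stage 1);
  I — coupling on (gradients flow end to end), still ground-truth boxes;
  J — boxes from the stage-1 prediction, identical to test-time behavior.
Optimizer state persists across steps (SGD, momentum 0.9).
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from autograd import value_and_grad

from . import attention, backbone, focusing, losses
from .backbone import BackboneConfig
from .nn import ops
from .nn.flat import flatten_tree, unflatten_tree
from .nn.layers import conv, init_conv
from .nn.optim import SGD
from .phantom import SliceSample

logger = logging.getLogger(__name__)


@dataclass
class CropRegion:
    row_min: int
    row_max: int
    col_min: int
    col_max: int
    margin_K: int = 0

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError(f"degenerate crop region: {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)


@dataclass
class StagePrediction:
    stage1_prob: np.ndarray            # full image, H x W
    stage2_probs: list[np.ndarray]     # 5 maps over the crop (coarse->fine), at crop size
    region: CropRegion
    final_mask: np.ndarray             # binary, full image coordinates


@dataclass
class TrainSchedule:
    epochs_S: int = 2
    epochs_I: int = 4
    epochs_J: int = 50

    def steps(self):
        return [("S", self.epochs_S), ("I", self.epochs_I), ("J", self.epochs_J)]


@dataclass
class CascadeConfig:
    image_size: int = 64
    stage2_size: int = 96
    base_channels: int = 32
    reduce_channels: int = 32
    margin_K: int = 20          # at 512-pixel scale; scaled to image_size
    crop_threshold: float = 0.5
    saliency_eps: float = 0.5
    use_localization: bool = True
    use_focusing: bool = True
    norm: str = "batch"
    lr: float = 1e-5
    momentum: float = 0.9
    weight_decay: float = 1e-7
    weights: losses.LossWeights = field(default_factory=losses.LossWeights)
    schedule: TrainSchedule = field(default_factory=TrainSchedule)
    seed: int = 0

    @property
    def margin_pixels(self) -> int:
        return max(1, round(self.margin_K * self.image_size / 512))

    def backbone_config(self) -> BackboneConfig:
        return BackboneConfig(in_channels=1, base_channels=self.base_channels, norm=self.norm)


# ------------------------------------------------------------- crop logic

def binarize_and_box(p: np.ndarray, threshold: float, margin: int) -> CropRegion:
    """Minimal box containing all pixels of P >= threshold, expanded by the
    margin and clamped.  An all-background map falls back to the full
    image so inference never fails on a missed pancreas."""
    p = np.asarray(p)
    z = p >= threshold
    h, w = z.shape
    if not z.any():
        return CropRegion(0, h, 0, w, margin_K=margin)
    rows = np.flatnonzero(z.any(axis=1))
    cols = np.flatnonzero(z.any(axis=0))
    return CropRegion(
        row_min=max(0, rows[0] - margin),
        row_max=min(h, rows[-1] + 1 + margin),
        col_min=max(0, cols[0] - margin),
        col_max=min(w, cols[-1] + 1 + margin),
        margin_K=margin,
    )


def salient_change(image, p, region: CropRegion, out_size: int, eps: float = 0.5,
                   active: bool = True):
    """Crop image and P to the region and form the stage-2 input.

    With the coupling active the cropped image is multiplied by
    ``eps + (1 - eps) * P`` (P traced, so stage-2 gradients reach stage 1);
    inactive (step S) the raw crop is used.  Bilinear resize to the
    stage-2 input size.
    """
    rs, re, cs, ce = region.row_min, region.row_max, region.col_min, region.col_max
    img_crop = image[:, :, rs:re, cs:ce]
    if active:
        p_crop = p[:, :, rs:re, cs:ce]
        weighted = img_crop * (eps + (1.0 - eps) * p_crop)
    else:
        weighted = img_crop
    return ops.resize_bilinear(weighted, out_size, out_size)


def crop_mask(mask: np.ndarray, region: CropRegion, out_size: int) -> np.ndarray:
    """Nearest-neighbour crop+resize for binary targets."""
    m = mask[region.row_min:region.row_max, region.col_min:region.col_max]
    return ops.resize_nearest(m.astype(float), out_size, out_size)


def paste_back(pred_fine: np.ndarray, region: CropRegion, full_shape: tuple[int, int],
               threshold: float = 0.5) -> np.ndarray:
    """Resize a crop-space probability map to the region and paste the
    thresholded mask into a full-size zero canvas."""
    pred_fine = np.asarray(pred_fine)
    if pred_fine.ndim != 2:
        raise ValueError(f"expected 2D prediction, got shape {pred_fine.shape}")
    rh, rw = region.shape
    if rh > full_shape[0] or rw > full_shape[1]:
        raise ValueError(f"region {region} exceeds image shape {full_shape}")
    resized = ops.resize_bilinear(pred_fine[None, None], rh, rw)[0, 0]
    out = np.zeros(full_shape, dtype=np.uint8)
    out[region.row_min:region.row_max, region.col_min:region.col_max] = resized > threshold
    return out


# ------------------------------------------------------------- the model

class CascadeModel:
    """Parameter container + forward passes for the full cascade."""

    def __init__(self, config: CascadeConfig):
        if config.stage2_size % 16 or config.image_size % 16:
            raise ValueError("image_size and stage2_size must be divisible by 16")
        self.config = config
        self.bb_config = config.backbone_config()
        rng = np.random.default_rng(config.seed)
        r = config.reduce_channels
        feat_widths = [self.bb_config.central_width] + self.bb_config.dec_widths
        params = {
            "stage1": backbone.init_backbone(rng, self.bb_config),
            "stage2_backbone": backbone.init_backbone(rng, self.bb_config),
            "reduce": [init_conv(rng, cw, r, 1) for cw in feat_widths],
        }
        if config.use_localization:
            params["loc"] = attention.init_nonlocal(rng, attention.NonLocalConfig(r))
        else:
            params["loc_head"] = init_conv(rng, r, 1, 1, bias_init=-2.0)
        if config.use_focusing:
            fc = focusing.FocusConfig(r, norm=config.norm)
            params["focus"] = [focusing.init_focus(rng, fc) for _ in range(4)]
        self.params = params

    # -- forward pieces -------------------------------------------------

    def stage1_forward(self, params, image):
        return backbone.backbone_forward(params["stage1"], image, self.bb_config)

    def stage2_forward(self, params, stage2_input):
        """Returns the list of stage-2 probability maps (coarse -> fine),
        each upsampled to the stage-2 input size."""
        cfg = self.config
        _, feats = backbone.backbone_features(params["stage2_backbone"], stage2_input, self.bb_config)
        reduced = [conv(rp, f) for rp, f in zip(params["reduce"], feats)]
        if cfg.use_localization:
            loc_logits, f_att = attention.localize(params["loc"], reduced[0])
        else:
            loc_logits = conv(params["loc_head"], reduced[0])
            f_att = reduced[0]
        logits_list = [loc_logits]
        if cfg.use_focusing:
            fcfg = focusing.FocusConfig(cfg.reduce_channels, norm=cfg.norm)
            f_h, pred_h = f_att, loc_logits
            for lvl in range(1, 5):
                f_h, pred = focusing.refine(params["focus"][lvl - 1], reduced[lvl], f_h, pred_h, fcfg)
                logits_list.append(pred)
                pred_h = pred
        s = cfg.stage2_size
        return [ops.sigmoid(ops.resize_bilinear(lg, s, s)) for lg in logits_list]

    def _region_for(self, sample: SliceSample, p_value: np.ndarray, step: str) -> CropRegion:
        cfg = self.config
        if step in ("S", "I"):
            source = sample.pancreas_mask.astype(float)
        else:  # step J and inference: stage-1 output
            source = p_value
        return binarize_and_box(source, cfg.crop_threshold, cfg.margin_pixels)

    # -- losses ----------------------------------------------------------

    def loss_terms(self, params, sample: SliceSample, step: str):
        """Differentiable (L_seg1, L_seg2) plus the crop region and the
        stage-2 tumor target used."""
        cfg = self.config
        image = sample.image[None, None]
        p, _ = self.stage1_forward(params, image)
        l_seg1 = losses.dice_loss(p[0, 0], sample.pancreas_mask)

        p_value = ops.getval(p)[0, 0]
        region = self._region_for(sample, p_value, step)
        stage2_in = salient_change(
            image, p, region, cfg.stage2_size, eps=cfg.saliency_eps, active=step != "S"
        )
        preds = self.stage2_forward(params, stage2_in)
        gt2 = crop_mask(sample.tumor_mask, region, cfg.stage2_size)
        if cfg.use_focusing:
            l_seg2 = losses.stage2_total(preds[0][0, 0], [q[0, 0] for q in preds[1:]],
                                         gt2, cfg.weights)
        else:
            l_seg2 = losses.localization_loss(preds[0][0, 0], gt2)
        return l_seg1, l_seg2, preds, gt2, region

    def training_loss(self, params, sample: SliceSample, step: str):
        l_seg1, l_seg2, preds, gt2, _ = self.loss_terms(params, sample, step)
        return l_seg1 + self.config.weights.alpha * l_seg2, (preds, gt2, l_seg1, l_seg2)

    # -- inference -------------------------------------------------------

    def predict(self, image: np.ndarray) -> StagePrediction:
        cfg = self.config
        x = np.asarray(image, dtype=float)[None, None]
        p, _ = self.stage1_forward(self.params, x)
        p = np.asarray(p)
        region = binarize_and_box(p[0, 0], cfg.crop_threshold, cfg.margin_pixels)
        stage2_in = salient_change(x, p, region, cfg.stage2_size, eps=cfg.saliency_eps)
        preds = [np.asarray(q) for q in self.stage2_forward(self.params, stage2_in)]
        final = paste_back(preds[-1][0, 0], region, image.shape, cfg.crop_threshold)
        return StagePrediction(
            stage1_prob=p[0, 0],
            stage2_probs=[q[0, 0] for q in preds],
            region=region,
            final_mask=final,
        )

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "params": self.params}, fh)

    @classmethod
    def load(cls, path) -> "CascadeModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        model = cls.__new__(cls)
        model.config = payload["config"]
        model.bb_config = payload["config"].backbone_config()
        model.params = payload["params"]
        return model


# ------------------------------------------------------------- training

def run_schedule(
    train_set: list[SliceSample],
    config: CascadeConfig,
    checkpoint_dir=None,
    schedule: TrainSchedule | None = None,
    lr: float | None = None,
) -> tuple[CascadeModel, list[dict]]:
    """Train through steps S -> I -> J; returns the model and per-epoch logs.

    Each log record carries (step, epoch, loss_seg1, loss_seg2, loss_isb,
    total) averaged over the epoch.  Optimizer state persists across steps.
    """
    if not train_set:
        raise ValueError("empty training set")
    schedule = schedule or config.schedule
    model = CascadeModel(config)
    theta, spec = flatten_tree(model.params)
    opt = SGD(theta.size, lr=lr if lr is not None else config.lr,
              momentum=config.momentum, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    logs: list[dict] = []

    beta = config.weights.beta
    for step, n_epochs in schedule.steps():
        for epoch in range(n_epochs):
            order = rng.permutation(len(train_set))
            sums = np.zeros(4)  # l_seg1, l_seg2, l_isb, total
            for idx in order:
                sample = train_set[idx]
                aux: dict = {}

                def objective(th, sample=sample, aux=aux):
                    params = unflatten_tree(th, spec)
                    loss, (preds, gt2, l1, l2) = model.training_loss(params, sample, step)
                    aux["l1"] = float(ops.getval(l1))
                    aux["l2"] = float(ops.getval(l2))
                    aux["pred_fine"] = np.asarray(ops.getval(preds[-1]))[0, 0]
                    aux["gt2"] = np.asarray(gt2)
                    return loss

                _, grads = value_and_grad(objective)(theta)
                theta = opt.step(theta, grads)
                model.params = unflatten_tree(theta, spec)
                # ISB penalty: evaluated on hard labels, gradient-free
                l_isb = losses.isb_loss(
                    aux["pred_fine"], losses.foreground_to_labels(aux["gt2"]), n_c=2
                )
                total = aux["l1"] + config.weights.alpha * aux["l2"] + beta * l_isb
                sums += (aux["l1"], aux["l2"], l_isb, total)
            n = len(train_set)
            record = {
                "step": step,
                "epoch": epoch,
                "loss_seg1": sums[0] / n,
                "loss_seg2": sums[1] / n,
                "loss_isb": sums[2] / n,
                "total": sums[3] / n,
            }
            logs.append(record)
            logger.info(
                "step=%s epoch=%d loss_seg1=%.4f loss_seg2=%.4f loss_isb=%.4f total=%.4f",
                step, epoch, record["loss_seg1"], record["loss_seg2"],
                record["loss_isb"], record["total"],
            )
        if checkpoint_dir is not None:
            model.save(Path(checkpoint_dir) / f"after_step_{step}.pkl")
    return model, logs
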