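"""Fully convolutional grid detector.

A backbone CNN downsamples the trap image by a fixed stride; a 1x1-conv
head (hidden layer, ReLU, dropout, 1x1 conv, per-cell softmax) turns the
feature map into a 3-class probability grid — background, female (DSF) and
male (DSM) — one probability vector per stride x stride cell. Detection is
then: tile the full image into patches, stitch the per-patch grids,
suppress non-maxima class-agnostically in each 3x3 neighbourhood, and read
the surviving cells out as point detections at cell centres.

Two backbone variants are provided: ``paper18`` — a residual network of
18-layer depth truncated at its last residual block (512 channels, stride
32, 512-px patches); and ``tiny`` — a three-layer strided conv stack
(64 channels, stride 8) small enough to train on a CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import _nn as nn
from .annotations_io import Detection

GRID_CLASSES = ("background", "DSF", "DSM")
BACKGROUND, IDX_DSF, IDX_DSM = 0, 1, 2

#: cells with confidence below this floor are dropped after NMS to bound
#: output size; evaluation sweeps thresholds above it
DEFAULT_CONFIDENCE_FLOOR = 0.05


@dataclass(frozen=True)
class DetectorConfig:
    backbone_depth: str = "paper18"  # "paper18" | "tiny"
    stride: int = 32
    head_hidden: int = 1024
    n_classes: int = 3
    dropout_p: float = 0.5
    patch_size: int = 512

    def __post_init__(self):
        if self.backbone_depth not in ("paper18", "tiny"):
            raise ValueError(f"unknown backbone {self.backbone_depth!r}")
        if self.n_classes != 3:
            raise ValueError("the detector head has exactly 3 classes")
        if self.patch_size % self.stride != 0:
            raise ValueError("patch_size must be divisible by stride")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")


def tiny_config(patch_size: int = 128, head_hidden: int = 128) -> DetectorConfig:
    """CPU-scale detector: stride-8 conv backbone, small head."""
    return DetectorConfig(backbone_depth="tiny", stride=8,
                          head_hidden=head_hidden, patch_size=patch_size)


@dataclass
class ProbabilityGrid:
    """Per-cell class probabilities at detector stride.

    ``probs`` has shape (rows, cols, 3) ordered (background, DSF, DSM);
    each cell's probabilities sum to 1. ``origin`` is the full-image pixel
    offset of the grid's top-left cell.
    """

    probs: np.ndarray
    stride: int
    origin: tuple[int, int] = (0, 0)

    @property
    def rows(self) -> int:
        return self.probs.shape[0]

    @property
    def cols(self) -> int:
        return self.probs.shape[1]

    def confidence_map(self) -> np.ndarray:
        """Class-agnostic confidence: max of the two fly-class probabilities."""
        return self.probs[:, :, (IDX_DSF, IDX_DSM)].max(axis=2)


@dataclass(frozen=True)
class CellDetection:
    row: int
    col: int
    pred_class: str  # "DSF" | "DSM"
    confidence: float


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

class GridModel:
    """Backbone + 1x1-conv head emitting per-cell class logits."""

    def __init__(self, cfg: DetectorConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        if cfg.backbone_depth == "paper18":
            if cfg.stride != 32:
                raise ValueError("paper18 backbone has stride 32")
            feat = 512
            layers: list[nn.Layer] = [
                nn.Conv2d(3, 64, 7, 2, 3, bias=False, rng=rng),
                nn.BatchNorm2d(64), nn.ReLU(), nn.MaxPool2d(3, 2, 1),
                nn.BasicBlock(64, 64, 1, rng=rng),
                nn.BasicBlock(64, 64, 1, rng=rng),
                nn.BasicBlock(64, 128, 2, rng=rng),
                nn.BasicBlock(128, 128, 1, rng=rng),
                nn.BasicBlock(128, 256, 2, rng=rng),
                nn.BasicBlock(256, 256, 1, rng=rng),
                nn.BasicBlock(256, 512, 2, rng=rng),
                nn.BasicBlock(512, 512, 1, rng=rng),
            ]
        else:
            if cfg.stride != 8:
                raise ValueError("tiny backbone has stride 8")
            feat = 64
            # three stride-2 convs reach stride 8; the trailing stride-1 conv
            # widens the receptive field past one whole fly silhouette
            layers = [
                nn.Conv2d(3, 16, 3, 2, 1, bias=False, rng=rng),
                nn.BatchNorm2d(16), nn.ReLU(),
                nn.Conv2d(16, 32, 3, 2, 1, bias=False, rng=rng),
                nn.BatchNorm2d(32), nn.ReLU(),
                nn.Conv2d(32, 64, 3, 2, 1, bias=False, rng=rng),
                nn.BatchNorm2d(64), nn.ReLU(),
                nn.Conv2d(64, 64, 3, 1, 1, bias=False, rng=rng),
                nn.BatchNorm2d(64), nn.ReLU(),
            ]
        self.dropout = nn.Dropout(cfg.dropout_p, rng=np.random.default_rng(seed + 1))
        layers += [
            nn.Conv2d(feat, cfg.head_hidden, 1, rng=rng),
            nn.ReLU(),
            self.dropout,
            nn.Conv2d(cfg.head_hidden, cfg.n_classes, 1, rng=rng),
        ]
        self.net = nn.Sequential(*layers)

    # -- numerical core ---------------------------------------------------

    @staticmethod
    def _prep(images: np.ndarray) -> np.ndarray:
        """HWC uint8 (or NHWC batch) -> normalised NCHW float32."""
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[None]
        x = x.astype(np.float32) / 255.0 - 0.5
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward_logits(self, x_nchw: np.ndarray, train: bool) -> np.ndarray:
        h, w = x_nchw.shape[2:]
        if h % self.cfg.stride or w % self.cfg.stride:
            raise ValueError(
                f"input {h}x{w} not divisible by stride {self.cfg.stride}; pad first")
        return self.net.forward(x_nchw, train)

    def backward(self, dlogits: np.ndarray) -> None:
        self.net.backward(dlogits)

    def parameters(self) -> list[nn.Parameter]:
        return self.net.parameters()

    def predict_probs(self, images) -> np.ndarray:
        """Inference probabilities, (N, rows, cols, 3); dropout disabled."""
        logits = self.forward_logits(self._prep(images), train=False)
        return nn.softmax(logits, axis=1).transpose(0, 2, 3, 1)

    # -- persistence ------------------------------------------------------

    def _batchnorms(self) -> list[nn.BatchNorm2d]:
        out = []

        def walk(layer):
            if isinstance(layer, nn.BatchNorm2d):
                out.append(layer)
            elif isinstance(layer, nn.Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, nn.BasicBlock):
                for sub in (layer.conv1, layer.bn1, layer.conv2, layer.bn2):
                    walk(sub)
                if layer.proj is not None:
                    walk(layer.proj[0])
                    walk(layer.proj[1])

        walk(self.net)
        return out

    def save(self, path: str | Path) -> None:
        """Checkpoint as .npz with a JSON sidecar recording the config."""
        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn_{i}_mean"] = bn.running_mean
            arrays[f"bn_{i}_var"] = bn.running_var
        np.savez(path, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(self.cfg), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GridModel":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        cfg = DetectorConfig(**json.loads(sidecar.read_text()))
        model = cls(cfg)
        with np.load(path) as data:
            for i, p in enumerate(model.parameters()):
                p.data[...] = data[f"param_{i}"]
            for i, bn in enumerate(model._batchnorms()):
                bn.running_mean = data[f"bn_{i}_mean"]
                bn.running_var = data[f"bn_{i}_var"]
        return model


def build_model(cfg: DetectorConfig, seed: int = 0) -> GridModel:
    """Construct a grid detector with He-normal initialisation."""
    return GridModel(cfg, seed=seed)


# --------------------------------------------------------------------------
# Inference
# --------------------------------------------------------------------------

def predict_patch(model: GridModel, patch: np.ndarray,
                  origin: tuple[int, int] = (0, 0)) -> ProbabilityGrid:
    """Probability grid for one patch_size x patch_size patch."""
    ps = model.cfg.patch_size
    if patch.shape[0] != ps or patch.shape[1] != ps:
        raise ValueError(f"patch must be {ps}x{ps}, got {patch.shape[:2]}")
    probs = model.predict_probs(patch)[0]
    return ProbabilityGrid(probs=probs, stride=model.cfg.stride, origin=origin)


def predict_image(model: GridModel, image: np.ndarray) -> ProbabilityGrid:
    """Tiled inference over an arbitrary-size image, stitched to one grid.

    The image is reflection-padded on the right/bottom to a multiple of the
    patch size, each tile evaluated separately, and the per-tile grids
    stitched back to the full extent. Cells whose centres fall inside the
    padding are discarded, so no detection can lie outside the original
    image bounds.
    """
    ps, stride = model.cfg.patch_size, model.cfg.stride
    h, w = image.shape[:2]
    ph = (ps - h % ps) % ps
    pw = (ps - w % ps) % ps
    padded = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect") \
        if (ph or pw) else image
    hp, wp = padded.shape[:2]
    grid = np.zeros((hp // stride, wp // stride, 3), dtype=np.float32)
    for y0 in range(0, hp, ps):
        for x0 in range(0, wp, ps):
            tile = padded[y0:y0 + ps, x0:x0 + ps]
            g = model.predict_probs(tile)[0]
            grid[y0 // stride:(y0 + ps) // stride,
                 x0 // stride:(x0 + ps) // stride] = g
    # keep only cells whose centre lies inside the original image
    n_rows = int(np.ceil(h / stride - 0.5))
    n_cols = int(np.ceil(w / stride - 0.5))
    return ProbabilityGrid(probs=grid[:n_rows, :n_cols], stride=stride,
                           origin=(0, 0))


# --------------------------------------------------------------------------
# Non-maximum suppression and point conversion
# --------------------------------------------------------------------------

def nms_grid(grid: ProbabilityGrid,
             min_confidence: float = DEFAULT_CONFIDENCE_FLOOR
             ) -> list[CellDetection]:
    """Class-agnostic 3x3 non-maximum suppression on the stitched grid.

    A cell's confidence is the larger of its two fly-class probabilities.
    A cell is retained iff it beats all 8 neighbours; equal-confidence ties
    go to the cell earlier in row-major order. Retained cells below
    ``min_confidence`` are dropped.
    """
    conf = grid.confidence_map()
    rows, cols = conf.shape
    padded = np.full((rows + 2, cols + 2), -np.inf, dtype=conf.dtype)
    padded[1:-1, 1:-1] = conf
    keep = np.ones((rows, cols), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr:1 + dr + rows, 1 + dc:1 + dc + cols]
            later = dr > 0 or (dr == 0 and dc > 0)
            if later:
                keep &= conf >= nb  # later neighbour loses ties
            else:
                keep &= conf > nb  # earlier neighbour wins ties
    keep &= conf >= min_confidence
    fly = grid.probs[:, :, (IDX_DSF, IDX_DSM)]
    cls_idx = fly.argmax(axis=2)  # 0 -> DSF, 1 -> DSM
    out = []
    for r, c in zip(*np.nonzero(keep)):
        out.append(CellDetection(
            row=int(r), col=int(c),
            pred_class="DSM" if cls_idx[r, c] else "DSF",
            confidence=float(conf[r, c])))
    return out


def cells_to_detections(cells: list[CellDetection], grid: ProbabilityGrid,
                        image_id: str = "") -> list[Detection]:
    """Grid cells -> full-image point detections at cell centres."""
    ox, oy = grid.origin
    s = grid.stride
    return [Detection(x=ox + (c.col + 0.5) * s, y=oy + (c.row + 0.5) * s,
                      pred_class=c.pred_class, confidence=c.confidence,
                      image_id=image_id)
            for c in cells]


def detect_image(model: GridModel, image: np.ndarray, image_id: str = "",
                 min_confidence: float = DEFAULT_CONFIDENCE_FLOOR
                 ) -> tuple[list[Detection], ProbabilityGrid]:
    """Full pipeline for one image: tiled inference, NMS, point readout."""
    grid = predict_image(model, image)
    cells = nms_grid(grid, min_confidence=min_confidence)
    return cells_to_detections(cells, grid, image_id=image_id), grid


def export_probability_maps(grid: ProbabilityGrid, out_prefix: str | Path
                            ) -> list[Path]:
    """Write per-fly-class probability maps as greyscale PNGs."""
    out_prefix = Path(out_prefix)
    paths = []
    for idx, name in ((IDX_DSF, "DSF"), (IDX_DSM, "DSM")):
        arr = (np.clip(grid.probs[:, :, idx], 0, 1) * 255).astype(np.uint8)
        p = out_prefix.parent / f"{out_prefix.name}_prob_{name}.png"
        Image.fromarray(arr, mode="L").save(p)
        paths.append(p)
    return paths
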