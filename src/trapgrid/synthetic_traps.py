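"""Synthetic sticky-trap scene generator.

Renders trap photographs the way the field collects them: a red sticky
card on a cluttered outdoor background, carrying dark fly silhouettes
(~5700 px² on the reference camera, box aspect ~1:1.3) and assorted
bycatch, under uniform, gradient or shadowed illumination. Male flies
carry two dark wing spots; females are otherwise identical — the single
visual cue separating the sexes, mirroring the real morphology. A UAV
degradation step adds defocus blur and framing offset.

Every scene is fully determined by its seed, so generated datasets are
reproducible fixtures for the detector, trainer and evaluator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import disk, ellipse

from .annotations_io import AnnotatedImage, BBox, write_voc_annotation

# Reference camera frame (20 MP compact camera used for the trap photographs).
DEFAULT_IMAGE_SIZE = (5472, 3648)

# Palette (R, G, B). Flies are darker than the trap by construction; the
# contrast margin below is asserted as a generator invariant in the tests.
TRAP_COLOR = (204, 46, 40)
FLY_BODY_COLOR = (52, 30, 22)
FLY_WING_COLOR = (150, 110, 95)
WING_SPOT_COLOR = (22, 14, 10)
BYCATCH_COLOR = (58, 52, 40)
FLY_CONTRAST_MARGIN = 10  # grey levels; mean(box) vs mean(trap card)

ILLUMINATION_MODES = ("uniform", "gradient", "shadowed")


class PlacementError(RuntimeError):
    """Requested insect counts could not be placed after bounded retries."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one rendered trap scene.

    ``fly_area_mean`` is the mean bounding-box area in px² and
    ``fly_aspect`` the mean long/short box-side ratio; both default to the
    reference trap photography (5700 px², 1:1.3). ``cluster_prob`` is the
    probability that an insect is placed adjacent to / overlapping an
    already placed one, producing the occluded regime that defeats grid
    detectors. ``blur_sigma`` emulates UAV defocus.
    """

    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE  # (width, height)
    n_dsm: int = 8
    n_dsf: int = 8
    n_bc: int = 12
    fly_area_mean: float = 5700.0
    fly_aspect: float = 1.3
    cluster_prob: float = 0.0
    illumination: str = "uniform"
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_dsm, self.n_dsf, self.n_bc) < 0:
            raise ValueError("insect counts must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.fly_area_mean <= 0:
            raise ValueError("fly_area_mean must be > 0")
        if self.illumination not in ILLUMINATION_MODES:
            raise ValueError(f"illumination must be one of {ILLUMINATION_MODES}")


@dataclass
class Scene:
    image: np.ndarray  # (H, W, 3) uint8
    annotation: AnnotatedImage


# --------------------------------------------------------------------------
# Size sampling
# --------------------------------------------------------------------------

# Log-normal spread of box areas; ~95% of areas fall within a factor ~2.3
# of the mean on either side, covering the small-to-large flies a trap shows.
AREA_LOG_SIGMA = 0.42
ASPECT_JITTER = 0.15


def sample_fly_box_dims(rng: np.random.Generator, area_mean: float,
                        aspect_mean: float) -> tuple[float, float]:
    """Sample (long, short) box side lengths in pixels.

    Areas are log-normal with mean exactly ``area_mean``; the aspect ratio
    is jittered uniformly ±15% around ``aspect_mean``.
    """
    mu = math.log(area_mean) - AREA_LOG_SIGMA ** 2 / 2.0
    area = rng.lognormal(mu, AREA_LOG_SIGMA)
    aspect = aspect_mean * rng.uniform(1 - ASPECT_JITTER, 1 + ASPECT_JITTER)
    long_side = math.sqrt(area * aspect)
    short_side = math.sqrt(area / aspect)
    return long_side, short_side


# --------------------------------------------------------------------------
# Background and trap
# --------------------------------------------------------------------------

def _multiscale_noise(rng, h, w):
    """Cheap fractal noise: random coarse grids upsampled and summed."""
    out = np.zeros((h, w), dtype=np.float32)
    amp = 1.0
    for cells in (4, 16, 64):
        gh, gw = min(cells, h), min(cells, w)
        grid = rng.random((gh, gw)).astype(np.float32)
        out += amp * np.asarray(
            Image.fromarray(grid, mode="F").resize((w, h), Image.BILINEAR))
        amp *= 0.5
    out -= out.min()
    peak = out.max()
    return out / peak if peak > 0 else out


def _render_background(rng, h, w):
    noise = _multiscale_noise(rng, h, w)
    base = np.stack([40 + 70 * noise, 60 + 80 * noise, 35 + 50 * noise], axis=-1)
    # scattered rectangles: leaves, boards, ground litter
    for _ in range(rng.integers(3, 9)):
        rh = int(rng.uniform(0.05, 0.3) * h)
        rw = int(rng.uniform(0.05, 0.3) * w)
        r0 = int(rng.uniform(0, h - rh))
        c0 = int(rng.uniform(0, w - rw))
        color = rng.uniform(20, 160, size=3)
        base[r0:r0 + rh, c0:c0 + rw] = 0.5 * base[r0:r0 + rh, c0:c0 + rw] + 0.5 * color
    return base


def _render_trap(rng, img, trap_rect):
    x0, y0, x1, y1 = trap_rect
    h, w = y1 - y0, x1 - x0
    red = np.empty((h, w, 3), dtype=np.float32)
    red[..., 0] = TRAP_COLOR[0]
    red[..., 1] = TRAP_COLOR[1]
    red[..., 2] = TRAP_COLOR[2]
    red += rng.normal(0, 4, size=red.shape)
    # printed grid texture on the card
    spacing = max(24, min(h, w) // 12)
    for r in range(0, h, spacing):
        red[r:r + 2, :] *= 0.75
    for c in range(0, w, spacing):
        red[:, c:c + 2] *= 0.75
    img[y0:y1, x0:x1] = red


# --------------------------------------------------------------------------
# Insects
# --------------------------------------------------------------------------

def _draw_fly_tile(th: int, tw: int, male: bool, rng,
                   body_color=FLY_BODY_COLOR,
                   wing_color=FLY_WING_COLOR) -> np.ndarray:
    """Render one fly into an RGBA float tile of shape (th, tw).

    Body is an ellipse along the tile's long axis with two splayed wings
    toward the rear; males additionally get one dark spot near each wing
    tip. Returns (th, tw, 4): RGB + alpha in [0, 1].
    """
    tile = np.zeros((th, tw, 4), dtype=np.float32)
    horizontal = tw >= th
    # work in (axial, lateral) then map to (row, col)
    L = tw if horizontal else th
    S = th if horizontal else tw

    def draw_ellipse(ax_c, lat_c, ax_r, lat_r, color, alpha):
        if horizontal:
            r_c, c_c, r_r, c_r = lat_c, ax_c, lat_r, ax_r
        else:
            r_c, c_c, r_r, c_r = ax_c, lat_c, ax_r, lat_r
        ys, xs = ellipse(r_c, c_c, max(r_r, 1.0), max(c_r, 1.0), shape=(th, tw))
        tile[ys, xs, :3] = (1 - alpha) * tile[ys, xs, :3] + alpha * np.asarray(color)
        tile[ys, xs, 3] = np.maximum(tile[ys, xs, 3], alpha)

    jitter = rng.uniform(0.95, 1.05)
    # wings first (splayed toward the rear), then body on top
    for side in (-1, 1):
        draw_ellipse(0.60 * L, S / 2 + side * 0.20 * S,
                     0.34 * L * jitter, 0.18 * S, wing_color, 0.9)
    draw_ellipse(0.40 * L, S / 2, 0.32 * L, 0.24 * S * jitter, body_color, 1.0)
    # head
    draw_ellipse(0.12 * L, S / 2, 0.10 * L, 0.14 * S, body_color, 1.0)
    if male:
        spot_r = max(1.5, 0.09 * L)
        for side in (-1, 1):
            c_ax, c_lat = 0.84 * L, S / 2 + side * 0.24 * S
            rc, cc = (c_lat, c_ax) if horizontal else (c_ax, c_lat)
            ys, xs = disk((rc, cc), spot_r, shape=(th, tw))
            tile[ys, xs, :3] = WING_SPOT_COLOR
            tile[ys, xs, 3] = 1.0
    return tile


def _draw_bycatch_tile(th: int, tw: int, rng) -> np.ndarray:
    tile = np.zeros((th, tw, 4), dtype=np.float32)
    shade = np.asarray(BYCATCH_COLOR) * rng.uniform(0.7, 1.5)
    if rng.random() < 0.5:
        # elongate: slender insect (wasp/cricket-like)
        ys, xs = ellipse(th / 2, tw / 2, max(th * 0.18, 1), max(tw * 0.45, 1),
                         shape=(th, tw))
    else:
        # round beetle-like blob
        ys, xs = ellipse(th / 2, tw / 2, max(th * 0.42, 1), max(tw * 0.42, 1),
                         shape=(th, tw))
    tile[ys, xs, :3] = np.clip(shade, 0, 255)
    tile[ys, xs, 3] = 1.0
    return tile


def _paste_tile(img, tile, x0, y0):
    th, tw = tile.shape[:2]
    alpha = tile[..., 3:4]
    region = img[y0:y0 + th, x0:x0 + tw]
    img[y0:y0 + th, x0:x0 + tw] = (1 - alpha) * region + alpha * tile[..., :3]


# --------------------------------------------------------------------------
# Scene assembly
# --------------------------------------------------------------------------

def _place_insects(rng, cfg: SceneConfig, trap_rect):
    """Sample (label, x0, y0, w, h) for every insect, with clustering."""
    tx0, ty0, tx1, ty1 = trap_rect
    labels = ["DSM"] * cfg.n_dsm + ["DSF"] * cfg.n_dsf + ["BC"] * cfg.n_bc
    rng.shuffle(labels)
    placed: list[tuple[str, str, int, int, int, int]] = []
    for label in labels:
        subtype = label
        if label == "BC":
            # bycatch mixes other drosophilids (spotless fly lookalikes,
            # the dominant confusion source for females) with insects of
            # a different size/shape family
            if rng.random() < 0.4:
                subtype = "droso"
                long_s, short_s = sample_fly_box_dims(
                    rng, cfg.fly_area_mean * 0.75, cfg.fly_aspect)
            else:
                subtype = "other"
                scale = rng.choice([0.55, 1.8])
                long_s, short_s = sample_fly_box_dims(
                    rng, cfg.fly_area_mean * scale,
                    cfg.fly_aspect * rng.uniform(1, 2.5))
        else:
            long_s, short_s = sample_fly_box_dims(
                rng, cfg.fly_area_mean, cfg.fly_aspect)
        if rng.random() < 0.5:
            bw, bh = long_s, short_s
        else:
            bw, bh = short_s, long_s
        bw, bh = max(3, int(round(bw))), max(3, int(round(bh)))
        if tx1 - tx0 <= bw or ty1 - ty0 <= bh:
            raise PlacementError(
                f"insect box {bw}x{bh} does not fit trap {tx1-tx0}x{ty1-ty0}")
        diag = math.hypot(bw, bh)
        for attempt in range(500):
            if placed and rng.random() < cfg.cluster_prob:
                _, _, px, py, pw, ph = placed[rng.integers(len(placed))]
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0.2, 0.7) * max(pw, ph)
                cx = px + pw / 2 + rad * math.cos(ang)
                cy = py + ph / 2 + rad * math.sin(ang)
                x0 = int(round(cx - bw / 2))
                y0 = int(round(cy - bh / 2))
                if not (tx0 <= x0 and x0 + bw <= tx1 and ty0 <= y0 and y0 + bh <= ty1):
                    continue
                break
            x0 = int(rng.integers(tx0, tx1 - bw))
            y0 = int(rng.integers(ty0, ty1 - bh))
            cx, cy = x0 + bw / 2, y0 + bh / 2
            # pairwise size-aware separation, relaxed after many rejections
            relax = 1.0 if attempt < 250 else 0.5
            if all(math.hypot(cx - (px + pw / 2), cy - (py + ph / 2))
                   >= relax * 0.65 * (diag + math.hypot(pw, ph))
                   for _, _, px, py, pw, ph in placed):
                break
        else:
            raise PlacementError(
                f"could not place insect {len(placed)+1} after 500 attempts")
        placed.append((label, subtype, x0, y0, bw, bh))
    return placed


def _apply_illumination(rng, img, mode):
    h, w = img.shape[:2]
    if mode == "gradient":
        ramp = np.linspace(0.6, 1.1, w, dtype=np.float32)[None, :, None]
        img *= ramp
    elif mode == "shadowed":
        cy, cx = rng.uniform(0.25, 0.75) * h, rng.uniform(0.25, 0.75) * w
        yy, xx = np.mgrid[0:h, 0:w]
        d2 = (((yy - cy) / (0.45 * h)) ** 2 + ((xx - cx) / (0.45 * w)) ** 2)
        shade = 1.0 - 0.45 * np.exp(-d2).astype(np.float32)
        img *= shade[..., None]


def render_scene(cfg: SceneConfig) -> Scene:
    """Render one trap scene deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.image_size
    img = _render_background(rng, h, w)

    margin_x, margin_y = int(0.07 * w), int(0.07 * h)
    trap_rect = (margin_x, margin_y, w - margin_x, h - margin_y)
    _render_trap(rng, img, trap_rect)

    placed = _place_insects(rng, cfg, trap_rect)
    boxes = []
    for label, subtype, x0, y0, bw, bh in placed:
        if subtype == "droso":
            shade = rng.uniform(1.15, 1.4)
            tile = _draw_fly_tile(
                bh, bw, male=False, rng=rng,
                body_color=tuple(min(255.0, c * shade) for c in FLY_BODY_COLOR),
                wing_color=FLY_WING_COLOR)
        elif subtype == "other":
            tile = _draw_bycatch_tile(bh, bw, rng)
        else:
            tile = _draw_fly_tile(bh, bw, male=(label == "DSM"), rng=rng)
        _paste_tile(img, tile, x0, y0)
        boxes.append(BBox(x0, y0, x0 + bw, y0 + bh, label))

    _apply_illumination(rng, img, cfg.illumination)
    img += rng.normal(0, 2.0, size=img.shape).astype(np.float32)
    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(cfg.blur_sigma, cfg.blur_sigma, 0))
    img = np.clip(img, 0, 255).astype(np.uint8)
    ann = AnnotatedImage(f"scene_{cfg.seed:08d}", w, h, boxes)
    return Scene(image=img, annotation=ann)


def render_dataset(n_scenes: int, cfg_template: SceneConfig,
                   out_dir: str | Path, seed: int) -> list[Path]:
    """Write ``n_scenes`` PNG + VOC XML pairs plus a manifest of ids.

    Per-scene seeds are derived from the master seed, so the dataset is
    reproducible as a whole and each scene individually.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child = np.random.SeedSequence(seed).generate_state(n_scenes) & 0x7FFFFFFF
    paths, ids = [], []
    for i in range(n_scenes):
        scene = render_scene(replace(cfg_template, seed=int(child[i])))
        image_id = f"scene_{i:04d}"
        scene.annotation.image_id = image_id
        png = out_dir / f"{image_id}.png"
        xml = out_dir / f"{image_id}.xml"
        Image.fromarray(scene.image).save(png)
        write_voc_annotation(scene.annotation, xml)
        paths += [png, xml]
        ids.append(image_id)
    manifest = out_dir / "manifest.txt"
    manifest.write_text("".join(f"{i}\n" for i in ids))
    paths.append(manifest)
    return paths


def degrade_uav(scene: Scene, blur_sigma: float, offset_px: tuple[int, int],
                seed: int = 0) -> Scene:
    """Emulate UAV acquisition: defocus blur plus framing offset.

    The image is blurred, translated by ``offset_px = (dx, dy)`` (revealed
    borders filled with a neutral grey) and lightly re-noised in proportion
    to the blur. Boxes shift identically; boxes pushed fully outside the
    frame are dropped, partially outside are clipped.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    img = scene.image.astype(np.float32)
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(blur_sigma, blur_sigma, 0))
    dx, dy = int(offset_px[0]), int(offset_px[1])
    h, w = img.shape[:2]
    out = np.full_like(img, 72.0)
    sx0, sx1 = max(0, -dx), min(w, w - dx)
    sy0, sy1 = max(0, -dy), min(h, h - dy)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 + dy:sy1 + dy, sx0 + dx:sx1 + dx] = img[sy0:sy1, sx0:sx1]
    if blur_sigma > 0:
        rng = np.random.default_rng(seed)
        out += rng.normal(0, 0.5 * blur_sigma, size=out.shape)
    out = np.clip(out, 0, 255).astype(np.uint8)

    boxes = []
    for b in scene.annotation.boxes:
        x0, y0 = b.xmin + dx, b.ymin + dy
        x1, y1 = b.xmax + dx, b.ymax + dy
        cx0, cy0 = max(0, x0), max(0, y0)
        cx1, cy1 = min(w, x1), min(h, y1)
        if cx1 <= cx0 or cy1 <= cy0:
            continue  # left the frame entirely
        boxes.append(BBox(cx0, cy0, cx1, cy1, b.label))
    ann = AnnotatedImage(scene.annotation.image_id + "_uav",
                         w, h, boxes)
    return Scene(image=out, annotation=ann)
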