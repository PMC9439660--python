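"""Tissue masking, tile-grid extraction, Reinhard stain transfer, balancing.

The image-preparation stage: a saturation-channel Otsu mask separates
stained tissue from white slide background, the tissue is cut into a
non-overlapping grid of square tiles (299 px in the original workflow,
configurable), and staining differences between cohorts are removed by
matching per-channel statistics in the decorrelated log color space (lαβ)
of the Reinhard color-transfer method.  The transfer is *masked*: the
statistics are pooled over tissue pixels only, so white background never
biases the template — that robustness is the whole point of the
modification and is asserted in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import gaussian, threshold_otsu

__all__ = [
    "TissueMask",
    "Tile",
    "StainTemplate",
    "tissue_mask",
    "tile_grid",
    "rgb_to_lab",
    "lab_to_rgb",
    "estimate_template",
    "reinhard_normalize",
    "augment_balance",
    "dihedral_transform",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TissueMask:
    """Binary tissue/background mask for one image."""

    mask: np.ndarray  # bool, same H×W as source
    threshold: float
    channel: str = "saturation"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def n_tissue(self) -> int:
        return int(self.mask.sum())


@dataclass
class Tile:
    """One square crop from a slide, addressed by its grid cell.

    ``grid_row``/``grid_col`` are 0-based tile indices; the tile's pixel
    origin is ``(grid_row * side, grid_col * side)`` with half-open extents.
    """

    pixels: np.ndarray  # uint8, side×side×3
    slide_id: Optional[str] = None
    grid_row: int = 0
    grid_col: int = 0
    coverage: float = 1.0
    label: Optional[str] = None

    @property
    def side(self) -> int:
        return int(self.pixels.shape[0])


@dataclass
class StainTemplate:
    """Per-channel mean/sd in lαβ space over pooled tissue pixels."""

    means: np.ndarray  # shape (3,)
    sds: np.ndarray    # shape (3,), strictly positive
    n_pixels: int

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(self.sds <= 0):
            raise ValueError("StainTemplate sds must be > 0")

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "n_pixels": int(self.n_pixels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainTemplate":
        return cls(np.asarray(d["means"]), np.asarray(d["sds"]), int(d["n_pixels"]))


def _require_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            "expected an RGB image of shape (H, W, 3); got shape "
            f"{image.shape} — convert grayscale input to RGB first"
        )
    return image


# ---------------------------------------------------------------------------
# Tissue masking
# ---------------------------------------------------------------------------

#: Saturation floor used when the slide has no white background at all
#: (unimodal saturation): white glass sits near 0, any stain well above.
_SATURATION_FLOOR = 0.08

#: Minimal Otsu between-class mean separation for the split to be trusted.
_MIN_BIMODAL_CONTRAST = 0.05

#: Saturation values are compressed above this cap before thresholding, so
#: that strongly saturated tissue (hemorrhage) cannot pull the Otsu split
#: into the middle of the tissue modes instead of the white/tissue gap.
_SATURATION_CAP = 0.25


def tissue_mask(image: np.ndarray, sigma: float = 3.0) -> TissueMask:
    """Otsu threshold on the (capped, blurred) saturation channel.

    White background has near-zero saturation while stained tissue is
    strongly colored, so Otsu on saturation separates the two.  A constant
    channel (e.g. an all-white scan) yields an all-background mask.  When
    the channel is non-constant but effectively unimodal (a slide that is
    wall-to-wall tissue), the Otsu split would cut through noise; in that
    case a fixed saturation floor is used instead.
    """
    image = _require_rgb(image)
    sat = np.minimum(rgb2hsv(image)[..., 1], _SATURATION_CAP)
    blurred = gaussian(sat, sigma=sigma, preserve_range=True)
    if float(blurred.max() - blurred.min()) < 1e-6:
        return TissueMask(np.zeros(blurred.shape, dtype=bool), float("nan"))
    thr = float(threshold_otsu(blurred))
    above = blurred > thr
    contrast = float(blurred[above].mean() - blurred[~above].mean()) if above.any() and (~above).any() else 0.0
    if contrast < _MIN_BIMODAL_CONTRAST:
        thr = _SATURATION_FLOOR
        above = blurred > thr
    return TissueMask(above, thr)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_grid(
    image: np.ndarray,
    mask: TissueMask,
    side: int = 299,
    min_coverage: float = 0.5,
    slide_id: Optional[str] = None,
) -> List[Tile]:
    """Cut a non-overlapping tile grid anchored at pixel (0, 0).

    Partial tiles at the right/bottom edges are discarded; tiles whose
    tissue coverage is below ``min_coverage`` are excluded.  Tiles are
    returned in row-major order.
    """
    image = _require_rgb(image)
    h, w = image.shape[:2]
    if side > min(h, w):
        raise ValueError(f"tile side {side} exceeds image dims {h}×{w}")
    if mask.mask.shape != (h, w):
        raise ValueError("mask dims do not match image dims")
    tiles: List[Tile] = []
    for r in range(h // side):
        for c in range(w // side):
            sl = (slice(r * side, (r + 1) * side), slice(c * side, (c + 1) * side))
            cov = float(mask.mask[sl].mean())
            if cov < min_coverage:
                continue
            tiles.append(
                Tile(
                    pixels=np.ascontiguousarray(image[sl]),
                    slide_id=slide_id,
                    grid_row=r,
                    grid_col=c,
                    coverage=cov,
                )
            )
    return tiles


# ---------------------------------------------------------------------------
# Reinhard lαβ color transfer (tissue-masked statistics)
# ---------------------------------------------------------------------------

# RGB → LMS cone response and the decorrelating log-space rotation of the
# Reinhard/Ruderman color-transfer method.
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.array(
    [
        [4.4679, -3.5873, 0.1193],
        [-1.2186, 2.3809, -0.1624],
        [0.0497, -0.2439, 1.2045],
    ]
)
_LAB_ROT = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float
)
_LAB_ROT_INV = np.linalg.inv(_LAB_ROT)

_LMS_EPS = 1e-6


def rgb_to_lab(pixels: np.ndarray) -> np.ndarray:
    """Map 8-bit RGB to lαβ (log-LMS decorrelated). Accepts (..., 3)."""
    rgb = np.asarray(pixels, dtype=float) / 255.0
    lms = rgb @ _RGB2LMS.T
    lms = np.clip(lms, _LMS_EPS, None)
    return np.log10(lms) @ _LAB_ROT.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`, clipped to valid 8-bit RGB."""
    lms = np.power(10.0, np.asarray(lab, dtype=float) @ _LAB_ROT_INV.T)
    rgb = lms @ _LMS2RGB.T
    return np.clip(rgb * 255.0, 0, 255)


def estimate_template(
    images: Sequence[np.ndarray],
    masks: Sequence[TissueMask],
    min_pixels: int = 1000,
) -> StainTemplate:
    """Pool tissue pixels across images and return lαβ channel statistics."""
    if len(images) == 0 or len(images) != len(masks):
        raise ValueError("need equally many images and masks, at least one each")
    chunks = []
    for img, m in zip(images, masks):
        img = _require_rgb(img)
        chunks.append(img[m.mask])
    pixels = np.concatenate(chunks, axis=0)
    if pixels.shape[0] < min_pixels:
        raise ValueError(
            f"only {pixels.shape[0]} tissue pixels pooled; need ≥ {min_pixels}"
        )
    lab = rgb_to_lab(pixels)
    means = lab.mean(axis=0)
    sds = np.maximum(lab.std(axis=0), 1e-6)  # clamp for constant-color tissue
    return StainTemplate(means, sds, pixels.shape[0])


def reinhard_normalize(
    image: np.ndarray,
    mask: TissueMask,
    target: StainTemplate,
) -> np.ndarray:
    """Transfer the target's lαβ statistics onto the image's tissue pixels.

    Tissue pixels are z-scored per channel using statistics computed over
    the mask only, rescaled to the target's sds and shifted to its means,
    then mapped back to RGB; background pixels pass through unchanged.
    """
    image = _require_rgb(image)
    if not mask.mask.any():
        warnings.warn("empty tissue mask: returning image unchanged")
        return image.copy()
    src = estimate_template([image], [mask], min_pixels=1)
    lab = rgb_to_lab(image[mask.mask])
    z = (lab - src.means) / src.sds
    out_lab = z * target.sds + target.means
    out = image.astype(np.uint8).copy()
    out[mask.mask] = np.rint(lab_to_rgb(out_lab)).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# Class balancing by dihedral augmentation
# ---------------------------------------------------------------------------

def dihedral_transform(pixels: np.ndarray, index: int) -> np.ndarray:
    """Apply one of the 8 dihedral-group transforms (0 = identity).

    Indices 0–3 rotate by 90° multiples; 4–7 flip left-right then rotate.
    """
    if not 0 <= index < 8:
        raise ValueError("dihedral index must be in 0..7")
    out = pixels[:, ::-1] if index >= 4 else pixels
    return np.ascontiguousarray(np.rot90(out, k=index % 4))


def augment_balance(
    tiles_by_class: Dict[str, List[Tile]],
    seed: int,
) -> Dict[str, List[Tile]]:
    """Upsample minority classes to the majority count with dihedral transforms.

    Augmented tiles are sampled as (source tile, non-identity transform)
    pairs without replacement; only once every one of the 8 transforms of
    every tile has been used does sampling repeat.
    """
    for label, tiles in tiles_by_class.items():
        if len(tiles) == 0:
            raise ValueError(f"class {label!r} has no tiles to augment from")
    rng = np.random.default_rng(seed)
    majority = max(len(t) for t in tiles_by_class.values())
    out: Dict[str, List[Tile]] = {}
    for label in tiles_by_class:
        tiles = list(tiles_by_class[label])
        deficit = majority - len(tiles)
        # fresh (tile, transform) pairs: transforms 1..7 of each original
        pairs = [(i, t) for i in range(len(tiles)) for t in range(1, 8)]
        order = rng.permutation(len(pairs))
        new: List[Tile] = []
        j = 0
        while len(new) < deficit:
            if j >= len(order):  # all 8 transforms of all tiles used: recycle
                order = rng.permutation(len(pairs))
                j = 0
            i, t = pairs[order[j]]
            src = tiles[i]
            new.append(
                Tile(
                    pixels=dihedral_transform(src.pixels, t),
                    slide_id=src.slide_id,
                    grid_row=src.grid_row,
                    grid_col=src.grid_col,
                    coverage=src.coverage,
                    label=src.label,
                )
            )
            j += 1
        out[label] = tiles + new
    return out
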