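"""Per-slide "pathological signatures": the features the LASSO-Cox consumes.

Each slide is summarized by a fixed, ordered catalogue of 138 named
scalars:

* 6   class area proportions over tissue tiles ("prop_<class>");
* 126 per-class blocks: the mean of 21 tile-level features over that
  class's top-K highest-probability tiles ("<class>_<feature>");
* 6   presence flags ("present_<class>"), 0 when a class is absent from
  the slide (its block is then zero-imputed).

The 21 tile features are per-channel mean/sd in RGB and lαβ (12), five
angle-averaged gray-level co-occurrence statistics (contrast, homogeneity,
energy, correlation, entropy; 32 gray levels, distance 1), and four
nuclei-proxy statistics from Otsu-thresholded dark blobs (count density
per 10^4 px², mean area, area fraction, mean eccentricity).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import threshold_otsu

from .constants import CLASS_LABELS
from .preprocess import rgb_to_lab
from .slidemap import ClassificationMap, TopTiles, truth_map, top_k_tiles

__all__ = [
    "CATALOGUE_VERSION",
    "TILE_FEATURE_NAMES",
    "SignatureVector",
    "tile_features",
    "tile_feature_matrix",
    "slide_signature",
    "catalogue_names",
    "image_tile_accessor",
    "cohort_signatures",
]

CATALOGUE_VERSION = "hs-catalogue-1"

_GLCM_LEVELS = 32
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

TILE_FEATURE_NAMES: tuple = (
    "mean_R", "mean_G", "mean_B", "sd_R", "sd_G", "sd_B",
    "mean_l", "mean_alpha", "mean_beta", "sd_l", "sd_alpha", "sd_beta",
    "glcm_contrast", "glcm_homogeneity", "glcm_energy",
    "glcm_correlation", "glcm_entropy",
    "blob_density", "blob_mean_area", "blob_area_fraction", "blob_eccentricity",
)


def catalogue_names() -> List[str]:
    """The fixed 138-name signature catalogue, in order."""
    names = [f"prop_{c}" for c in CLASS_LABELS]
    for c in CLASS_LABELS:
        names.extend(f"{c}_{f}" for f in TILE_FEATURE_NAMES)
    names.extend(f"present_{c}" for c in CLASS_LABELS)
    return names


def tile_features(pixels: np.ndarray) -> "OrderedDict[str, float]":
    """Deterministic 21-feature summary of one RGB tile."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("tile_features expects an RGB tile of shape (H, W, 3)")
    out: "OrderedDict[str, float]" = OrderedDict()
    flat = pixels.reshape(-1, 3).astype(float)
    for i, ch in enumerate("RGB"):
        out[f"mean_{ch}"] = float(flat[:, i].mean())
    for i, ch in enumerate("RGB"):
        out[f"sd_{ch}"] = float(flat[:, i].std())
    lab = rgb_to_lab(flat)
    for i, ch in enumerate(("l", "alpha", "beta")):
        out[f"mean_{ch}"] = float(lab[:, i].mean())
    for i, ch in enumerate(("l", "alpha", "beta")):
        out[f"sd_{ch}"] = float(lab[:, i].std())

    gray = rgb2gray(pixels)  # in [0, 1]
    q = np.minimum((gray * _GLCM_LEVELS).astype(np.uint8), _GLCM_LEVELS - 1)
    glcm = graycomatrix(q, distances=[1], angles=list(_GLCM_ANGLES),
                        levels=_GLCM_LEVELS, symmetric=True, normed=True)
    for prop in ("contrast", "homogeneity", "energy", "correlation"):
        out[f"glcm_{prop}"] = float(graycoprops(glcm, prop).mean())
    p = glcm[:, :, 0, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(p * np.log2(p, where=p > 0, out=np.zeros_like(p))).sum(axis=(0, 1))
    out["glcm_entropy"] = float(ent.mean())

    gray255 = gray * 255.0
    h, w = gray.shape
    if float(gray255.max() - gray255.min()) < 1e-9:
        blobs = (0.0, 0.0, 0.0, 0.0)
    else:
        dark = gray255 < threshold_otsu(gray255)
        lab_img, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            blobs = (0.0, 0.0, 0.0, 0.0)
        else:
            blobs = (
                n / (h * w) * 1e4,
                float(dark.sum() / n),
                float(dark.mean()),
                float(_mean_eccentricity(lab_img, n)),
            )
    out["blob_density"], out["blob_mean_area"] = blobs[0], blobs[1]
    out["blob_area_fraction"], out["blob_eccentricity"] = blobs[2], blobs[3]
    return out


def _mean_eccentricity(lab_img: np.ndarray, n: int) -> float:
    """Mean ellipse eccentricity over labeled regions, via inertia tensors.

    Vectorized equivalent of skimage ``regionprops`` eccentricity: the
    second central moments of each region give the inertia-tensor
    eigenvalues λ1 ≥ λ2, and ecc = sqrt(1 − λ2/λ1) (0 for single pixels).
    """
    ys, xs = np.nonzero(lab_img)
    lbl = lab_img[ys, xs] - 1
    cnt = np.bincount(lbl, minlength=n).astype(float)
    ys = ys.astype(float)
    xs = xs.astype(float)
    cy = np.bincount(lbl, ys, minlength=n) / cnt
    cx = np.bincount(lbl, xs, minlength=n) / cnt
    mu20 = np.bincount(lbl, ys * ys, minlength=n) / cnt - cy**2
    mu02 = np.bincount(lbl, xs * xs, minlength=n) / cnt - cx**2
    mu11 = np.bincount(lbl, ys * xs, minlength=n) / cnt - cy * cx
    half_trace = 0.5 * (mu20 + mu02)
    delta = np.sqrt((0.5 * (mu20 - mu02)) ** 2 + mu11**2)
    l1 = half_trace + delta
    l2 = half_trace - delta
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc = np.where(l1 > 0, np.sqrt(np.clip(1.0 - l2 / np.maximum(l1, 1e-300), 0.0, 1.0)), 0.0)
    return float(ecc.mean())


def tile_feature_matrix(tiles: Sequence) -> np.ndarray:
    """Stack :func:`tile_features` over tiles (accepts Tile or array)."""
    rows = []
    for t in tiles:
        pixels = t.pixels if hasattr(t, "pixels") else t
        rows.append(list(tile_features(pixels).values()))
    return np.asarray(rows, dtype=float)


@dataclass
class SignatureVector:
    """One slide's ordered, named signature values."""

    slide_id: Optional[str]
    values: "OrderedDict[str, float]"
    catalogue_version: str = CATALOGUE_VERSION

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.slide_id)


def image_tile_accessor(image: np.ndarray, side: int) -> Callable[[int, int], np.ndarray]:
    """Tile accessor mapping grid coordinates to pixel blocks of a slide."""

    def get(r: int, c: int) -> np.ndarray:
        return image[r * side : (r + 1) * side, c * side : (c + 1) * side]

    return get


def slide_signature(
    cmap: ClassificationMap,
    topk: Dict[str, TopTiles],
    tile_accessor: Callable[[int, int], np.ndarray],
    slide_id: Optional[str] = None,
) -> SignatureVector:
    """Concatenate class proportions, per-class top-K feature means, flags.

    Blocks of classes absent from the slide are zero-imputed with their
    presence flag set to 0, so cohorts keep one fixed-length vector per
    slide regardless of which tissues each slide contains.
    """
    slide_id = slide_id or cmap.slide_id
    if cmap.slide_id is not None and slide_id != cmap.slide_id:
        raise ValueError(
            f"slide mismatch: map is for {cmap.slide_id!r}, requested {slide_id!r}"
        )
    values: "OrderedDict[str, float]" = OrderedDict()
    props = cmap.class_proportions()
    for c, label in enumerate(CLASS_LABELS):
        values[f"prop_{label}"] = float(props[c])
    flags = {}
    for label in CLASS_LABELS:
        # sorted by grid position so the mean is independent of ranking order
        entries = sorted(topk[label].entries, key=lambda e: e[0])
        if entries:
            feats = np.array(
                [list(tile_features(tile_accessor(r, c)).values()) for (r, c), _ in entries]
            )
            mean_feats = feats.mean(axis=0)
            flags[label] = 1.0
        else:
            mean_feats = np.zeros(len(TILE_FEATURE_NAMES))
            flags[label] = 0.0
        for name, v in zip(TILE_FEATURE_NAMES, mean_feats):
            values[f"{label}_{name}"] = float(v)
    for label in CLASS_LABELS:
        values[f"present_{label}"] = flags[label]
    return SignatureVector(slide_id=slide_id, values=values)


def cohort_signatures(
    slides: Sequence,
    tile_side: int = 96,
    min_coverage: float = 0.5,
    k: int = 10,
    model=None,
    smooth: bool = True,
) -> pd.DataFrame:
    """Signature matrix for a list of synthetic slides (one row per slide).

    With ``model=None`` the classification maps come from the slides'
    ground-truth masks (tile purity as probability); otherwise the trained
    classifier is run on every tile.
    """
    from .preprocess import tissue_mask
    from .slidemap import build_map, smooth_map

    rows = []
    index = []
    for i, slide in enumerate(slides):
        sid = getattr(slide, "slide_id", None) or f"S{i:04d}"
        if model is None:
            cmap = truth_map(slide.truth_mask, tile_side, min_coverage, slide_id=sid)
        else:
            cmap = build_map(
                slide.image, tissue_mask(slide.image), model,
                side=tile_side, min_coverage=min_coverage, slide_id=sid,
            )
            if smooth:
                cmap = smooth_map(cmap)
        tk = top_k_tiles(cmap, k=k)
        sig = slide_signature(cmap, tk, image_tile_accessor(slide.image, tile_side), slide_id=sid)
        rows.append(sig.values)
        index.append(sid)
    return pd.DataFrame(rows, index=index, columns=catalogue_names())
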