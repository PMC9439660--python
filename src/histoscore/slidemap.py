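"""Per-slide classification maps: assembly, morphological smoothing, top-K.

A classification map is the tile-resolution summary of one slide: a grid
with one cell per tile, holding the predicted class label and the six-class
probability vector.  Raw maps are noisy at region boundaries, so a
label-grid morphology pass — 3×3 majority vote followed by absorption of
tiny connected components — mimics the morphological post-processing used
on real slides.  The ten highest-probability tiles per class ("top-K") are
the tiles from which per-class signatures are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .constants import BACKGROUND_CODE, CLASS_LABELS, N_CLASSES
from .preprocess import TissueMask, tile_grid

__all__ = [
    "ClassificationMap",
    "TopTiles",
    "build_map",
    "truth_map",
    "smooth_map",
    "top_k_tiles",
]


@dataclass
class ClassificationMap:
    """Tile-label grid plus matching probability grid for one slide.

    ``labels`` holds class codes 0..5 and ``BACKGROUND_CODE`` for excluded
    cells; ``probs`` is (rows, cols, 6) with NaN rows for background cells.
    """

    labels: np.ndarray
    probs: np.ndarray
    slide_id: Optional[str] = None
    tile_side: int = 96

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != self.labels.shape + (N_CLASSES,):
            raise ValueError("probs grid must be labels grid × 6")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    def tissue_cells(self) -> np.ndarray:
        return self.labels != BACKGROUND_CODE

    def class_proportions(self) -> np.ndarray:
        """Label fractions over tissue cells (zeros if no tissue)."""
        tissue = self.tissue_cells()
        n = int(tissue.sum())
        if n == 0:
            return np.zeros(N_CLASSES)
        return np.bincount(self.labels[tissue], minlength=N_CLASSES) / n


def build_map(
    image: np.ndarray,
    mask: TissueMask,
    model,
    side: Optional[int] = None,
    min_coverage: float = 0.5,
    slide_id: Optional[str] = None,
) -> ClassificationMap:
    """Run the tile classifier over a slide's tile grid.

    ``model`` must expose ``class_labels`` (the fixed six-class order) and
    ``predict_proba_pixels`` on a stack of tiles.
    """
    if tuple(model.class_labels) != CLASS_LABELS:
        raise ValueError(
            f"model class order {tuple(model.class_labels)} does not match {CLASS_LABELS}"
        )
    side = side or model.tile_side
    h, w = image.shape[:2]
    rows, cols = h // side, w // side
    labels = np.full((rows, cols), BACKGROUND_CODE, dtype=np.int8)
    probs = np.full((rows, cols, N_CLASSES), np.nan)
    tiles = tile_grid(image, mask, side=side, min_coverage=min_coverage, slide_id=slide_id)
    if tiles:
        p = model.predict_proba_pixels(np.stack([t.pixels for t in tiles]))
        for t, pv in zip(tiles, p):
            labels[t.grid_row, t.grid_col] = int(np.argmax(pv))
            probs[t.grid_row, t.grid_col] = pv
    return ClassificationMap(labels, probs, slide_id=slide_id, tile_side=side)


def truth_map(
    truth_mask: np.ndarray,
    side: int,
    min_coverage: float = 0.5,
    slide_id: Optional[str] = None,
) -> ClassificationMap:
    """Ground-truth classification map from a per-pixel truth mask.

    Each cell's probability vector is the within-tile class purity (class
    pixel fractions over tissue pixels), the label its argmax; cells whose
    tissue coverage falls below ``min_coverage`` become background.
    """
    h, w = truth_mask.shape
    rows, cols = h // side, w // side
    labels = np.full((rows, cols), BACKGROUND_CODE, dtype=np.int8)
    probs = np.full((rows, cols, N_CLASSES), np.nan)
    for r in range(rows):
        for c in range(cols):
            block = truth_mask[r * side : (r + 1) * side, c * side : (c + 1) * side]
            tissue = block >= 0
            if tissue.mean() < min_coverage:
                continue
            counts = np.bincount(block[tissue].astype(int), minlength=N_CLASSES)
            p = counts / counts.sum()
            labels[r, c] = int(np.argmax(p))
            probs[r, c] = p
    return ClassificationMap(labels, probs, slide_id=slide_id, tile_side=side)


def smooth_map(
    cmap: ClassificationMap,
    window: int = 3,
    min_region: int = 2,
) -> ClassificationMap:
    """Label-grid morphology: majority vote, then small-component absorption.

    Each tissue cell takes the majority label of its ``window``×``window``
    neighborhood (background cells do not vote; ties keep the original
    label).  Connected components (4-connectivity) smaller than
    ``min_region`` cells are then absorbed into their largest neighboring
    component.  Probabilities are left untouched.
    """
    labels = cmap.labels.copy()
    rows, cols = labels.shape
    half = window // 2
    voted = labels.copy()
    for r in range(rows):
        for c in range(cols):
            if labels[r, c] == BACKGROUND_CODE:
                continue
            win = labels[max(0, r - half) : r + half + 1, max(0, c - half) : c + half + 1]
            votes = win[win != BACKGROUND_CODE]
            counts = np.bincount(votes, minlength=N_CLASSES)
            best = counts.max()
            winners = np.flatnonzero(counts == best)
            if len(winners) == 1:
                voted[r, c] = winners[0]
            # tie → retain original label
    labels = voted

    # absorb small components into their largest neighbor; order and ties
    # are canonical (by initial size, then first cell in row-major order)
    # so the result is independent of component enumeration
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    comp_id = np.full(labels.shape, -1, dtype=int)
    comp_label: List[int] = []
    comp_size: List[int] = []
    comp_first: List[Tuple[int, int]] = []  # smallest (row, col) of each component
    next_id = 0
    for k in range(N_CLASSES):
        lab, n = ndimage.label(labels == k, structure=structure)
        for j in range(1, n + 1):
            cells = np.argwhere(lab == j)
            comp_id[lab == j] = next_id
            comp_label.append(k)
            comp_size.append(len(cells))
            comp_first.append((int(cells[0, 0]), int(cells[0, 1])))
            next_id += 1
    order = sorted(range(next_id), key=lambda i: (comp_size[i], comp_first[i]))
    for cid in order:
        if comp_size[cid] >= min_region:
            continue
        cells = np.argwhere(comp_id == cid)
        neigh: Dict[int, int] = {}
        for r, c in cells:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    other = comp_id[rr, cc]
                    if other >= 0 and other != cid:
                        neigh[other] = comp_size[other]
        if not neigh:
            continue
        target = min(neigh, key=lambda i: (-neigh[i], comp_first[i]))
        for r, c in cells:
            labels[r, c] = comp_label[target]
            comp_id[r, c] = target
        comp_size[target] += len(cells)
        comp_size[cid] = 0
    return ClassificationMap(labels, cmap.probs.copy(), slide_id=cmap.slide_id, tile_side=cmap.tile_side)


@dataclass
class TopTiles:
    """Top-K tiles of one class: ((grid_row, grid_col), probability) pairs."""

    entries: List[Tuple[Tuple[int, int], float]]
    truncated: bool  # True when fewer than k tiles carried the class


def top_k_tiles(cmap: ClassificationMap, k: int = 10) -> Dict[str, TopTiles]:
    """The k tiles with the highest class probability, per class.

    Selection is restricted to tiles whose (smoothed) label equals the
    class; ranking is by that class's probability, descending, with ties
    broken by row-major grid order.
    """
    out: Dict[str, TopTiles] = {}
    for code, label in enumerate(CLASS_LABELS):
        cells = np.argwhere(cmap.labels == code)
        scored = [
            ((int(r), int(c)), float(cmap.probs[r, c, code])) for r, c in cells
        ]
        scored.sort(key=lambda e: (-e[1], e[0][0], e[0][1]))
        out[label] = TopTiles(entries=scored[:k], truncated=len(scored) < k)
    return out
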