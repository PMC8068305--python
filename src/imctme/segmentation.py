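"""Watershed cell segmentation, weak-label tile export, and Dice evaluation.

The watershed runs on the smoothed nuclear projection: foreground by Otsu
threshold, seeds at local intensity maxima separated by a minimum distance,
then watershed on the inverted intensity restricted to the foreground.

Tiling cuts a mask + image into a grid of ~250 px tiles and serializes the
clipped instances as COCO-style annotations — a weak training set for an
external instance-segmentation model (the network itself is out of scope;
externally produced masks re-enter through the LabelMask reader).

Evaluation matches every cell of an evaluated mask to its maximum-overlap
cell in a reference mask and scores the Sorensen-Dice coefficient
``2|x & y| / (|x| + |y|)``; segmentations are compared across samples by a
paired t test on per-sample Dice means (and, separately, sds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .stacks import LabelMask

__all__ = [
    "watershed_segment",
    "export_weak_labels",
    "tileset_to_coco",
    "dice_per_cell",
    "compare_segmentations",
    "Tile",
    "TileSet",
    "DiceReport",
]


def watershed_segment(
    img: np.ndarray,
    min_seed_distance: int = 5,
    foreground_threshold: float | None = None,
) -> LabelMask:
    """Seeded watershed on a smoothed nuclear image.

    ``foreground_threshold`` defaults to Otsu on the image; pixels below it
    are background.  Seeds are local maxima at least ``min_seed_distance``
    pixels apart.  A blank image yields an empty mask.
    """
    img = np.asarray(img, dtype=float)
    if img.max() == img.min():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), provenance="watershed")
    thr = threshold_otsu(img) if foreground_threshold is None else foreground_threshold
    foreground = img > thr
    if not foreground.any():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), provenance="watershed")
    coords = peak_local_max(
        img, min_distance=min_seed_distance, labels=foreground, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-img, markers=markers, mask=foreground)
    return LabelMask(labels.astype(np.int32), provenance="watershed")


@dataclass
class Tile:
    """One grid tile with its clipped instance masks."""

    row: int
    col: int
    image: np.ndarray
    instance_masks: list[np.ndarray] = field(default_factory=list)
    boxes: list[tuple[int, int, int, int]] = field(default_factory=list)  # x, y, w, h
    source_labels: list[int] = field(default_factory=list)


@dataclass
class TileSet:
    tiles: list[Tile]
    grid: tuple[int, int]

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def n_instances(self) -> int:
        return sum(len(t.instance_masks) for t in self.tiles)


def export_weak_labels(
    mask: LabelMask,
    img: np.ndarray,
    grid: tuple[int, int] = (4, 4),
    min_instance_px: int = 10,
) -> TileSet:
    """Cut a mask + image into grid tiles with per-instance annotations.

    Instances are clipped at tile borders; clipped fragments smaller than
    ``min_instance_px`` pixels are dropped (degenerate training boxes).
    Remainder rows/columns are folded into the last tile so the grid always
    yields exactly ``rows * cols`` tiles.
    """
    rows, cols = grid
    if rows <= 0 or cols <= 0:
        raise ValueError("grid must have positive rows and cols")
    if mask.shape != img.shape:
        raise ValueError("mask and image shapes differ")
    h, w = mask.shape
    y_edges = [int(round(i * h / rows)) for i in range(rows + 1)]
    x_edges = [int(round(j * w / cols)) for j in range(cols + 1)]
    tiles = []
    for i in range(rows):
        for j in range(cols):
            sl = np.s_[y_edges[i] : y_edges[i + 1], x_edges[j] : x_edges[j + 1]]
            sub = mask.labels[sl]
            tile = Tile(row=i, col=j, image=img[sl].copy())
            for lab in np.unique(sub):
                if lab == 0:
                    continue
                inst = sub == lab
                if inst.sum() < min_instance_px:
                    continue
                ys, xs = np.nonzero(inst)
                x0, y0 = xs.min(), ys.min()
                tile.instance_masks.append(inst)
                tile.boxes.append((int(x0), int(y0), int(xs.max() - x0 + 1), int(ys.max() - y0 + 1)))
                tile.source_labels.append(int(lab))
            tiles.append(tile)
    return TileSet(tiles=tiles, grid=grid)


def tileset_to_coco(tileset: TileSet) -> dict:
    """Serialize a TileSet as a COCO-style instance-annotation dict
    (single category ``cell``, masks as polygon-free RLE counts)."""
    images, annotations = [], []
    ann_id = 1
    for idx, tile in enumerate(tileset.tiles):
        h, w = tile.image.shape
        images.append({"id": idx, "height": int(h), "width": int(w),
                       "tile_row": tile.row, "tile_col": tile.col})
        for inst, box in zip(tile.instance_masks, tile.boxes):
            flat = inst.ravel(order="F")
            # uncompressed RLE: run lengths alternating 0s/1s, column-major
            changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
            runs = np.diff(np.concatenate([[0], changes + 1, [flat.size]]))
            counts = runs.tolist() if not flat[0] else [0] + runs.tolist()
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": idx,
                    "category_id": 1,
                    "bbox": list(box),
                    "area": int(inst.sum()),
                    "iscrowd": 0,
                    "segmentation": {"size": [int(h), int(w)], "counts": counts},
                }
            )
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "cell"}],
    }


def dice_per_cell(eval_mask: LabelMask, ref_mask: LabelMask) -> dict[int, float]:
    """Sorensen-Dice of each eval cell against its maximum-overlap ref cell.

    For eval cell x the match is the ref cell y maximizing ``|x & y|`` (ties
    broken by smallest ref label); Dice = ``2|x & y| / (|x| + |y|)``.  Eval
    cells overlapping only background score 0.  Matching is independent per
    eval cell — one ref cell may be the best match of several.
    """
    if eval_mask.shape != ref_mask.shape:
        raise ValueError("masks must have the same shape")
    ev = eval_mask.labels.ravel()
    rf = ref_mask.labels.ravel()
    eval_sizes = np.bincount(ev)
    ref_sizes = np.bincount(rf)
    # joint histogram over (eval, ref) label pairs
    n_ref = rf.max() + 1
    pair_codes = ev.astype(np.int64) * n_ref + rf
    counts = np.bincount(pair_codes)
    nz = np.flatnonzero(counts)
    ev_lab = nz // n_ref
    rf_lab = nz % n_ref
    overlap = counts[nz]

    result: dict[int, float] = {int(lab): 0.0 for lab in np.unique(ev) if lab > 0}
    keep = (ev_lab > 0) & (rf_lab > 0)
    order = np.lexsort((rf_lab[keep], -overlap[keep], ev_lab[keep]))
    ev_k, rf_k, ov_k = ev_lab[keep][order], rf_lab[keep][order], overlap[keep][order]
    seen: set[int] = set()
    for e, r, o in zip(ev_k, rf_k, ov_k):
        if e in seen:
            continue
        seen.add(int(e))
        result[int(e)] = 2.0 * o / (eval_sizes[e] + ref_sizes[r])
    return result


@dataclass
class DiceReport:
    """Per-sample Dice summaries of two segmentation methods and the paired
    t tests on their per-sample means and standard deviations."""

    mean_a: np.ndarray
    mean_b: np.ndarray
    sd_a: np.ndarray
    sd_b: np.ndarray
    t_mean: float | None
    p_mean: float | None
    t_sd: float | None
    p_sd: float | None
    degenerate_mean: bool = False
    degenerate_sd: bool = False


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float | None, float | None, bool]:
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        return None, None, True
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p), False


def compare_segmentations(
    per_sample_dice_a: list[np.ndarray], per_sample_dice_b: list[np.ndarray]
) -> DiceReport:
    """Paired comparison of two methods' per-sample Dice distributions.

    Zero-variance paired differences (e.g. identical methods or a constant
    shift) are flagged degenerate rather than assigned a p-value.
    """
    if len(per_sample_dice_a) != len(per_sample_dice_b):
        raise ValueError("both methods must cover the same samples")
    if len(per_sample_dice_a) < 2:
        raise ValueError("need at least 2 samples for a paired test")
    mean_a = np.array([np.mean(d) for d in per_sample_dice_a])
    mean_b = np.array([np.mean(d) for d in per_sample_dice_b])
    sd_a = np.array([np.std(d) for d in per_sample_dice_a])
    sd_b = np.array([np.std(d) for d in per_sample_dice_b])
    t_mean, p_mean, degen_mean = _paired_t(mean_a, mean_b)
    t_sd, p_sd, degen_sd = _paired_t(sd_a, sd_b)
    return DiceReport(
        mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b,
        t_mean=t_mean, p_mean=p_mean, t_sd=t_sd, p_sd=p_sd,
        degenerate_mean=degen_mean, degenerate_sd=degen_sd,
    )
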