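"""Classifier input preparation, dataset splitting and augmentation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .. import PHENOTYPES

SOMA_LEVEL = 1.0
PROCESS_LEVEL = 0.5


@dataclass
class LabeledCellImage:
    """A square single-channel classifier input with its phenotype label."""

    pixels: np.ndarray
    label: str  # phenotype name or "unknown"
    provenance: str = ""


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")


def _fit_square(cell_mask: np.ndarray, soma_mask: np.ndarray, side: int) -> np.ndarray:
    """Tri-level raster: crop to content, pad to square, rescale to side."""
    ys, xs = np.nonzero(cell_mask)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    cell = cell_mask[y0:y1, x0:x1]
    soma = soma_mask[y0:y1, x0:x1]
    img = np.where(soma, SOMA_LEVEL, np.where(cell, PROCESS_LEVEL, 0.0))
    h, w = img.shape
    s = max(h, w)
    sq = np.zeros((s, s), dtype=np.float64)
    oy, ox = (s - h) // 2, (s - w) // 2
    sq[oy : oy + h, ox : ox + w] = img
    out = resize(sq, (side, side), order=0, anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def render_trilevel(cell_mask: np.ndarray, soma_mask: np.ndarray, side: int = 128) -> np.ndarray:
    """Render masks as the tri-level convention (soma white, processes gray)."""
    if not np.any(cell_mask):
        raise ValueError("empty cell mask")
    return _fit_square(np.asarray(cell_mask, bool), np.asarray(soma_mask, bool), side)


def prepare_input(cell, mode: str = "mask", side: int = 128) -> LabeledCellImage:
    """Crop, square-pad (aspect preserved) and rescale one extracted cell.

    ``mode="mask"`` renders background 0 / processes 0.5 / soma 1; ``"gray"``
    rescales the grayscale crop (outside-cell pixels zeroed) to [0, 1].
    """
    if not np.any(cell.cell_mask):
        raise ValueError("empty cell")
    if mode == "mask":
        px = _fit_square(cell.cell_mask, cell.soma_mask, side)
    elif mode == "gray":
        ys, xs = np.nonzero(cell.cell_mask)
        y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
        img = np.where(cell.cell_mask, cell.gray_crop, 0.0)[y0:y1, x0:x1]
        h, w = img.shape
        s = max(h, w)
        sq = np.zeros((s, s))
        sq[(s - h) // 2 : (s - h) // 2 + h, (s - w) // 2 : (s - w) // 2 + w] = img
        px = resize(sq, (side, side), order=1, anti_aliasing=True, preserve_range=True)
        px = np.clip(px, 0, 1).astype(np.float32)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return LabeledCellImage(pixels=px, label="unknown", provenance=f"cell/{cell.cell_id}")


def split_dataset(
    data: list[LabeledCellImage], spec: SplitSpec
) -> tuple[list[LabeledCellImage], list[LabeledCellImage], list[LabeledCellImage]]:
    """Deterministic stratified train/val/test split.

    Per class, counts are floored from the fractions and remainders go to
    the training partition, so 1,000 cells at 70/15/15 yield 700/150/150.
    """
    rng = np.random.default_rng(spec.seed)
    groups: dict[str, list[int]] = {}
    for i, item in enumerate(data):
        groups.setdefault(item.label if spec.stratified else "all", []).append(i)
    train_idx, val_idx, test_idx = [], [], []
    f_train, f_val, f_test = spec.fractions
    for label in sorted(groups):
        idx = np.array(groups[label])
        rng.shuffle(idx)
        n = len(idx)
        n_val = int(np.floor(f_val * n))
        n_test = int(np.floor(f_test * n))
        n_train = n - n_val - n_test
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train : n_train + n_val])
        test_idx.extend(idx[n_train + n_val :])
    pick = lambda ix: [data[i] for i in sorted(ix)]
    return pick(train_idx), pick(val_idx), pick(test_idx)


#: The 8 exact dihedral transforms (4 rotations x optional reflection).
def dihedral_transforms(img: np.ndarray) -> list[np.ndarray]:
    out = []
    for k in range(4):
        r = np.rot90(img, k)
        out.append(r)
        out.append(np.fliplr(r))
    return out


def augment(train_set: list[LabeledCellImage], n_transforms: int = 8) -> list[LabeledCellImage]:
    """Static dihedral augmentation: each image becomes its 8 variants."""
    out = []
    for item in train_set:
        for t, img in enumerate(dihedral_transforms(item.pixels)[:n_transforms]):
            out.append(
                LabeledCellImage(
                    pixels=np.ascontiguousarray(img),
                    label=item.label,
                    provenance=f"{item.provenance}/d{t}",
                )
            )
    return out


def to_arrays(items: list[LabeledCellImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack into ``(N, H, W, 1)`` float32 inputs and integer class labels."""
    x = np.stack([it.pixels for it in items]).astype(np.float32)[..., None]
    y = np.array([PHENOTYPES.index(it.label) for it in items], dtype=np.int64)
    return x, y
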