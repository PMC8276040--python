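"""Preprocessing and hybrid soma/process segmentation of tissue images.

Stage order (each stage is an exported function, `segment_image` chains them):

1. ``preprocess``            — CLAHE, then grayscale inversion (cells bright).
2. ``detect_somata``         — top-hat + Gaussian, Otsu, size filter, closing.
3. ``detect_processes``      — local adaptive segmentation of the image and of
   its ridge-filtered version, united.
4. ``merge_and_reconstruct`` — union of masks, endpoint-to-soma bridging,
   orphan clearing, border-cell removal.
5. ``separate_cells``        — parallel flood fill from soma regions.
6. ``extract_cells``         — per-label crops with soma/process split and
   process skeleton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage import exposure, feature, filters, morphology

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def disk_footprint(radius: float) -> np.ndarray:
    """All pixels whose center lies within ``radius`` of the origin.

    Handles non-integer radii (the closing step uses 7.5 px).
    """
    r = int(math.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= radius * radius


@dataclass
class SegmentationConfig:
    clahe_clip_limit: float = 0.005
    clahe_tile_grid: int = 8
    tophat_radius_px: float = 45.0
    gaussian_sigma_px: float = 5.0
    soma_min_area_px: int = 1500
    closing_radius_px: float = 7.5
    adaptive_radius_px: float = 5.0
    adaptive_offset: float = 0.10
    ridge_sigma_px: float = 5.0
    bridge_max_dist_px: float = 50.0
    bridge_line_width_px: float = 3.0
    bridge_min_component_px: int = 15
    pixel_size_um: float = 0.122

    def __post_init__(self) -> None:
        for name in ("tophat_radius_px", "gaussian_sigma_px", "closing_radius_px",
                     "adaptive_radius_px", "ridge_sigma_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.soma_min_area_px < 1:
            raise ValueError("soma_min_area_px must be >= 1")
        if self.bridge_max_dist_px < 0:
            raise ValueError("bridge_max_dist_px must be >= 0")


@dataclass
class CellExtract:
    """One segmented cell, crop-local masks plus full-image bookkeeping."""

    cell_id: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    cell_mask: np.ndarray
    soma_mask: np.ndarray
    process_mask: np.ndarray
    skeleton: np.ndarray
    gray_crop: np.ndarray
    soma_centroid: tuple[int, int]  # full-image (row, col)


def _as_gray(image: np.ndarray) -> np.ndarray:
    """Coerce input to a float [0,1] single-channel image."""
    img = np.asarray(image)
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        rgb = img[..., :3].astype(np.float64)
        img = rgb @ np.array([0.2125, 0.7154, 0.0721])
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    img = img.astype(np.float64)
    if img.max() > 1.0:
        img = img / (255.0 if img.max() <= 255 else 65535.0)
    return np.clip(img, 0.0, 1.0)


def preprocess(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, then inversion.

    Dark cells on a light background become bright on dark; a constant image
    maps to its constant inverse (equalization is skipped when there is no
    contrast to redistribute).
    """
    img = _as_gray(image)
    if img.max() > img.min():
        ks = max(8, min(img.shape) // cfg.clahe_tile_grid)
        img = exposure.equalize_adapthist(img, kernel_size=ks, clip_limit=cfg.clahe_clip_limit)
    return 1.0 - img


def detect_somata(inv: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Soma mask: top-hat + Gaussian enhancement, Otsu, size filter, closing.

    Components smaller than ``soma_min_area_px`` (strictly) are removed
    before the morphological closing, so every surviving component had at
    least the threshold pixel count.
    """
    # decomposed (approximate) disc keeps the large-radius top-hat tractable
    foot = morphology.disk(int(round(cfg.tophat_radius_px)), decomposition="sequence")
    enhanced = morphology.white_tophat(inv, footprint=foot)
    enhanced = ndi.gaussian_filter(enhanced, cfg.gaussian_sigma_px)
    if enhanced.max() <= enhanced.min():
        return np.zeros(inv.shape, dtype=bool)
    mask = enhanced > filters.threshold_otsu(enhanced)
    mask = size_filter(mask, cfg.soma_min_area_px)
    mask = ndi.binary_closing(
        mask, structure=disk_footprint(cfg.closing_radius_px), border_value=0
    )
    return mask


def size_filter(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    """Drop 8-connected components with pixel count < ``min_area_px``.

    A component of exactly ``min_area_px`` pixels survives.
    """
    lab, n = ndi.label(np.asarray(mask, bool), structure=_EIGHT)
    if n == 0:
        return np.zeros(mask.shape, dtype=bool)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[lab]


def adaptive_segment(image: np.ndarray, radius_px: float, offset: float = 0.0) -> np.ndarray:
    """Threshold each pixel against the mean of its disc neighborhood."""
    foot = disk_footprint(radius_px).astype(np.float64)
    local_mean = ndi.convolve(image, foot / foot.sum(), mode="reflect")
    return image > local_mean + offset


def ridge_filter(image: np.ndarray, sigma: float) -> np.ndarray:
    """Positive part of the negated smallest Hessian eigenvalue (bright ridges)."""
    H = feature.hessian_matrix(
        image, sigma=sigma, order="rc", use_gaussian_derivatives=True
    )
    eigvals = feature.hessian_matrix_eigvals(H)  # sorted decreasing
    ridge = np.maximum(0.0, -eigvals[-1])
    # curvature units are tiny; rescale so adaptive_offset is comparable
    # across the direct and ridge channels
    if ridge.max() > 0:
        ridge = ridge / ridge.max()
    return ridge


def detect_processes(inv: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Union of adaptively segmented image and its ridge-amplified version."""
    direct = adaptive_segment(inv, cfg.adaptive_radius_px, cfg.adaptive_offset)
    ridged = adaptive_segment(
        ridge_filter(inv, cfg.ridge_sigma_px), cfg.adaptive_radius_px, cfg.adaptive_offset
    )
    return direct | ridged


def _skeleton_endpoints(skel: np.ndarray) -> np.ndarray:
    """(n, 2) coordinates of skeleton pixels with <= 1 skeleton neighbor."""
    nb = ndi.convolve(skel.astype(np.uint8), np.ones((3, 3), dtype=np.uint8),
                      mode="constant") - skel.astype(np.uint8)
    pts = np.argwhere(skel & (nb <= 1))
    if pts.size == 0:
        pts = np.argwhere(skel)
    return pts


def merge_and_reconstruct(
    somata: np.ndarray, processes: np.ndarray, cfg: SegmentationConfig,
    stats: dict | None = None,
) -> np.ndarray:
    """Merge masks, bridge orphan processes to nearby somata, clean up.

    Components without a soma pixel are bridged from the skeleton endpoint
    nearest to any soma boundary pixel with a straight drawn line, provided
    the Euclidean gap is at most ``bridge_max_dist_px``; after bridging,
    remaining soma-less components and components touching the image border
    are deleted. Specks below ``bridge_min_component_px`` are never bridged.
    """
    if somata.shape != processes.shape:
        raise ValueError("mask shapes differ")
    merged = somata | processes
    soma_boundary = somata & ~ndi.binary_erosion(somata, structure=_EIGHT)
    bpts = np.argwhere(soma_boundary)
    n_bridged = 0
    if bpts.size:
        tree = cKDTree(bpts)
        lab, n = ndi.label(merged, structure=_EIGHT)
        has_soma = np.unique(lab[somata])
        orphan_ids = np.setdiff1d(np.arange(1, n + 1), has_soma)
        bridges = np.zeros_like(merged)
        slices = ndi.find_objects(lab)
        for oid in orphan_ids:
            sl = slices[oid - 1]
            comp = lab[sl] == oid
            if comp.sum() < cfg.bridge_min_component_px:
                continue
            skel = morphology.skeletonize(comp)
            eps = _skeleton_endpoints(skel)
            eps[:, 0] += sl[0].start
            eps[:, 1] += sl[1].start
            dists, idx = tree.query(eps)
            order = np.lexsort((eps[:, 1], eps[:, 0]))  # tie-break low (row, col)
            order = order[np.argsort(dists[order], kind="stable")]
            best = order[0]
            if dists[best] <= cfg.bridge_max_dist_px:
                target = bpts[idx[best]]
                rr, cc = skdraw.line(eps[best, 0], eps[best, 1], target[0], target[1])
                bridges[rr, cc] = True
                n_bridged += 1
        if n_bridged:
            bridges = ndi.binary_dilation(
                bridges, structure=disk_footprint(cfg.bridge_line_width_px / 2)
            )
            merged |= bridges
    # clear remaining orphans
    lab, n = ndi.label(merged, structure=_EIGHT)
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(lab[somata])] = True
    keep[0] = False
    n_orphans = int(n - keep.sum())
    merged = keep[lab]
    # remove border-touching cells
    lab, n = ndi.label(merged, structure=_EIGHT)
    border = np.zeros(lab.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    drop = np.unique(lab[border])
    n_border = int((drop > 0).sum())
    keep = np.ones(n + 1, dtype=bool)
    keep[drop] = False
    keep[0] = False
    if stats is not None:
        stats.update(bridged=n_bridged, orphans_cleared=n_orphans, border_removed=n_border)
    return keep[lab]


def separate_cells(mask: np.ndarray, somata: np.ndarray) -> np.ndarray:
    """Partition the mask into one label per soma by parallel flood fill.

    All soma regions grow simultaneously (synchronous 8-connected BFS,
    geodesic inside the mask); a pixel reached by two fronts in the same
    step takes the lower label id.
    """
    somata = somata & mask
    labels, n = ndi.label(somata, structure=_EIGHT)
    labels = labels.astype(np.int32)
    if n == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    INF = np.iinfo(np.int32).max
    work = np.where(labels > 0, labels, INF)
    work[~mask] = 0  # outside mask: never fillable
    work[mask & (labels == 0)] = INF
    shifts = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    while True:
        padded = np.pad(work, 1, constant_values=0)
        best = np.full(work.shape, INF, dtype=np.int32)
        for dy, dx in shifts:
            nb = padded[1 + dy : 1 + dy + work.shape[0], 1 + dx : 1 + dx + work.shape[1]]
            cand = np.where(nb > 0, nb, INF)
            best = np.minimum(best, cand)
        frontier = (work == INF) & (best < INF)
        if not frontier.any():
            break
        work[frontier] = best[frontier]
    out = np.where((work > 0) & (work < INF), work, 0).astype(np.int32)
    return out


def extract_cells(
    labels: np.ndarray, somata: np.ndarray, gray: np.ndarray
) -> list[CellExtract]:
    """Crop every labeled cell into a :class:`CellExtract`.

    The exported skeleton is the morphological thinning of the process mask
    (soma excluded); a label without soma pixels violates the pipeline
    contract and raises.
    """
    if not (labels.shape == somata.shape == gray.shape):
        raise ValueError("shape mismatch")
    extracts = []
    for sl, cid in zip(ndi.find_objects(labels), range(1, labels.max() + 1)):
        if sl is None:
            continue
        cell = labels[sl] == cid
        soma = cell & somata[sl]
        if not soma.any():
            raise ValueError(f"label {cid} contains no soma pixel")
        proc = cell & ~soma
        skel = morphology.skeletonize(proc) if proc.any() else np.zeros_like(proc)
        ys, xs = np.nonzero(soma)
        centroid = (
            int(round(ys.mean())) + sl[0].start,
            int(round(xs.mean())) + sl[1].start,
        )
        extracts.append(
            CellExtract(
                cell_id=cid,
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                cell_mask=cell,
                soma_mask=soma,
                process_mask=proc,
                skeleton=skel & cell,
                gray_crop=gray[sl].copy(),
                soma_centroid=centroid,
            )
        )
    return extracts


@dataclass
class SegmentationResult:
    labels: np.ndarray
    extracts: list[CellExtract]
    merged_mask: np.ndarray
    soma_mask: np.ndarray
    stats: dict = field(default_factory=dict)


def segment_image(image: np.ndarray, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Run the full stage chain on one image."""
    cfg = cfg or SegmentationConfig()
    inv = preprocess(image, cfg)
    somata = detect_somata(inv, cfg)
    stats = {"somata_found": int(ndi.label(somata, structure=_EIGHT)[1])}
    processes = detect_processes(inv, cfg)
    merged = merge_and_reconstruct(somata, processes, cfg, stats=stats)
    labels = separate_cells(merged, somata)
    extracts = extract_cells(labels, somata & merged, inv)
    stats["cells_extracted"] = len(extracts)
    return SegmentationResult(
        labels=labels, extracts=extracts, merged_mask=merged,
        soma_mask=somata & merged, stats=stats,
    )
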