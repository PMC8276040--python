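"""Per-cell morphological parameters and per-image metrics.

Eighteen parameters per cell: areas/perimeters of the cell, its convex hull
and its soma; solidity, convexity, circularity (cell and soma); skeleton
length, branch points, endpoints; number of processes; and four quantities
derived from Sholl analysis (branching index, critical radius, dendritic
maximum, Schoenen ramification index).

Perimeters come from marching-squares polygonal contours so an ideal disc has
circularity 1; the convex hull is taken over the (sub-pixel) contour
vertices. The Schoenen ramification index is undefined (NaN) for cells with
no processes; every other parameter is always defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure

from .segmentation import CellExtract, disk_footprint

_EIGHT = np.ones((3, 3), dtype=bool)

#: Column order of the 18 per-cell parameters.
PARAM_NAMES = (
    "cell_area_um2",
    "cell_perimeter_um",
    "convex_hull_area_um2",
    "convex_hull_perimeter_um",
    "cell_solidity",
    "cell_convexity",
    "cell_circularity",
    "soma_area_um2",
    "soma_perimeter_um",
    "soma_circularity",
    "skeleton_length_um",
    "skeleton_branch_points",
    "skeleton_endpoints",
    "n_processes",
    "branching_index",
    "critical_radius_um",
    "dendritic_maximum",
    "sri",
)

#: The 17 parameters retained for nearest-centroid analyses (SRI excluded
#: because it is undefined for process-free cells).
NC_PARAM_NAMES = tuple(p for p in PARAM_NAMES if p != "sri")


@dataclass
class MorphometryRecord:
    cell_id: int
    cell_area_um2: float
    cell_perimeter_um: float
    convex_hull_area_um2: float
    convex_hull_perimeter_um: float
    cell_solidity: float
    cell_convexity: float
    cell_circularity: float
    soma_area_um2: float
    soma_perimeter_um: float
    soma_circularity: float
    skeleton_length_um: float
    skeleton_branch_points: int
    skeleton_endpoints: int
    n_processes: int
    branching_index: float
    critical_radius_um: float
    dendritic_maximum: int
    sri: float  # NaN when n_processes == 0

    def to_dict(self) -> dict:
        return {"cell_id": self.cell_id, **{k: getattr(self, k) for k in PARAM_NAMES}}


@dataclass
class ShollProfile:
    radii_um: np.ndarray  # strictly increasing
    crossings: np.ndarray  # same length, counts >= 0
    center: tuple[int, int]


@dataclass
class ImageMetrics:
    segmented_area_pct: float
    cell_density_per_mm2: float


def circularity(area: float, perimeter: float) -> float:
    """4*pi*area / perimeter**2 — equals 1 for a perfect circle."""
    return 4.0 * math.pi * area / perimeter**2


#: Circular moving-average window applied to contour vertices; corrects the
#: marching-squares staircase bias so a rasterized disc's circularity is ~1.
_SMOOTH_WINDOW = 5


def _contours(mask: np.ndarray) -> list[np.ndarray]:
    padded = np.pad(mask.astype(float), 1)
    return [_smooth_closed(c) for c in measure.find_contours(padded, 0.5)]


def _smooth_closed(contour: np.ndarray, window: int = _SMOOTH_WINDOW) -> np.ndarray:
    ring = contour[:-1]  # find_contours closes the loop; drop the duplicate
    n = len(ring)
    if n < window:
        return contour
    half = window // 2
    idx = (np.arange(n)[:, None] + np.arange(-half, half + 1)[None, :]) % n
    sm = ring[idx].mean(axis=1)
    return np.vstack([sm, sm[:1]])


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


def region_metrics(mask: np.ndarray, pixel_size_um: float):
    """Area, perimeter, convex-hull metrics and shape descriptors of a mask.

    Returns ``(area_um2, perimeter_um, hull_area_um2, hull_perimeter_um,
    solidity, convexity, circularity)``. Area is the pixel count; perimeter
    the total marching-squares contour length; the hull is computed over all
    contour vertices.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    px, px2 = pixel_size_um, pixel_size_um**2
    area = float(mask.sum()) * px2
    contours = _contours(mask)
    perimeter = sum(_polyline_length(c) for c in contours) * px
    pts = np.concatenate(contours, axis=0)
    hull = ConvexHull(pts)
    hull_area = hull.volume * px2  # in 2D, volume is the polygon area
    hull_perimeter = hull.area * px  # ... and area is its perimeter
    return (
        area,
        perimeter,
        hull_area,
        hull_perimeter,
        area / hull_area,
        hull_perimeter / perimeter,
        circularity(area, perimeter),
    )


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=np.uint8)
    k[1, 1] = 0
    return ndi.convolve(skel.astype(np.uint8), k, mode="constant")


def skeleton_metrics(skeleton: np.ndarray, pixel_size_um: float):
    """Length (step-sum rule), branch-point count and endpoint count.

    Length sums unique adjacent pixel pairs: 1 per 4-neighbor step, sqrt(2)
    per diagonal step; a diagonal step is skipped when either of its two
    common 4-neighbors is foreground (it would double-count the corner).
    Endpoints have exactly one skeleton neighbor, branch points three or more.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        return 0.0, 0, 0
    nb = _neighbor_counts(skel)
    endpoints = int(((nb == 1) & skel).sum())
    branch_points = int(((nb >= 3) & skel).sum())
    s = np.pad(skel, 1)
    straight = int((s[1:-1, 1:-1] & s[1:-1, 2:]).sum() + (s[1:-1, 1:-1] & s[2:, 1:-1]).sum())
    diag = 0.0
    for dy, dx in ((1, 1), (1, -1)):
        a = s[1:-1, 1:-1]
        b = s[1 + dy : s.shape[0] - 1 + dy, 1 + dx : s.shape[1] - 1 + dx]
        c1 = s[1 + dy : s.shape[0] - 1 + dy, 1:-1]  # shares row step
        c2 = s[1:-1, 1 + dx : s.shape[1] - 1 + dx]  # shares col step
        diag += math.sqrt(2.0) * int((a & b & ~c1 & ~c2).sum())
    return (straight + diag) * pixel_size_um, branch_points, endpoints


def count_processes(cell_mask: np.ndarray, soma_mask: np.ndarray) -> int:
    """Isolated components of the cell after subtracting the 3-px-dilated soma."""
    collar = ndi.binary_dilation(soma_mask, structure=disk_footprint(3.0))
    residue = cell_mask & ~collar
    _, n = ndi.label(residue, structure=_EIGHT)
    return int(n)


def sholl_profile(
    skeleton: np.ndarray,
    soma_centroid: tuple[int, int],
    soma_area_px: float,
    pixel_size_um: float,
    step_um: float = 2.0,
) -> ShollProfile:
    """Process crossings on concentric 1-px rings around the soma centroid.

    The first ring sits one step beyond the soma-equivalent radius
    sqrt(soma_area/pi); a crossing is one 8-connected component of
    skeleton-on-ring. ``soma_centroid`` is in the skeleton's coordinates.
    """
    skel = np.asarray(skeleton, dtype=bool)
    r0_um = math.sqrt(soma_area_px / math.pi) * pixel_size_um + step_um
    cy, cx = soma_centroid
    if skel.any():
        ys, xs = np.nonzero(skel)
        max_um = float(np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2).max()) * pixel_size_um
    else:
        max_um = r0_um
    radii = [r0_um]
    while radii[-1] + step_um <= max_um + step_um:
        radii.append(radii[-1] + step_um)
    yy, xx = np.mgrid[0 : skel.shape[0], 0 : skel.shape[1]]
    dist_px = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    crossings = []
    for r_um in radii:
        r_px = r_um / pixel_size_um
        ring = np.abs(dist_px - r_px) <= 0.5
        _, n = ndi.label(skel & ring, structure=_EIGHT)
        crossings.append(n)
    return ShollProfile(
        radii_um=np.asarray(radii), crossings=np.asarray(crossings), center=soma_centroid
    )


def sholl_derived(profile: ShollProfile, n_processes: int):
    """Branching index, critical radius, dendritic maximum and SRI.

    The branching index sums radius-weighted positive crossing increments
    (baseline zero before the first ring); the critical radius is the
    smallest radius attaining the maximum crossing count; SRI is the
    dendritic maximum over the number of primary processes — NaN when the
    cell has none.
    """
    counts = profile.crossings
    radii = profile.radii_um
    dmax = int(counts.max(initial=0))
    critical = float(radii[int(np.argmax(counts))]) if len(radii) else 0.0
    prev = np.concatenate(([0], counts[:-1]))
    inc = counts - prev
    branching = float((inc[inc > 0] * radii[inc > 0]).sum())
    sri = float(dmax) / n_processes if n_processes > 0 else float("nan")
    return branching, critical, dmax, sri


def image_metrics(
    labels: np.ndarray,
    segmented_mask: np.ndarray,
    pixel_size_um: float,
) -> ImageMetrics:
    """Segmented-pixel percentage and cell density per mm^2 for one image."""
    total = segmented_mask.size
    if total == 0:
        raise ValueError("zero-area image")
    pct = 100.0 * float(np.count_nonzero(segmented_mask)) / total
    n_cells = int(labels.max())
    area_mm2 = labels.shape[0] * labels.shape[1] * (pixel_size_um * 1e-3) ** 2
    return ImageMetrics(segmented_area_pct=pct, cell_density_per_mm2=n_cells / area_mm2)


def compute_record(
    extract: CellExtract,
    pixel_size_um: float = 0.122,
    sholl_step_um: float = 2.0,
) -> MorphometryRecord:
    """All 18 parameters for one extracted cell."""
    px = pixel_size_um
    (cell_area, cell_perim, hull_area, hull_perim,
     solidity, convexity, cell_circ) = region_metrics(extract.cell_mask, px)
    soma_area, soma_perim, *_ , soma_circ = region_metrics(extract.soma_mask, px)
    skel_len, branch_pts, endpoints = skeleton_metrics(extract.skeleton, px)
    n_proc = count_processes(extract.cell_mask, extract.soma_mask)
    centroid_local = (
        extract.soma_centroid[0] - extract.bbox[0],
        extract.soma_centroid[1] - extract.bbox[1],
    )
    profile = sholl_profile(
        extract.skeleton, centroid_local, float(extract.soma_mask.sum()), px, sholl_step_um
    )
    branching, critical, dmax, sri = sholl_derived(profile, n_proc)
    return MorphometryRecord(
        cell_id=extract.cell_id,
        cell_area_um2=cell_area,
        cell_perimeter_um=cell_perim,
        convex_hull_area_um2=hull_area,
        convex_hull_perimeter_um=hull_perim,
        cell_solidity=solidity,
        cell_convexity=convexity,
        cell_circularity=cell_circ,
        soma_area_um2=soma_area,
        soma_perimeter_um=soma_perim,
        soma_circularity=soma_circ,
        skeleton_length_um=skel_len,
        skeleton_branch_points=branch_pts,
        skeleton_endpoints=endpoints,
        n_processes=n_proc,
        branching_index=branching,
        critical_radius_um=critical,
        dendritic_maximum=dmax,
        sri=sri,
    )


def records_to_frame(records) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in records])
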