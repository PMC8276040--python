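"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they are used to
check: connected components via explicit BFS, convex hulls via exhaustive
pairwise half-plane tests, multi-source growth via a literal layered BFS.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from microgliamorph import PHENOTYPES
from microgliamorph import synthetic_data as sd

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def bfs_components(mask: np.ndarray) -> int:
    """Count 8-connected components by explicit flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    n = 0
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        n += 1
        q = deque([(sy, sx)])
        seen[sy, sx] = True
        while q:
            y, x = q.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (
                        0 <= ny < mask.shape[0]
                        and 0 <= nx < mask.shape[1]
                        and mask[ny, nx]
                        and not seen[ny, nx]
                    ):
                        seen[ny, nx] = True
                        q.append((ny, nx))
    return n


def exhaustive_hull(points: np.ndarray) -> tuple[float, float]:
    """(area, perimeter) of the convex hull by O(n^2) edge testing.

    An ordered pair (p, q) is a hull edge iff every other point lies on or to
    the left of the directed line p->q. Works for any non-degenerate point
    set; intended for small inputs only.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if np.all(cross >= -1e-9):
                # keep only the farthest collinear endpoint for this direction
                on_line = np.abs(cross) < 1e-9
                t = rel[on_line] @ d
                if t.max() > (pts[j] - pts[i]) @ d + 1e-9:
                    continue
                edges[i] = j
    # walk the edge cycle
    start = next(iter(edges))
    order = [start]
    cur = edges[start]
    while cur != start:
        order.append(cur)
        cur = edges[cur]
    poly = pts[order]
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    closed = np.vstack([poly, poly[:1]])
    perim = float(np.sqrt(((closed[1:] - closed[:-1]) ** 2).sum(axis=1)).sum())
    return float(area), perim


def two_source_bfs(mask: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Synchronous multi-source 8-connected BFS; ties go to the lower label.

    ``seeds`` is a label image (0 = unseeded). Literal layer-by-layer
    expansion, one deque per label, lower labels expand first in each layer.
    """
    mask = np.asarray(mask, bool)
    out = np.where(mask, seeds, 0).astype(int)
    labels = sorted(set(np.unique(seeds)) - {0})
    frontiers = {l: deque(map(tuple, np.argwhere(out == l))) for l in labels}
    while any(frontiers.values()):
        claims: dict[tuple[int, int], int] = {}
        for l in labels:
            q = frontiers[l]
            frontiers[l] = deque()
            for y, x in q:
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < mask.shape[0]
                            and 0 <= nx < mask.shape[1]
                            and mask[ny, nx]
                            and out[ny, nx] == 0
                            and (ny, nx) not in claims
                        ):
                            claims[(ny, nx)] = l
        for (y, x), l in claims.items():
            out[y, x] = l
            frontiers[l].append((y, x))
    return out


def rank_then_pearson(x, y) -> float:
    """Spearman rho by hand: average ranks, then the Pearson formula."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        for val in np.unique(v):
            sel = v == val
            r[sel] = r[sel].mean()
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_cells() -> dict[str, sd.SyntheticCell]:
    return {ph: sd.generate_cell(sd.DEFAULT_PARAMS[ph], seed=11) for ph in PHENOTYPES}


@pytest.fixture(scope="session")
def small_tile():
    """A 5-cell noisy tile plus its rendered image and ground truth."""
    scene = sd.make_tile_scene(5, size=640, seed=3, noise_sd=0.02)
    img, truth = sd.render_tile(scene)
    return scene, img, truth


@pytest.fixture(scope="session")
def segmented_tile(small_tile):
    from microgliamorph.segmentation import segment_image

    scene, img, truth = small_tile
    return scene, img, truth, segment_image(img)
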