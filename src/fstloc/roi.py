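"""ROI delineation from contrast maps, and overlap metrics.

Encodes the manual delineation procedure as a deterministic heuristic:
threshold the 2D- and 3D-motion contrast maps at a hemisphere-wide
percentile (starting at the 95th), take the largest 4-connected cluster of
the 2D mask as hMT/MST, and take as pFST the 3D-active cluster outside
hMT/MST that is adjacent (or within a small distance) and whose centroid
lies anterior and/or inferior to the hMT/MST centroid. If no candidate
qualifies, both thresholds are lowered in 1-percentile steps down to the
90th. Overlap metrics (Dice coefficient, centroid distance, surface area)
quantify agreement with ground truth or an atlas label set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .glm import ContrastMap

__all__ = [
    "ROISet",
    "percentile_threshold",
    "connected_clusters",
    "classify_scenario",
    "delineate",
    "dice",
    "centroid_distance",
    "surface_area",
]

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ROISet:
    """Delineated label map: 0 = none, 1 = hMTMST, 2 = pFST."""

    labels: np.ndarray
    threshold_used_2d: float
    threshold_used_3d: float
    scenario: str
    pfst_found: bool = True
    notes: list[str] = field(default_factory=list)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == {"hMTMST": 1, "pFST": 2}[name]


def percentile_threshold(map_: ContrastMap | np.ndarray, q: float) -> np.ndarray:
    """Vertices at or above the q-th percentile of the whole hemisphere.

    ``q`` must lie in the [90, 95] band used for delineation; percentiles
    use linear interpolation. A constant map passes everywhere (every value
    equals its own percentile).
    """
    if not 90.0 <= q <= 95.0:
        raise ValueError(f"threshold percentile must be in [90, 95], got {q}")
    values = map_.values if isinstance(map_, ContrastMap) else np.asarray(map_, float)
    thr = np.percentile(values, q)
    return values >= thr


def connected_clusters(mask: np.ndarray, shape: tuple[int, int] | None = None) -> list[np.ndarray]:
    """4-connected components of a binary mask, as boolean maps.

    Sorted by size descending, ties broken by smallest contained flat
    vertex index (deterministic).
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim == 1:
        if shape is None:
            raise ValueError("flat mask needs an explicit grid shape")
        m = m.reshape(shape)
    lab, n = ndimage.label(m, structure=FOUR_CONN)
    clusters = [lab == i for i in range(1, n + 1)]
    return sorted(
        clusters,
        key=lambda c: (-int(c.sum()), int(np.flatnonzero(c.ravel())[0])),
    )


def classify_scenario(mask2d: np.ndarray, mask3d: np.ndarray) -> str:
    """Relationship of the 2D- and 3D-localizer activation masks.

    'disjoint' when they do not intersect; otherwise whichever residual is
    larger decides between 'overlap_3d_superset' (3D activation extends
    beyond the 2D one, the commonly observed case) and
    'overlap_2d_superset'.
    """
    m2 = np.asarray(mask2d, bool)
    m3 = np.asarray(mask3d, bool)
    if m2.shape != m3.shape:
        raise ValueError("masks must have the same shape")
    if not np.any(m2 & m3):
        return "disjoint"
    only3 = int(np.sum(m3 & ~m2))
    only2 = int(np.sum(m2 & ~m3))
    return "overlap_3d_superset" if only3 >= only2 else "overlap_2d_superset"


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def delineate(
    map2d: ContrastMap | np.ndarray,
    map3d: ContrastMap | np.ndarray,
    shape: tuple[int, int],
    q_start: float = 95.0,
    q_min: float = 90.0,
    q_step: float = 1.0,
    adjacency_dist: int = 3,
    window_mask: np.ndarray | None = None,
) -> ROISet:
    """Delineate hMT/MST and pFST from the two motion contrast maps.

    hMT/MST is the largest 4-connected cluster of the thresholded 2D map
    (drawn first). pFST candidates are the clusters of the thresholded 3D
    map outside hMT/MST; among candidates within ``adjacency_dist``
    city-block steps of hMT/MST, the one whose centroid scores highest on
    the anterior/inferior criterion (delta-col + delta-row relative to the
    hMT/MST centroid, must be positive) is selected, larger cluster winning
    ties. When no candidate qualifies, both thresholds are lowered together
    by ``q_step`` down to ``q_min``; if none qualifies even there, pFST is
    returned empty and flagged. ``window_mask`` optionally restricts the
    search to an anatomical window (lateral-occipital / inferior temporal
    stand-in).
    """
    v2 = (map2d.values if isinstance(map2d, ContrastMap) else np.asarray(map2d, float)).reshape(shape)
    v3 = (map3d.values if isinstance(map3d, ContrastMap) else np.asarray(map3d, float)).reshape(shape)
    notes: list[str] = []

    best_partial: ROISet | None = None
    q = q_start
    while q >= q_min - 1e-9:
        m2 = percentile_threshold(v2.ravel(), q).reshape(shape)
        m3 = percentile_threshold(v3.ravel(), q).reshape(shape)
        if window_mask is not None:
            m2 = m2 & window_mask
            m3 = m3 & window_mask

        clusters2 = connected_clusters(m2)
        if not clusters2:
            q -= q_step
            continue
        hmt = clusters2[0]
        scenario = classify_scenario(m2, m3)

        candidates = connected_clusters(m3 & ~hmt)
        # city-block distance from hMT/MST; 1 = sharing a 4-neighbor edge
        dist = ndimage.distance_transform_cdt(~hmt, metric="taxicab")
        r_mt, c_mt = _centroid(hmt)
        qualified = []
        for cand in candidates:
            if int(dist[cand].min()) > adjacency_dist:
                continue
            r_c, c_c = _centroid(cand)
            score = (c_c - c_mt) + (r_c - r_mt)
            if score > 0:
                qualified.append((score, int(cand.sum()), cand))
        if qualified:
            qualified.sort(key=lambda t: (-t[0], -t[1]))
            if len(qualified) > 1:
                notes.append(
                    f"{len(qualified)} qualifying pFST candidates at q={q:g}; "
                    "took the highest anterior/inferior score"
                )
            pfst = qualified[0][2] & ~hmt
            labels = np.zeros(shape, dtype=int)
            labels[hmt] = 1
            labels[pfst] = 2
            return ROISet(labels, q, q, scenario, pfst_found=True, notes=notes)
        if best_partial is None:
            labels = np.zeros(shape, dtype=int)
            labels[hmt] = 1
            best_partial = ROISet(labels, q, q, scenario, pfst_found=False, notes=notes)
        q -= q_step

    if best_partial is None:
        raise RuntimeError(
            "no hMT/MST cluster found in the 2D contrast map at any threshold "
            f"in [{q_min}, {q_start}]"
        )
    best_partial.notes.append("no qualifying pFST candidate down to the 90th percentile")
    return best_partial


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 0 when both sets are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 0.0
    return 2.0 * int(np.sum(a & b)) / total


def centroid_distance(
    a: np.ndarray, b: np.ndarray, spacing: float = 1.0
) -> float:
    """Euclidean distance between unweighted vertex centroids.

    ``spacing`` converts grid units to physical units (e.g. mm per vertex).
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if not a.any() or not b.any():
        raise ValueError("centroid_distance requires two non-empty sets")
    ra, ca = _centroid(a)
    rb, cb = _centroid(b)
    return float(np.hypot(ra - rb, ca - cb)) * spacing


def surface_area(roi: np.ndarray, vertex_area: float = 1.0) -> float:
    """Total surface area: vertex count times per-vertex area (mm^2)."""
    if vertex_area <= 0:
        raise ValueError("vertex_area must be positive")
    return float(np.asarray(roi, bool).sum()) * vertex_area
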