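"""Nucleus segmentation, cell-compartment construction and speckle detection.

Compartments per cell:

* **nucleus** — segmented from the DNA channel by Otsu thresholding;
* **dilated nucleus** — every pixel within a fixed Euclidean distance of the
  nucleus, contested pixels going to the nearest nucleus (cheap cell proxy
  when no membrane stain exists);
* **cytoplasm ring** — dilated nucleus minus nucleus;
* **cell** — nuclei propagated outward through the green-marker foreground
  along a gradient-penalized geodesic, so cell borders follow intensity
  edges;
* **speckles** — small bright spots found by white top-hat enhancement and
  per-object Otsu thresholding, assigned to their enclosing parent cell.

Labels are preserved through every derivation: compartment k always belongs
to nucleus k.  Pixel coordinates are 0-based row-major (row, col) and
objects use 4-connectivity unless stated otherwise.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening
from skimage.segmentation import clear_border, watershed

__all__ = [
    "SegmentationParams",
    "segment_nuclei",
    "dilate_objects",
    "subtract_compartment",
    "propagate_cells",
    "tophat_enhance",
    "detect_speckles",
    "assign_parents",
    "relabel_consecutive",
]

#: Minimum pixels in a parent before a per-object Otsu threshold is trusted.
MIN_PIXELS_PER_OBJECT_OTSU = 64


@dataclass(frozen=True)
class SegmentationParams:
    """Nucleus segmentation knobs.

    threshold_method: 'otsu_global' thresholds raw intensities; 'otsu_log'
    thresholds log-intensities, which helps when foreground spans decades.
    min_area/max_area bound accepted nucleus sizes in pixels; declump splits
    touching nuclei by a distance-transform watershed; smoothing_sigma is
    the Gaussian pre-smooth in pixels.
    """

    threshold_method: str = "otsu_global"
    min_area: int = 40
    max_area: int = 5000
    declump: bool = True
    smoothing_sigma: float = 1.0
    remove_border: bool = True
    connectivity: int = 4

    def __post_init__(self):
        if self.threshold_method not in ("otsu_global", "otsu_log"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if not (0 < self.min_area < self.max_area):
            raise ValueError("require 0 < min_area < max_area")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Relabel positive labels to consecutive 1..n preserving label order."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return lut[labels]


def segment_nuclei(dna: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment nuclei from a corrected DNA-channel raster.

    Gaussian pre-smooth, global Otsu threshold (optionally in log space),
    hole filling, size filtering, border-object removal and optional
    declumping by watershed on the negated distance transform.  Returns a
    consecutively labeled raster; an all-background field yields zero
    objects rather than an error.
    """
    params = params or SegmentationParams()
    dna = np.asarray(dna, dtype=np.float64)
    if not np.isfinite(dna).all():
        raise ValueError("DNA raster contains non-finite pixels")
    img = ndi.gaussian_filter(dna, params.smoothing_sigma) if params.smoothing_sigma > 0 else dna
    tvals = img
    if params.threshold_method == "otsu_log":
        tvals = np.log1p(img)
    if np.ptp(tvals) < 1e-12:
        return np.zeros(dna.shape, dtype=np.int32)
    thr = threshold_otsu(tvals)
    mask = tvals > thr
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(dna.shape, dtype=np.int32)

    structure = _structure(params.connectivity)
    if params.declump:
        dist = ndi.distance_transform_edt(mask)
        # Slight smoothing breaks EDT ridge plateaus so a single convex
        # object yields one seed instead of a chain of near-equal maxima.
        dist_s = ndi.gaussian_filter(dist, 1.5)
        min_sep = max(1, int(round(np.sqrt(params.min_area) / 2)))
        peaks = peak_local_max(
            dist_s, min_distance=min_sep, labels=mask, exclude_border=False
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        # raster order of peaks gives deterministic marker numbering
        order = np.lexsort((peaks[:, 1], peaks[:, 0]))
        for i, (r, c) in enumerate(peaks[order], start=1):
            markers[r, c] = i
        labels = watershed(-dist, markers=markers, mask=mask, connectivity=structure)
    else:
        labels, _ = ndi.label(mask, structure=structure)

    sizes = np.bincount(labels.ravel())
    bad = (sizes < params.min_area) | (sizes > params.max_area)
    bad[0] = False
    labels[bad[labels]] = 0
    if params.remove_border:
        labels = clear_border(labels)
    return relabel_consecutive(labels)


def nearest_object_maps(objects: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (distance, label) of the nearest object, lower label on ties.

    Computed by one Euclidean distance transform per label, sweeping labels
    in increasing order and replacing only on strictly smaller distance —
    this pins the tie-break to the lower label, which a single indexed EDT
    would leave unspecified.
    """
    objects = np.asarray(objects)
    best_dist = np.full(objects.shape, np.inf)
    best_label = np.zeros(objects.shape, dtype=np.int32)
    for lab in np.unique(objects[objects > 0]):
        d = ndi.distance_transform_edt(objects != lab)
        closer = d < best_dist
        best_dist[closer] = d[closer]
        best_label[closer] = lab
    return best_dist, best_label


def dilate_objects(objects: np.ndarray, distance: float) -> np.ndarray:
    """Grow each object to all pixels within Euclidean ``distance`` of it.

    Contested pixels go to the nearest object (lower label on exact ties);
    objects never merge and keep their labels.  ``distance`` 0 is the
    identity.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    objects = np.asarray(objects)
    if distance == 0 or objects.max() == 0:
        return objects.astype(np.int32, copy=True)
    dist, label = nearest_object_maps(objects)
    out = np.where(dist <= distance, label, 0).astype(np.int32)
    return out


def subtract_compartment(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Cytoplasm ring: outer object k minus inner object k, labels kept.

    Requires inner k to be contained in outer k; an empty ring is simply an
    object of zero area (flagged missing by downstream measurements).
    """
    outer = np.asarray(outer)
    inner = np.asarray(inner)
    if outer.shape != inner.shape:
        raise ValueError("shape mismatch")
    inside = inner > 0
    if not np.array_equal(inner[inside], outer[inside]):
        raise ValueError("containment violation: inner object leaves its outer object")
    out = outer.astype(np.int32, copy=True)
    out[inside] = 0
    return out


def propagate_cells(
    seeds: np.ndarray,
    green: np.ndarray,
    threshold: float,
    regularization: float = 0.05,
) -> np.ndarray:
    """Propagate seed labels through the green foreground along geodesics.

    Foreground is ``green >= threshold`` union the seed pixels.  Every
    foreground pixel is assigned to the seed reachable at minimum geodesic
    cost, where moving through a pixel costs
    ``sqrt(regularization + |grad green|^2)`` per unit path length: a large
    regularization makes the cost pure path length (nearest-seed), a small
    one makes boundaries hug intensity edges.  Foreground disconnected from
    every seed stays background; seed labels are preserved.
    """
    seeds = np.asarray(seeds)
    green = np.asarray(green, dtype=np.float64)
    if seeds.shape != green.shape:
        raise ValueError("shape mismatch")
    if seeds.max() == 0:
        raise ValueError("no seeds")
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")

    fg = (green >= threshold) | (seeds > 0)
    gy, gx = np.gradient(green)
    node_cost = np.sqrt(regularization + gy**2 + gx**2)

    from skimage.graph import MCP_Geometric

    cost_arr = np.where(fg, node_cost, np.inf)
    seed_pix = np.argwhere(seeds > 0)
    mcp = MCP_Geometric(cost_arr, fully_connected=True)
    costs, traceback = mcp.find_costs([tuple(p) for p in seed_pix])

    offsets = np.asarray(mcp.offsets)
    out = np.zeros(seeds.shape, dtype=np.int32)
    out[seeds > 0] = seeds[seeds > 0]

    reachable = np.isfinite(costs) & fg & (seeds == 0)
    rr, cc = np.nonzero(reachable)
    order = np.argsort(costs[rr, cc], kind="stable")
    for idx in order:
        r, c = rr[idx], cc[idx]
        t = traceback[r, c]
        if t < 0:
            continue
        pr, pc = r - offsets[t, 0], c - offsets[t, 1]
        out[r, c] = out[pr, pc]
    return out


def geodesic_costs_dijkstra(
    cost: np.ndarray, sources: list[tuple[int, int]]
) -> np.ndarray:
    """Reference multi-source Dijkstra on the 8-connected pixel graph.

    Edge weight between neighbors p, q is
    ``dist(p, q) * (cost[p] + cost[q]) / 2`` — the discrete geodesic used by
    :func:`propagate_cells`.  Pure-Python; intended for small grids and as
    an independent check, not for production use.
    """
    h, w = cost.shape
    dist = np.full((h, w), np.inf)
    heap = []
    for s in sources:
        dist[s] = 0.0
        heapq.heappush(heap, (0.0, s))
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in nbrs:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w):
                continue
            if not np.isfinite(cost[nr, nc]):
                continue
            step = np.hypot(dr, dc) * (cost[r, c] + cost[nr, nc]) / 2.0
            nd = d + step
            if nd < dist[nr, nc]:
                dist[nr, nc] = nd
                heapq.heappush(heap, (nd, (nr, nc)))
    return dist


def tophat_enhance(green: np.ndarray, element_radius: int) -> np.ndarray:
    """White top-hat: image minus its opening with a disk element.

    Enhances bright structures smaller than the element and suppresses the
    diffuse background; output is everywhere >= 0.
    """
    if element_radius < 1:
        raise ValueError("element_radius must be >= 1")
    green = np.asarray(green, dtype=np.float64)
    opened = opening(green, footprint=disk(element_radius))
    return np.maximum(green - opened, 0.0)


def detect_speckles(
    enhanced: np.ndarray,
    parents: np.ndarray,
    min_area: int = 2,
    max_area: int = 200,
    per_object: bool = True,
    min_threshold: float = 0.0,
) -> tuple[np.ndarray, dict[int, int]]:
    """Find bright speckles in a top-hat-enhanced raster.

    With ``per_object`` an Otsu threshold is computed separately from the
    enhanced pixels inside each parent and applied within that parent —
    robust to per-cell background differences; otherwise one global Otsu is
    used.  Connected components outside [min_area, max_area] are dropped,
    survivors relabeled consecutively and mapped to their enclosing parent.
    A parent with fewer than 64 pixels or zero intensity variance falls back
    to the global threshold.

    ``min_threshold`` is an absolute floor applied to every threshold; Otsu
    splits noise when a parent holds no real spots, so a small floor keeps
    spot-free cells clean.
    """
    enhanced = np.asarray(enhanced, dtype=np.float64)
    parents = np.asarray(parents)
    if enhanced.shape != parents.shape:
        raise ValueError("shape mismatch")
    if not (1 <= min_area < max_area):
        raise ValueError("require 1 <= min_area < max_area")
    if per_object and parents.max() == 0:
        raise ValueError("per-object thresholding needs a non-empty parent raster")

    inside = parents > 0
    mask = np.zeros(enhanced.shape, dtype=bool)
    vals_inside = enhanced[inside]
    global_thr = (
        threshold_otsu(vals_inside)
        if vals_inside.size and np.ptp(vals_inside) > 1e-12
        else np.inf
    )
    if per_object:
        for lab in np.unique(parents[inside]):
            sel = parents == lab
            vals = enhanced[sel]
            if vals.size < MIN_PIXELS_PER_OBJECT_OTSU or np.ptp(vals) < 1e-12:
                thr = global_thr
            else:
                thr = threshold_otsu(vals)
            mask[sel] = enhanced[sel] > max(thr, min_threshold)
    else:
        mask[inside] = enhanced[inside] > max(global_thr, min_threshold)

    labels, _ = ndi.label(mask, structure=_structure(4))
    sizes = np.bincount(labels.ravel())
    bad = (sizes < min_area) | (sizes > max_area)
    bad[0] = False
    labels[bad[labels]] = 0
    labels = relabel_consecutive(labels)
    return labels, assign_parents(labels, parents)


def assign_parents(children: np.ndarray, parents: np.ndarray) -> dict[int, int]:
    """Map each child label to the parent with the largest pixel overlap.

    Ties go to the lower parent label; a child overlapping only background
    maps to 0.
    """
    children = np.asarray(children)
    parents = np.asarray(parents)
    if children.shape != parents.shape:
        raise ValueError("shape mismatch")
    out: dict[int, int] = {}
    child_ids = np.unique(children[children > 0])
    for ch in child_ids:
        overlap = parents[children == ch]
        counts = np.bincount(overlap[overlap > 0])
        if counts.size == 0 or counts.max() == 0:
            out[int(ch)] = 0
        else:
            out[int(ch)] = int(np.argmax(counts))  # argmax takes lowest on ties
    return out
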