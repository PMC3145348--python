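"""Per-object measurement library.

Every function takes a label raster (0 = background, objects labeled
1..n) and returns a pandas DataFrame indexed by object label with short
column names; the pipeline prefixes compartment/channel context to build
the full ``Compartment_Category_Name_Channel[_scale]`` feature names.

Degenerate objects (empty rings, zero intensity range, too few texture
pairs) produce NaN — explicitly missing — never raise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

__all__ = [
    "measure_intensity",
    "measure_shape",
    "measure_texture",
    "measure_correlation",
    "measure_radial",
    "count_children",
    "INTENSITY_NAMES",
    "TEXTURE_NAMES",
    "SHAPE_NAMES",
    "CORRELATION_NAMES",
]

INTENSITY_NAMES = [
    "Integrated", "Mean", "Median", "Std", "Max", "Min", "MAD",
    "IntegratedEdge", "MeanEdge", "StdEdge", "MaxEdge", "MinEdge",
]
SHAPE_NAMES = [
    "Area", "Perimeter", "FormFactor", "Eccentricity", "Solidity",
    "Extent", "EquivalentDiameter",
]
TEXTURE_NAMES = [
    "ASM", "Contrast", "Correlation", "Variance", "InverseDifferenceMoment",
    "SumAverage", "SumVariance", "SumEntropy", "Entropy",
    "DifferenceVariance", "DifferenceEntropy", "InfoMeas1", "InfoMeas2",
]
CORRELATION_NAMES = ["Correlation", "Slope", "Overlap"]


def _labels_of(objects: np.ndarray) -> np.ndarray:
    labs = np.unique(objects)
    return labs[labs > 0]


def _check_shapes(objects: np.ndarray, *rasters: np.ndarray) -> None:
    for r in rasters:
        if r.shape != objects.shape:
            raise ValueError(f"shape mismatch: {r.shape} vs {objects.shape}")


def _sample_std(v: np.ndarray) -> float:
    """Sample SD (ddof=1); defined as 0 for a single sample."""
    return float(np.std(v, ddof=1)) if v.size > 1 else 0.0


def _edge_mask(objects: np.ndarray) -> np.ndarray:
    """Pixels of an object whose 8-neighborhood leaves the object.

    Image-border pixels count as boundary (the constant pad is background).
    """
    mx = ndi.maximum_filter(objects, size=3, mode="constant", cval=0)
    mn = ndi.minimum_filter(objects, size=3, mode="constant", cval=0)
    return (objects > 0) & ((mx != objects) | (mn != objects))


def measure_intensity(objects: np.ndarray, raster: np.ndarray) -> pd.DataFrame:
    """Intensity statistics per object, plus edge statistics on the object's
    internal boundary (pixels with an 8-neighbor outside the object)."""
    objects = np.asarray(objects)
    raster = np.asarray(raster, dtype=np.float64)
    _check_shapes(objects, raster)
    labs = _labels_of(objects)
    edge = _edge_mask(objects)
    rows = {}
    slices = ndi.find_objects(objects)
    for lab in labs:
        sl = slices[lab - 1]
        sel = objects[sl] == lab
        v = raster[sl][sel]
        ev = raster[sl][sel & edge[sl]]
        med = float(np.median(v))
        rows[int(lab)] = [
            float(v.sum()), float(v.mean()), med, _sample_std(v),
            float(v.max()), float(v.min()), float(np.median(np.abs(v - med))),
            float(ev.sum()), float(ev.mean()), _sample_std(ev),
            float(ev.max()), float(ev.min()),
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=INTENSITY_NAMES)


def measure_shape(objects: np.ndarray) -> pd.DataFrame:
    """Size and shape per object.

    Perimeter uses the weighted chain-code estimate of ``regionprops``
    (Benkrid/line-pattern weighting); FormFactor = 4*pi*Area/Perimeter^2 is
    1 for an ideal circle and is missing for objects with zero perimeter.
    """
    objects = np.asarray(objects)
    rows = {}
    for rp in regionprops(objects):
        area = float(rp.area)
        perim = float(rp.perimeter)
        ff = 4 * np.pi * area / perim**2 if perim > 0 else np.nan
        rows[int(rp.label)] = [
            area, perim, ff, float(rp.eccentricity), float(rp.solidity),
            float(rp.extent), float(rp.equivalent_diameter_area),
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=SHAPE_NAMES)


# ---------------------------------------------------------------------------
# Haralick texture on a per-object, range-quantized GLCM
# ---------------------------------------------------------------------------

_GLCM_OFFSETS = lambda d: [(0, d), (d, 0), (d, d), (d, -d)]  # noqa: E731


def glcm_for_object(
    values: np.ndarray, mask: np.ndarray, offset: int, levels: int
) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix for one object patch.

    Pixels are quantized to ``levels`` equal-width bins spanning the
    object's own min-max range (illumination-robust); pairs are counted at
    the four direction offsets of distance ``offset`` with both pixels
    inside the object.  Returns None when the object has zero intensity
    range or fewer than 4 valid pairs.
    """
    v = values[mask]
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return None
    q = np.clip(((values - lo) / (hi - lo) * levels).astype(np.int64), 0, levels - 1)
    h, w = values.shape
    counts = np.zeros((levels, levels), dtype=np.float64)
    npairs = 0
    for dr, dc in _GLCM_OFFSETS(offset):
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a_mask = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        a = q[r0:r1, c0:c1][a_mask]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc][a_mask]
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
        npairs += a.size
    if npairs < 4:
        return None
    return counts / counts.sum()


def haralick_from_glcm(p: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics of a normalized symmetric GLCM.

    Entropies are in bits (log base 2).  Variance centers on the marginal
    mean; SumVariance centers on SumAverage.  Correlation is missing when a
    marginal variance vanishes.
    """
    L = p.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    eps = np.finfo(float).tiny
    log2 = lambda x: np.log2(np.maximum(x, eps))  # noqa: E731

    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_diff = i

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    corr = np.nan
    if var > 0:
        corr = float(((ii - mu) * (jj - mu) * p).sum() / var)
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = float(-(p_sum * log2(p_sum))[p_sum > 0].sum())
    ent = float(-(p * log2(p))[p > 0].sum())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = float(-(p_diff * log2(p_diff))[p_diff > 0].sum())

    pxy = np.outer(px, px)
    hxy1 = float(-(p * log2(pxy)).sum())
    hxy2 = float(-(pxy * log2(pxy))[pxy > 0].sum())
    hx = float(-(px * log2(px))[px > 0].sum())
    denom = max(hx, hx)  # symmetric GLCM: HX == HY
    im1 = (ent - hxy1) / denom if denom > 0 else np.nan
    im2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))))

    return dict(zip(TEXTURE_NAMES, [
        asm, contrast, corr, var, idm, sum_avg, sum_var, sum_ent, ent,
        diff_var, diff_ent, im1, im2,
    ]))


def measure_texture(
    objects: np.ndarray, raster: np.ndarray, offset: int = 1, levels: int = 8
) -> pd.DataFrame:
    """Haralick texture per object at one co-occurrence distance."""
    if offset < 1:
        raise ValueError("offset must be >= 1")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    objects = np.asarray(objects)
    raster = np.asarray(raster, dtype=np.float64)
    _check_shapes(objects, raster)
    rows = {}
    slices = ndi.find_objects(objects)
    for lab in _labels_of(objects):
        sl = slices[lab - 1]
        mask = objects[sl] == lab
        glcm = glcm_for_object(raster[sl], mask, offset, levels)
        if glcm is None:
            rows[int(lab)] = [np.nan] * len(TEXTURE_NAMES)
        else:
            rows[int(lab)] = list(haralick_from_glcm(glcm).values())
    return pd.DataFrame.from_dict(rows, orient="index", columns=TEXTURE_NAMES)


def measure_correlation(
    objects: np.ndarray, raster_a: np.ndarray, raster_b: np.ndarray
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Channel co-localization per object and over the whole image.

    Pearson correlation of the two channels over the object's pixels, the
    least-squares slope of B on A, and the Manders-style overlap
    coefficient sum(AB)/sqrt(sum(A^2) sum(B^2)).  Constant channels give
    missing Correlation/Slope.
    """
    objects = np.asarray(objects)
    a_full = np.asarray(raster_a, dtype=np.float64)
    b_full = np.asarray(raster_b, dtype=np.float64)
    _check_shapes(objects, a_full, b_full)

    def stats(a: np.ndarray, b: np.ndarray) -> list[float]:
        va, vb = a.var(), b.var()
        if a.size < 2 or va < 1e-30 or vb < 1e-30:
            r, slope = np.nan, np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
            slope = float(np.cov(a, b, ddof=1)[0, 1] / np.var(a, ddof=1))
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        overlap = float((a * b).sum() / denom) if denom > 0 else np.nan
        return [r, slope, overlap]

    rows = {}
    slices = ndi.find_objects(objects)
    for lab in _labels_of(objects):
        sl = slices[lab - 1]
        sel = objects[sl] == lab
        rows[int(lab)] = stats(a_full[sl][sel], b_full[sl][sel])
    perobj = pd.DataFrame.from_dict(rows, orient="index", columns=CORRELATION_NAMES)
    image_stats = dict(zip(CORRELATION_NAMES, stats(a_full.ravel(), b_full.ravel())))
    return perobj, image_stats


# ---------------------------------------------------------------------------
# Radial intensity distribution
# ---------------------------------------------------------------------------

_N_NORM_SECTORS = 36  # angular discretization of "per-ray" edge distance


def measure_radial(
    objects: np.ndarray, raster: np.ndarray, n_bins: int = 4, n_wedges: int = 8
) -> pd.DataFrame:
    """Radial intensity distribution per object.

    Each object pixel gets a normalized radius: distance from the object
    centroid divided by the maximum distance within the object along the
    pixel's angular ray (rays discretized into 36 sectors), clamped to
    [0, 1], then binned into ``n_bins`` annuli.  Per annulus b (1-based):

    * ``FracAtD_b`` — fraction of total object intensity in the annulus;
    * ``MeanFrac_b`` — FracAtD_b divided by the annulus pixel fraction
      (1 everywhere for a uniform object);
    * ``RadialCV_b`` — coefficient of variation of the per-wedge intensity
      sums across ``n_wedges`` equal angular sectors (0 for angularly
      uniform intensity).

    Zero-intensity objects are entirely missing.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_wedges < 2:
        raise ValueError("n_wedges must be >= 2")
    objects = np.asarray(objects)
    raster = np.asarray(raster, dtype=np.float64)
    _check_shapes(objects, raster)
    cols = (
        [f"FracAtD_{b}" for b in range(1, n_bins + 1)]
        + [f"MeanFrac_{b}" for b in range(1, n_bins + 1)]
        + [f"RadialCV_{b}" for b in range(1, n_bins + 1)]
    )
    rows = {}
    slices = ndi.find_objects(objects)
    for lab in _labels_of(objects):
        sl = slices[lab - 1]
        sel = objects[sl] == lab
        rr, cc = np.nonzero(sel)
        vals = raster[sl][sel]
        total = vals.sum()
        if total <= 0:
            rows[int(lab)] = [np.nan] * len(cols)
            continue
        cy, cx = rr.mean(), cc.mean()
        dy, dx = rr - cy, cc - cx
        r = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)  # [-pi, pi]
        sector = np.clip(
            ((theta + np.pi) / (2 * np.pi) * _N_NORM_SECTORS).astype(int),
            0, _N_NORM_SECTORS - 1,
        )
        max_per_sector = np.zeros(_N_NORM_SECTORS)
        np.maximum.at(max_per_sector, sector, r)
        denom = np.where(max_per_sector > 0, max_per_sector, 1.0)
        rnorm = np.clip(r / denom[sector], 0.0, 1.0)
        b = np.minimum((rnorm * n_bins).astype(int), n_bins - 1)
        wedge = np.clip(
            ((theta + np.pi) / (2 * np.pi) * n_wedges).astype(int), 0, n_wedges - 1
        )
        frac, meanfrac, radcv = [], [], []
        npix = len(vals)
        for bi in range(n_bins):
            inb = b == bi
            inten = vals[inb].sum()
            frac.append(inten / total)
            pixfrac = inb.sum() / npix
            meanfrac.append((inten / total) / pixfrac if pixfrac > 0 else np.nan)
            if inb.any():
                wsum = np.bincount(wedge[inb], weights=vals[inb], minlength=n_wedges)
                m = wsum.mean()
                radcv.append(float(wsum.std() / m) if m > 0 else np.nan)
            else:
                radcv.append(np.nan)
        rows[int(lab)] = frac + meanfrac + radcv
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def count_children(
    parent_map: dict[int, int], parents: np.ndarray
) -> tuple[pd.DataFrame, int]:
    """Children per parent and the per-image total.

    Childless parents get 0; children mapped to no parent (label 0) count
    toward the image total only.
    """
    parents = np.asarray(parents)
    labs = _labels_of(parents)
    counts = {int(lab): 0 for lab in labs}
    for _child, parent in parent_map.items():
        if parent in counts:
            counts[parent] += 1
    per_parent = pd.DataFrame.from_dict(
        {k: [float(v)] for k, v in counts.items()}, orient="index",
        columns=["ChildCount"],
    )
    return per_parent, len(parent_map)
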