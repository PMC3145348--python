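"""Synthetic two-channel image sets with plate metadata and ground truth.

Emulates the two assay families the screening pipeline targets, with known
per-cell truth so every stage can be tested without external downloads:

* **translocation** — a green marker redistributes from cytoplasm to
  nucleus with increasing effect: cytoplasm level ``baseline + (1 - e) c``
  and nucleus level ``n + e (c - n + delta)`` for effect e in [0, 1];
* **speckle** — a diffuse green marker condenses into small bright spots;
  each cell receives ``K ~ Poisson(lambda_max * e)`` Gaussian spots.

Dose maps to effect through a logistic (Hill) curve; negative controls sit
at dose 0 and positives at the top of the dose grid.  A low-order
multiplicative illumination gradient and Gaussian read noise corrupt the
renders (both default to small but non-zero values).  The cells are
deliberately simple geometric shapes — controllable statistical structure,
not photorealism, is the goal.

Everything is deterministic given the seed: identical parameters produce
byte-identical images and metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SynthParams",
    "logistic_response",
    "generate_translocation_set",
    "generate_speckle_set",
]


@dataclass(frozen=True)
class SynthParams:
    """Generator conditions.

    Intensities are on the [0, 1] raster scale, sizes in pixels, doses in
    arbitrary concentration units.  ``cells_per_image`` is a Poisson mean;
    cell centers are rejection-sampled so nuclei never overlap and cells
    barely touch.  ``effect_hi`` is the plateau of the dose-effect Hill
    curve (effect 0.9 at saturating dose by default).
    """

    image_size: tuple[int, int] = (256, 256)
    cells_per_image: float = 30.0
    nucleus_radius: tuple[float, float] = (5.0, 8.0)
    cell_radius: tuple[float, float] = (12.0, 16.0)
    dna_intensity: float = 0.7
    green_cyto: float = 0.40     # cytoplasm level c at zero effect
    green_nuc: float = 0.08      # nucleus level n at zero effect
    green_baseline: float = 0.0  # residual cytoplasm level at full effect
    delta: float = 0.10          # extra nuclear gain at full effect
    speckle_rate_max: float = 8.0
    speckle_sigma: float = 1.5
    speckle_amplitude: float = 0.5
    dose_grid: tuple[float, ...] = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0)
    images_per_dose: int = 2
    ec50: float = 0.05
    hill: float = 2.0
    effect_lo: float = 0.0
    effect_hi: float = 0.9
    noise_sd: float = 0.01
    illum_gradient: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.nucleus_radius) <= 0 or min(self.cell_radius) <= 0:
            raise ValueError("radii must be positive")
        for v in (self.dna_intensity, self.green_cyto, self.green_nuc,
                  self.green_baseline):
            if not (0 <= v <= 1):
                raise ValueError("intensities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(d < 0 for d in self.dose_grid) or len(self.dose_grid) < 2:
            raise ValueError("dose_grid needs >= 2 non-negative doses")


def logistic_response(
    dose: float, ec50: float, hill: float, lo: float, hi: float
) -> float:
    """Hill dose-response: lo at dose 0, midpoint lo+(hi-lo)/2 at the EC50."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if ec50 <= 0 or hill <= 0:
        raise ValueError("ec50 and hill must be positive")
    if lo > hi:
        raise ValueError("require lo <= hi")
    if dose == 0:
        return lo
    dh = dose**hill
    return lo + (hi - lo) * dh / (ec50**hill + dh)


def illumination_surface(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth low-order multiplicative shading, mean roughly 1."""
    h, w = shape
    v = (np.arange(h) / max(h - 1, 1) - 0.5)[:, None]
    u = (np.arange(w) / max(w - 1, 1) - 0.5)[None, :]
    return 1.0 + amplitude * (u + 0.7 * v + 0.5 * u * v)


def _place_cells(p: SynthParams, rng: np.random.Generator):
    """Rejection-sample cell centers/radii; nuclei never overlap."""
    h, w = p.image_size
    n_cells = int(rng.poisson(p.cells_per_image))
    cells = []
    for _ in range(n_cells):
        rc = rng.uniform(*p.cell_radius)
        rn_a = rng.uniform(*p.nucleus_radius)
        rn_b = rng.uniform(*p.nucleus_radius)
        phi = rng.uniform(0, np.pi)
        placed = False
        for _attempt in range(1000):
            cy = rng.uniform(rc, h - rc)
            cx = rng.uniform(rc, w - rc)
            ok = all(
                np.hypot(cy - c["cy"], cx - c["cx"]) >= 0.9 * (rc + c["rc"])
                for c in cells
            )
            if ok:
                cells.append(dict(cy=cy, cx=cx, rc=rc, rn_a=rn_a, rn_b=rn_b, phi=phi))
                placed = True
                break
        if not placed:
            # field saturated; keep the cells placed so far
            break
    if n_cells > 0 and not cells:
        raise ValueError("parameters make cells unplaceable")
    return cells


def _masks_for_cell(shape, cell):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cell["cy"], xx - cell["cx"]
    disk = dy**2 + dx**2 <= cell["rc"] ** 2
    c, s = np.cos(cell["phi"]), np.sin(cell["phi"])
    u = c * dx + s * dy
    v = -s * dx + c * dy
    nucleus = (u / cell["rn_a"]) ** 2 + (v / cell["rn_b"]) ** 2 <= 1.0
    return disk, nucleus


def _corrupt_and_quantize(
    clean: np.ndarray, p: SynthParams, rng: np.random.Generator
) -> np.ndarray:
    img = clean * illumination_surface(clean.shape, p.illum_gradient)
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return np.round(img * 65535).astype(np.uint16)


def _effects_and_controls(p: SynthParams):
    """(dose, effect, control) per image set, controls at the grid endpoints."""
    rows = []
    lo_dose, hi_dose = min(p.dose_grid), max(p.dose_grid)
    for dose in p.dose_grid:
        e = logistic_response(dose, p.ec50, p.hill, p.effect_lo, p.effect_hi)
        if dose == lo_dose:
            control = "negative"
        elif dose == hi_dose:
            control = "positive"
        else:
            control = "sample"
        for _rep in range(p.images_per_dose):
            rows.append((dose, e, control))
    return rows


def _write_set(out_dir: Path, kind: str, renders: list[dict], truth_rows: list[dict]):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, r in enumerate(renders):
        set_id = f"{kind}_{i:03d}"
        dna_path = out_dir / f"{set_id}_dna.tif"
        green_path = out_dir / f"{set_id}_green.tif"
        tifffile.imwrite(dna_path, r["dna"])
        tifffile.imwrite(green_path, r["green"])
        meta.append(
            dict(
                set_id=set_id,
                path_dna=str(dna_path),
                path_green=str(green_path),
                plate="P1",
                well=f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}",
                compound="cpdA" if r["control"] == "sample" else r["control"],
                dose=r["dose"],
                control=r["control"],
                cell_type="synthetic",
            )
        )
    plate_path = out_dir / "plate.csv"
    pd.DataFrame(meta).to_csv(plate_path, index=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return plate_path, truth


def generate_translocation_set(p: SynthParams, out_dir: str | Path):
    """Render a cytoplasm-to-nucleus translocation dose series.

    Returns (plate_csv_path, truth DataFrame).  Truth records, per cell,
    the rendered nucleus and cytoplasm green levels and their
    nucleus:cytoplasm ratio before illumination/noise corruption.
    """
    rng = np.random.default_rng(p.seed)
    renders, truth_rows = [], []
    for i, (dose, e, control) in enumerate(_effects_and_controls(p)):
        cells = _place_cells(p, rng)
        dna = np.zeros(p.image_size)
        green = np.zeros(p.image_size)
        cyt_level = p.green_baseline + (1.0 - e) * p.green_cyto
        nuc_level = p.green_nuc + e * (p.green_cyto - p.green_nuc + p.delta)
        for j, cell in enumerate(cells):
            disk, nucleus = _masks_for_cell(p.image_size, cell)
            dna[nucleus] = p.dna_intensity
            green[disk] = np.maximum(green[disk], cyt_level)
            green[nucleus] = nuc_level
            truth_rows.append(
                dict(
                    set_id=f"translocation_{i:03d}", cell=j,
                    cy=cell["cy"], cx=cell["cx"],
                    nucleus_a=cell["rn_a"], nucleus_b=cell["rn_b"],
                    cell_radius=cell["rc"], dose=dose, effect=e, control=control,
                    nuc_level=nuc_level, cyt_level=cyt_level,
                    ratio=nuc_level / cyt_level if cyt_level > 0 else np.nan,
                    speckles=0,
                )
            )
        renders.append(
            dict(
                dna=_corrupt_and_quantize(dna, p, rng),
                green=_corrupt_and_quantize(green, p, rng),
                dose=dose, control=control,
            )
        )
    return _write_set(Path(out_dir), "translocation", renders, truth_rows)


def generate_speckle_set(p: SynthParams, out_dir: str | Path):
    """Render a speckle-formation (GPCR-style) dose series.

    Each cell carries a diffuse cytoplasmic green level plus
    ``K ~ Poisson(speckle_rate_max * effect)`` Gaussian spots, placed
    uniformly inside the cell disk with spot centers rejection-sampled to
    avoid overlap; K is recorded as truth.
    """
    rng = np.random.default_rng(p.seed)
    diffuse = 0.15
    renders, truth_rows = [], []
    for i, (dose, e, control) in enumerate(_effects_and_controls(p)):
        cells = _place_cells(p, rng)
        dna = np.zeros(p.image_size)
        green = np.zeros(p.image_size)
        h, w = p.image_size
        yy, xx = np.mgrid[0:h, 0:w]
        lam = p.speckle_rate_max * e
        for j, cell in enumerate(cells):
            disk, nucleus = _masks_for_cell(p.image_size, cell)
            dna[nucleus] = p.dna_intensity
            green[disk] = np.maximum(green[disk], diffuse)
            k = int(rng.poisson(lam))
            centers: list[tuple[float, float]] = []
            placed = 0
            attempts = 0
            min_sep = 4.0 * p.speckle_sigma
            while placed < k and attempts < 1000:
                attempts += 1
                rr = cell["rc"] * 0.85 * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                sy, sx = cell["cy"] + rr * np.sin(th), cell["cx"] + rr * np.cos(th)
                if any(np.hypot(sy - a, sx - b) < min_sep for a, b in centers):
                    continue
                centers.append((sy, sx))
                placed += 1
            for sy, sx in centers:
                d2 = (yy - sy) ** 2 + (xx - sx) ** 2
                bump = p.speckle_amplitude * np.exp(-d2 / (2 * p.speckle_sigma**2))
                bump[d2 > (3 * p.speckle_sigma) ** 2] = 0.0
                green = np.maximum(green, np.minimum(green + bump, 1.0))
            truth_rows.append(
                dict(
                    set_id=f"speckle_{i:03d}", cell=j,
                    cy=cell["cy"], cx=cell["cx"],
                    nucleus_a=cell["rn_a"], nucleus_b=cell["rn_b"],
                    cell_radius=cell["rc"], dose=dose, effect=e, control=control,
                    nuc_level=diffuse, cyt_level=diffuse,
                    ratio=1.0, speckles=len(centers),
                )
            )
        renders.append(
            dict(
                dna=_corrupt_and_quantize(dna, p, rng),
                green=_corrupt_and_quantize(green, p, rng),
                dose=dose, control=control,
            )
        )
    return _write_set(Path(out_dir), "speckle", renders, truth_rows)


def two_dose_params(images_per_group: int = 8, seed: int = 0, **overrides) -> SynthParams:
    """Conditions for a minimal 2-dose control experiment (negative at dose
    0, positive at the top dose, light noise)."""
    base = SynthParams(
        dose_grid=(0.0, 1.0),
        images_per_dose=images_per_group,
        noise_sd=0.005,
        illum_gradient=0.2,
        seed=seed,
    )
    return replace(base, **overrides)
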