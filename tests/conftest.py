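"""Shared fixtures: small deterministic rasters and synthetic image sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from assayscreen.synth import SynthParams, generate_translocation_set


def render_disk(shape, center, radius, value=1.0, background=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=float)
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = value
    return img


def disk_labels(shape, centers, radius):
    """Label raster with one disk per center, labeled in list order."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    labels = np.zeros(shape, dtype=np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = i
    return labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_translocation(tmp_path_factory):
    """Noise-free, gradient-free 2-dose translocation set with roomy cells.

    Cell radii exceed the largest nucleus semi-axis plus the 5 px dilation,
    so the 5 px cytoplasm ring sits entirely inside the uniform cytoplasm.
    """
    out = tmp_path_factory.mktemp("clean_transloc")
    p = SynthParams(
        image_size=(192, 192),
        cells_per_image=8,
        nucleus_radius=(4.0, 6.0),
        cell_radius=(13.0, 15.0),
        dose_grid=(0.0, 1.0),
        images_per_dose=2,
        noise_sd=0.0,
        illum_gradient=0.0,
        seed=7,
    )
    plate, truth = generate_translocation_set(p, out)
    return p, plate, truth


@pytest.fixture(scope="session")
def small_feature_table(rng):
    """Per-image table: one informative feature among noise features."""
    n_per = 6
    set_ids = [f"s{i}" for i in range(2 * n_per)]
    control = ["negative"] * n_per + ["positive"] * n_per
    informative = np.r_[rng.normal(0, 0.05, n_per), rng.normal(1, 0.05, n_per)]
    data = {"Nucleus_Intensity_Mean_green": informative}
    for k in range(20):
        data[f"Cell_Texture_Entropy_green_{k}"] = rng.normal(0, 1, 2 * n_per)
    data["Cell_Shape_Area"] = np.full(2 * n_per, 3.0)  # constant -> invalid
    table = pd.DataFrame(data, index=set_ids)
    doses = {s: (0.0 if c == "negative" else 1.0) for s, c in zip(set_ids, control)}
    return table, control, doses
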