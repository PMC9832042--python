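import warnings

import numpy as np
import pandas as pd
import pytest

from cartimorph.simulate import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort config used across tests (fast to render)."""
    return CohortConfig(
        n_samples_per_group=2,
        images_per_sample=2,
        image_size=(192, 192),
        nuclei_per_image=(4, 7),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tmp_path_factory):
    """A small cohort rendered on disk once per session."""
    out = tmp_path_factory.mktemp("cohort")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        paths = generate_cohort(tiny_config, out)
    return paths


def quartic_fit_oracle(x, y):
    """Brute-force normal-equations quartic least squares.

    Independent oracle for the polynomial fit: builds the 5-column
    Vandermonde on (scaled) x and solves the normal equations directly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = (x - x.mean()) / max(x.std(), 1.0)
    V = np.vander(xs, 5, increasing=True)
    beta = np.linalg.solve(V.T @ V, V.T @ y)
    fitted = V @ beta
    return fitted, y - fitted


def moments_oracle(mask):
    """Double-loop central-moment computation on a binary object."""
    rows, cols = np.nonzero(mask)
    n = len(rows)
    cx = cols.mean()
    cy = rows.mean()
    mu20 = mu02 = mu11 = 0.0
    for r, c in zip(rows, cols):
        mu20 += (c - cx) ** 2
        mu02 += (r - cy) ** 2
        mu11 += (c - cx) * (r - cy)
    mu20 /= n
    mu02 /= n
    mu11 /= n
    tr = mu20 + mu02
    d = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam_max = (tr + d) / 2
    lam_min = max((tr - d) / 2, 0.0)
    ecc = np.sqrt(1 - lam_min / lam_max) if lam_min > 0 else 1.0
    return {
        "centroid": (cx, cy),
        "lam_max": lam_max,
        "lam_min": lam_min,
        "eccentricity": ecc,
        "major_axis_length": 4 * np.sqrt(lam_max),
        "minor_axis_length": 4 * np.sqrt(lam_min),
    }


def raster_ellipse(a, b, phi_deg=0.0, pad=6):
    """Rasterize an axis-aligned or rotated ellipse as a boolean mask."""
    import math

    size = int(2 * a) + 2 * pad + 1
    cy = cx = size // 2
    rr, cc = np.mgrid[0:size, 0:size]
    phi = math.radians(phi_deg)
    dx = cc - cx
    dy = rr - cy
    u = (dx * np.cos(phi) + dy * np.sin(phi)) / a
    v = (-dx * np.sin(phi) + dy * np.cos(phi)) / b
    return (u**2 + v**2) <= 1.0
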