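"""Cartilage surface-roughness index from a binary tissue mask.

The articular surface is read off a binary mask of the medial-tibia
cartilage as the topmost foreground pixel per column of the largest
connected component (row 0 is the image top, y grows downward).  A
4th-order polynomial is least-squares fitted to the (x, y) contour, the
error E is the mean absolute deviation of the contour from the fitted
curve, the cartilage length L is the straight-line distance between the
contour endpoints, and the roughness index is R = E / L.  R is
dimensionless and invariant under uniform rescaling of the image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)


@dataclass
class SurfaceContour:
    """Ordered (x, y) pixel coordinates of the extracted cartilage surface.

    ``x`` is strictly increasing with exactly one surface row ``y`` per
    column; at least 6 points are required (degree-4 fit with residual
    degrees of freedom).
    """

    x: np.ndarray
    y: np.ndarray
    image_id: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 6:
            raise ValueError("contour too short: need >= 6 points for a quartic fit")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")


@dataclass
class RoughnessResult:
    """Quartic-fit coefficients and the roughness index of one surface.

    ``coefficients`` are c0..c4 in the original pixel domain
    (y = c0 + c1 x + ... + c4 x^4); ``error`` is the mean absolute
    residual E (px), ``length`` the endpoint-to-endpoint distance L (px),
    and ``roughness`` the dimensionless index R = E / L.
    """

    coefficients: np.ndarray
    error: float
    length: float
    roughness: float
    metric: str = "mad"
    image_id: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (5,):
            raise ValueError("expected exactly 5 coefficients (degree 4)")
        if self.error < 0 or self.length <= 0:
            raise ValueError("error must be >= 0 and length > 0")


def extract_surface_contour(
    mask: np.ndarray, image_id: str | None = None
) -> SurfaceContour:
    """Extract the top surface contour from a binary tissue mask.

    Uses the largest connected foreground component; for every column the
    component occupies, y is its topmost foreground row.  Columns inside
    the component's x-span with no foreground (torn tissue) are excluded
    from the contour and logged, never interpolated.
    """
    mask = np.asarray(mask)
    binary = mask > 0
    if not binary.any():
        raise ValueError("no tissue: mask is empty")
    lab = cc_label(binary, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    component = lab == sizes.argmax()

    has_fg = component.any(axis=0)
    cols = np.nonzero(has_fg)[0]
    span = np.arange(cols[0], cols[-1] + 1)
    gaps = span[~has_fg[span]]
    if len(gaps):
        logger.warning(
            "%d columns without tissue inside the surface span excluded "
            "(first at column %d)",
            len(gaps),
            gaps[0],
        )
    usable = span[has_fg[span]]
    if len(usable) < 6:
        raise ValueError("contour too short: fewer than 6 usable columns")
    y = component[:, usable].argmax(axis=0)
    return SurfaceContour(usable.astype(float), y.astype(float), image_id)


def fit_quartic(contour: SurfaceContour) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial of degree exactly 4 through the contour.

    x is centered and scaled internally for conditioning; coefficients
    are reported in the original pixel domain (ascending powers).
    Returns ``(coefficients, residuals)`` with residual
    r_i = y_i - yhat(x_i).
    """
    if len(np.unique(contour.x)) < 5:
        raise ValueError("degenerate design: fewer than 5 distinct x values")
    poly = Polynomial.fit(contour.x, contour.y, deg=4)
    coeffs = poly.convert().coef
    coeffs = np.pad(coeffs, (0, 5 - len(coeffs)))  # trailing exact zeros
    residuals = contour.y - poly(contour.x)
    return coeffs, residuals


def compute_roughness(
    contour: SurfaceContour, metric: str = "mad"
) -> RoughnessResult:
    """Roughness index of one surface contour.

    E is the mean absolute residual from the quartic fit (``metric="mad"``,
    the default) or the root-mean-square residual (``metric="rms"``,
    offered for sensitivity analysis); L is the Euclidean distance
    between the first and last contour points; R = E / L.
    """
    if metric not in ("mad", "rms"):
        raise ValueError("metric must be 'mad' or 'rms'")
    coeffs, residuals = fit_quartic(contour)
    if metric == "mad":
        error = float(np.mean(np.abs(residuals)))
    else:
        error = float(np.sqrt(np.mean(residuals**2)))
    length = float(
        np.hypot(contour.x[-1] - contour.x[0], contour.y[-1] - contour.y[0])
    )
    if length == 0:
        raise ValueError("zero cartilage length: cannot normalize")
    return RoughnessResult(
        coefficients=coeffs,
        error=error,
        length=length,
        roughness=error / length,
        metric=metric,
        image_id=contour.image_id,
    )


def roughness_from_mask(
    mask: np.ndarray, image_id: str | None = None, metric: str = "mad"
) -> RoughnessResult:
    """Convenience: contour extraction followed by the roughness index."""
    return compute_roughness(extract_surface_contour(mask, image_id), metric=metric)


def roughness_by_group(
    masks: dict[str, np.ndarray],
    metadata: pd.DataFrame,
    metric: str = "mad",
) -> tuple[pd.DataFrame, "RegressionOutput"]:
    """Per-sample roughness table and the age-trend regression.

    ``masks`` maps image ids to binary masks; ``metadata`` must carry
    ``image_id``, ``sample_id``, ``group`` and ordinal ``group_code``
    (young=0, middle=1, aged=2).  Each sample's R is the mean over its
    masks; the trend is an OLS of per-sample R on the group code.
    Samples whose masks all fail contour extraction are excluded with a
    warning.
    """
    from cartimorph.stats import regress_trend

    required = {"image_id", "sample_id", "group", "group_code"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")

    rows = []
    for rec in metadata.to_dict("records"):
        img_id = rec["image_id"]
        if img_id not in masks:
            continue
        try:
            res = roughness_from_mask(masks[img_id], img_id, metric=metric)
        except ValueError as exc:
            warnings.warn(f"mask {img_id} failed: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "sample_id": rec["sample_id"],
                "image_id": img_id,
                "group": rec["group"],
                "group_code": rec["group_code"],
                "E_px": res.error,
                "L_px": res.length,
                "R": res.roughness,
            }
        )
    if not rows:
        raise ValueError("no usable masks")
    table = pd.DataFrame(rows)
    per_sample = (
        table.groupby(["sample_id", "group", "group_code"], sort=True)["R"]
        .mean()
        .reset_index()
    )
    groups = per_sample.groupby("group_code").size()
    if len(groups) < 2 or (groups < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each for the trend")
    trend = regress_trend(
        per_sample["R"].to_numpy(), per_sample["group_code"].to_numpy()
    )
    return per_sample, trend
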