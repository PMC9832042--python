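"""Nuclear segmentation and the fixed 53-descriptor shape/geometry vector.

Chondrocyte nuclei are segmented from a DAPI-style grayscale image by
global Otsu thresholding, hole filling, connected-component labeling and
an area filter.  Each nucleus is then summarised by a fixed roster of 53
shape/geometry descriptors: 23 classical geometry measures (area,
perimeter, form factor, moments-ellipse eccentricity and axes, radii from
the distance transform, Feret diameters, ...) plus the magnitudes of the
30 Zernike moments of orders n = 0..9 computed on the unit disk
circumscribing the object's bounding box.

Eccentricity e = sqrt(1 - (minor/major)^2) of the second-central-moment
ellipse is the aging marker of interest: 0 for a circle, approaching 1
for an elongated nucleus.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton, regionprops
from skimage.morphology import convex_hull_image

logger = logging.getLogger(__name__)

#: Geometry descriptors, fixed order.
GEOMETRY_FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "form_factor",
    "solidity",
    "extent",
    "euler_number",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "orientation",
    "compactness",
    "equivalent_diameter",
    "max_radius",
    "mean_radius",
    "median_radius",
    "min_feret_diameter",
    "max_feret_diameter",
    "bbox_area",
    "bbox_aspect_ratio",
    "centroid_x",
    "centroid_y",
    "convex_area",
    "circularity_complement",
)

#: Valid Zernike (n, m) index pairs for orders n = 0..9 (m >= 0, n - m even).
ZERNIKE_INDICES: tuple[tuple[int, int], ...] = tuple(
    (n, m) for n in range(10) for m in range(n % 2, n + 1, 2)
)

ZERNIKE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"zernike_{n}_{m}" for n, m in ZERNIKE_INDICES
)

#: The full 53-descriptor roster, fixed order and names.
FEATURE_NAMES: tuple[str, ...] = GEOMETRY_FEATURE_NAMES + ZERNIKE_FEATURE_NAMES

assert len(FEATURE_NAMES) == 53


@dataclass
class LabeledNuclei:
    """Connected-component labeling of the nuclei in one image.

    ``labels`` uses consecutive positive integers (0 = background);
    ``border_labels`` flags objects touching the image border (they are
    retained for measurement).
    """

    labels: np.ndarray
    count: int
    image_id: str | None = None
    border_labels: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) != self.count or (
            len(present) and present[-1] != self.count
        ):
            raise ValueError("labels must be consecutive integers 1..count")


def segment_nuclei(
    image: np.ndarray,
    min_area: float = 50,
    max_area: float = 5000,
    image_id: str | None = None,
) -> LabeledNuclei:
    """Segment bright nuclei from a grayscale image.

    Global Otsu threshold, hole filling, connected-component labeling
    (8-connectivity) and an area filter to ``[min_area, max_area]``.
    Border-touching objects are flagged but retained.  No objects after
    filtering is a warning, not an error (empty result returned).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if not min_area < max_area:
        raise ValueError("min_area must be < max_area")

    if np.all(image == image.flat[0]):
        warnings.warn("uniform image: no objects found", stacklevel=2)
        return LabeledNuclei(np.zeros(image.shape, dtype=np.int32), 0, image_id)

    thresh = threshold_otsu(image)
    binary = image > thresh
    binary = ndimage.binary_fill_holes(binary)
    raw = cc_label(binary, connectivity=2)

    # area filter, then relabel consecutively
    keep = []
    for rp in regionprops(raw):
        if min_area <= rp.area <= max_area:
            keep.append(rp.label)
    out = np.zeros(image.shape, dtype=np.int32)
    border = []
    for new, old in enumerate(keep, start=1):
        mask = raw == old
        out[mask] = new
        rows, cols = np.nonzero(mask)
        if (
            rows.min() == 0
            or cols.min() == 0
            or rows.max() == image.shape[0] - 1
            or cols.max() == image.shape[1] - 1
        ):
            border.append(new)
    if not keep:
        warnings.warn("no objects after size filtering", stacklevel=2)
    return LabeledNuclei(out, len(keep), image_id, tuple(border))


def _central_moments(coords: np.ndarray) -> tuple[float, float, float, float, float]:
    """Raw central moments (mu20, mu11, mu02) and centroid of a pixel list.

    ``coords`` is (N, 2) in (row, col) order.  Moments are normalised by
    the pixel count, i.e. they are the covariance entries of the pixel
    centre coordinates with x = columns, y = rows.
    """
    rows = coords[:, 0].astype(float)
    cols = coords[:, 1].astype(float)
    cy = rows.mean()
    cx = cols.mean()
    dx = cols - cx
    dy = rows - cy
    mu20 = float(np.mean(dx * dx))
    mu02 = float(np.mean(dy * dy))
    mu11 = float(np.mean(dx * dy))
    return mu20, mu11, mu02, cx, cy


def ellipse_from_coords(coords: np.ndarray) -> dict:
    """Moments-ellipse parameters of a pixel list.

    Returns major/minor axis lengths (4*sqrt(eigenvalue), the diameter
    convention), eccentricity e = sqrt(1 - lambda_min/lambda_max),
    orientation of the major axis in degrees in (-90, 90] measured from
    the x-axis (columns) with y increasing downward, and the centroid.

    Degenerate conventions: a single pixel gives e = 0, axes = 1 px; a
    perfectly collinear pixel set gives e = 1 - 1e-9 with
    ``degenerate=True``.
    """
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (N, 2) array of (row, col)")
    mu20, mu11, mu02, cx, cy = _central_moments(coords)

    # eigenvalues of [[mu20, mu11], [mu11, mu02]]
    tr = mu20 + mu02
    det_term = math.sqrt(max((mu20 - mu02) ** 2 + 4.0 * mu11**2, 0.0))
    lam_max = (tr + det_term) / 2.0
    lam_min = (tr - det_term) / 2.0
    lam_min = max(lam_min, 0.0)

    degenerate = False
    if lam_max <= 0.0:  # single pixel
        return {
            "eccentricity": 0.0,
            "major_axis_length": 1.0,
            "minor_axis_length": 1.0,
            "orientation": 0.0,
            "centroid_x": cx,
            "centroid_y": cy,
            "degenerate": False,
        }
    if lam_min == 0.0:  # collinear pixels
        ecc = 1.0 - 1e-9
        degenerate = True
    else:
        ecc = math.sqrt(1.0 - lam_min / lam_max)

    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    deg = math.degrees(theta)
    if deg <= -90.0:
        deg += 180.0
    elif deg > 90.0:
        deg -= 180.0

    return {
        "eccentricity": ecc,
        "major_axis_length": 4.0 * math.sqrt(lam_max),
        "minor_axis_length": 4.0 * math.sqrt(lam_min) if lam_min > 0 else 1.0,
        "orientation": deg,
        "centroid_x": cx,
        "centroid_y": cy,
        "degenerate": degenerate,
    }


def eccentricity_from_moments(obj: np.ndarray) -> float:
    """Eccentricity of a binary object (mask) or pixel list from its
    second central moments.

    e = sqrt(1 - lambda_min / lambda_max) with lambda the eigenvalues of
    the pixel covariance matrix.  Collinear pixel sets return the 1-1e-9
    convention (flagged via a logged warning).
    """
    obj = np.asarray(obj)
    if obj.ndim == 2 and obj.shape[1] != 2:
        coords = np.argwhere(obj)
    elif obj.ndim == 2:
        coords = obj
    else:
        raise ValueError("expected a 2-D mask or an (N, 2) pixel list")
    if len(coords) < 2:
        raise ValueError("object area must be >= 2 px")
    res = ellipse_from_coords(coords)
    if res["degenerate"]:
        logger.warning("collinear object: eccentricity set to 1 - 1e-9")
    return res["eccentricity"]


def _pixel_corner_points(coords: np.ndarray) -> np.ndarray:
    """The four corners of every pixel, as (x, y) points."""
    rows = coords[:, 0].astype(float)
    cols = coords[:, 1].astype(float)
    pts = np.concatenate(
        [
            np.stack([cols - 0.5, rows - 0.5], axis=1),
            np.stack([cols + 0.5, rows - 0.5], axis=1),
            np.stack([cols - 0.5, rows + 0.5], axis=1),
            np.stack([cols + 0.5, rows + 0.5], axis=1),
        ]
    )
    return np.unique(pts, axis=0)


def _feret_diameters(coords: np.ndarray) -> tuple[float, float]:
    """(min, max) Feret diameters from the convex hull of pixel corners.

    Max Feret = largest pairwise hull-vertex distance; min Feret = the
    smallest hull width over directions normal to hull edges (for a
    convex polygon the minimum width is attained on an edge normal).
    """
    pts = _pixel_corner_points(coords)
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:
        verts = pts  # tiny/degenerate object: use all corner points
    diffs = verts[:, None, :] - verts[None, :, :]
    dmax = float(np.sqrt((diffs**2).sum(axis=2)).max())

    n = len(verts)
    widths = []
    for i in range(n):
        p0 = verts[i]
        p1 = verts[(i + 1) % n]
        edge = p1 - p0
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        proj = (verts - p0) @ normal
        widths.append(float(proj.max() - proj.min()))
    dmin = min(widths) if widths else dmax
    return dmin, dmax


def zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Radial Zernike polynomial R_nm evaluated at radii ``rho``."""
    out = np.zeros_like(rho, dtype=float)
    for s in range((n - m) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out += c * rho ** (n - 2 * s)
    return out


def zernike_magnitudes(coords: np.ndarray, bbox: tuple | None = None) -> np.ndarray:
    """Magnitudes of Zernike moments (orders n = 0..9) of a binary object.

    The object is mapped onto the unit disk circumscribing its bounding
    box (centre = bbox centre, radius = half the bbox diagonal) and
    treated as unit mass spread over its pixels, so the magnitudes are
    scale-normalised and rotation-invariant shape descriptors.
    """
    coords = np.asarray(coords, dtype=float)
    rows = coords[:, 0]
    cols = coords[:, 1]
    if bbox is None:
        bbox = (rows.min(), cols.min(), rows.max(), cols.max())
    rmin, cmin, rmax, cmax = bbox
    cy = (rmin + rmax) / 2.0
    cx = (cmin + cmax) / 2.0
    # +1 accounts for pixel extent so corners stay inside the disk
    radius = math.hypot(rmax - rmin + 1.0, cmax - cmin + 1.0) / 2.0
    dx = (cols - cx) / radius
    dy = (rows - cy) / radius
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    npix = len(coords)

    mags = np.empty(len(ZERNIKE_INDICES))
    for i, (n, m) in enumerate(ZERNIKE_INDICES):
        rad = zernike_radial(n, m, rho)
        re = float(np.sum(rad * np.cos(m * theta)))
        im = float(np.sum(rad * np.sin(m * theta)))
        mags[i] = (n + 1) / math.pi * math.hypot(re, im) / npix
    return mags


def _measure_one(coords: np.ndarray) -> dict:
    """The 53-descriptor vector for one object given its pixel list."""
    area = float(len(coords))

    # object mask cropped to bbox (pad 1 so edt sees the boundary)
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    mask = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
    mask[coords[:, 0] - rmin + 1, coords[:, 1] - cmin + 1] = True

    if area == 1.0:
        perim = 1.0  # convention for single-pixel objects
    else:
        perim = float(perimeter_crofton(mask, directions=4))
        perim = max(perim, 1.0)
    form_factor = min(1.0, 4.0 * math.pi * area / perim**2)

    ell = ellipse_from_coords(coords)

    # radii from the Euclidean distance transform inside the object
    edt = ndimage.distance_transform_edt(mask)
    radii = edt[mask]

    dmin, dmax = _feret_diameters(coords)

    bbox_h = float(rmax - rmin + 1)
    bbox_w = float(cmax - cmin + 1)
    bbox_area = bbox_h * bbox_w
    bbox_aspect = max(bbox_h, bbox_w) / min(bbox_h, bbox_w)

    # convex area as the pixel count of the convex hull image (the
    # rasterized convention, consistent with pixel-count area)
    if area >= 3:
        convex_area = float(convex_hull_image(mask).sum())
    else:
        convex_area = area
    solidity = min(1.0, area / convex_area) if convex_area > 0 else 1.0

    # Euler number on the cropped mask (8-connectivity objects)
    filled = ndimage.binary_fill_holes(mask)
    n_holes = cc_label(filled & ~mask, connectivity=1).max()
    euler = 1.0 - float(n_holes)

    extent = area / bbox_area

    feats = {
        "area": area,
        "perimeter": perim,
        "form_factor": form_factor,
        "solidity": solidity,
        "extent": extent,
        "euler_number": euler,
        "eccentricity": ell["eccentricity"],
        "major_axis_length": ell["major_axis_length"],
        "minor_axis_length": ell["minor_axis_length"],
        "orientation": ell["orientation"],
        "compactness": perim**2 / (4.0 * math.pi * area),
        "equivalent_diameter": math.sqrt(4.0 * area / math.pi),
        "max_radius": float(radii.max()),
        "mean_radius": float(radii.mean()),
        "median_radius": float(np.median(radii)),
        "min_feret_diameter": dmin,
        "max_feret_diameter": dmax,
        "bbox_area": bbox_area,
        "bbox_aspect_ratio": bbox_aspect,
        "centroid_x": ell["centroid_x"],
        "centroid_y": ell["centroid_y"],
        "convex_area": convex_area,
        "circularity_complement": 1.0 - form_factor,
    }
    for name, mag in zip(ZERNIKE_FEATURE_NAMES, zernike_magnitudes(coords)):
        feats[name] = float(mag)
    return feats


def measure_features(labels: LabeledNuclei | np.ndarray) -> pd.DataFrame:
    """Measure the fixed 53-descriptor vector for every labeled nucleus.

    Returns one row per nucleus with columns ``image_id``, ``nucleus_id``
    and the 53 feature columns in :data:`FEATURE_NAMES` order.  All
    values are finite; single-pixel objects follow documented
    conventions (perimeter 1, axes 1 px) rather than yielding NaN.
    """
    if isinstance(labels, LabeledNuclei):
        lab_img = labels.labels
        image_id = labels.image_id
        count = labels.count
    else:
        lab_img = np.asarray(labels)
        image_id = None
        count = int(lab_img.max())
    if count < 1:
        raise ValueError("no labeled objects to measure")

    rows = []
    obj_slices = ndimage.find_objects(lab_img)
    for lbl in range(1, count + 1):
        sl = obj_slices[lbl - 1]
        sub = lab_img[sl] == lbl
        coords = np.argwhere(sub)
        coords[:, 0] += sl[0].start
        coords[:, 1] += sl[1].start
        feats = _measure_one(coords)
        feats["image_id"] = image_id
        feats["nucleus_id"] = lbl
        rows.append(feats)

    df = pd.DataFrame(rows, columns=["image_id", "nucleus_id", *FEATURE_NAMES])
    if not np.isfinite(df[list(FEATURE_NAMES)].to_numpy(dtype=float)).all():
        raise AssertionError("non-finite feature value produced")
    return df


def aggregate_nuclei_by_sample(
    features: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample mean of each descriptor: per-image means averaged over
    the sample's images (matching per-sample averaging of randomly
    sampled fields of view).

    ``metadata`` maps ``image_id`` to ``sample_id`` (and optionally
    ``group``).  Samples contributing zero nuclei are dropped with a
    warning.  The output carries ``n_nuclei`` per sample.
    """
    required = {"image_id", "sample_id"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    merged = features.merge(
        metadata[[c for c in metadata.columns if c in ("image_id", "sample_id", "group")]],
        on="image_id",
        how="left",
    )
    if merged["sample_id"].isna().any():
        bad = sorted(features.loc[merged["sample_id"].isna(), "image_id"].unique())
        raise ValueError(f"images not present in metadata: {bad}")

    feat_cols = [c for c in FEATURE_NAMES if c in features.columns]
    per_image = merged.groupby(["sample_id", "image_id"], sort=True)[feat_cols].mean()
    per_sample = per_image.groupby("sample_id", sort=True).mean()
    counts = merged.groupby("sample_id", sort=True).size().rename("n_nuclei")
    per_sample = per_sample.join(counts)

    all_samples = set(metadata["sample_id"].unique())
    dropped = all_samples - set(per_sample.index)
    if dropped:
        warnings.warn(
            f"samples with zero nuclei dropped: {sorted(dropped)}", stacklevel=2
        )
    if "group" in metadata.columns:
        grp = metadata.drop_duplicates("sample_id").set_index("sample_id")["group"]
        per_sample = per_sample.join(grp)
    if per_sample.empty:
        warnings.warn("empty cohort: no samples with nuclei", stacklevel=2)
    return per_sample.reset_index()
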