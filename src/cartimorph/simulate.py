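"""Synthetic cohort generator for the cartilage-aging image pipeline.

Emulates the statistical structure of an aging histology study on three
ordinal age groups (young=0, middle=1, aged=2):

- per-sample cartilage surface masks whose roughness amplitude (the mean
  absolute deviation of the surface from a smooth quartic baseline)
  increases with age group,
- DAPI-style nuclei images: non-overlapping rotated ellipses whose
  analytic eccentricity distribution shifts upward with age,
- a paired marker channel (an alpha-Klotho-like longevity marker) whose
  per-nucleus integrated intensity is intercept(group) + slope * e +
  noise, decreasing with age and negatively related to eccentricity.

Every generated object is recorded once in ground-truth tables, so all
downstream recovery tests can read truth without touching pixels.  A
fixed seed yields a bit-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS: tuple[str, ...] = ("young", "middle", "aged")
GROUP_CODES: dict[str, int] = {g: i for i, g in enumerate(GROUPS)}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a murine aging cohort: 5 animals per age group, 5
    randomly selected fields of view per animal, 6-12 nuclei per field
    (30-60 nuclei per animal), an eccentricity shift of about two
    within-animal SDs between young and aged, surface roughness rising
    from 1 px to 4 px, and a marker channel that loses intensity with
    age and with eccentricity.
    """

    n_samples_per_group: int = 5
    groups: tuple[str, ...] = GROUPS
    images_per_sample: int = 5
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0
    roughness_amplitude_by_group: dict[str, float] = field(
        default_factory=lambda: {"young": 1.0, "middle": 2.0, "aged": 4.0}
    )
    eccentricity_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"young": 0.57, "middle": 0.67, "aged": 0.77}
    )
    eccentricity_sd: float = 0.06
    # between-animal SD of the eccentricity mean: real cohorts vary by
    # animal, and without it age and mean eccentricity are near-collinear
    eccentricity_sample_sd: float = 0.025
    marker_intensity_slope_vs_eccentricity: float = -300.0
    marker_intensity_intercept_by_group: dict[str, float] = field(
        default_factory=lambda: {"young": 800.0, "middle": 650.0, "aged": 500.0}
    )
    intensity_noise_sd: float = 50.0
    nuclei_per_image: tuple[int, int] = (6, 12)
    min_nucleus_separation: float = 4.0
    nucleus_semi_major_range: tuple[float, float] = (9.5, 10.5)
    # fractional radial boundary irregularity (Fourier modes 3-6): real
    # nuclei are not perfect ellipses, and the wobble decorrelates the
    # otherwise deterministic relations among the shape descriptors
    boundary_irregularity: float = 0.05
    surface_smooth_window: int = 5

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1 or self.images_per_sample < 1:
            raise ValueError("counts must be positive")
        if any(d < 8 for d in self.image_size):
            raise ValueError("image_size too small")
        for g in self.groups:
            if g not in GROUP_CODES:
                raise ValueError(f"unknown group {g!r}; expected {GROUPS}")
            e = self.eccentricity_mean_by_group[g]
            if not 0.0 <= e < 1.0:
                raise ValueError("eccentricity means must lie in [0, 1)")
            if self.roughness_amplitude_by_group[g] < 0:
                raise ValueError("roughness amplitudes must be >= 0")
        if self.eccentricity_sd < 0 or self.eccentricity_sample_sd < 0:
            raise ValueError("eccentricity SDs must be >= 0")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")
        lo, hi = self.nuclei_per_image
        if lo < 0 or hi < lo:
            raise ValueError("invalid nuclei_per_image range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = list(self.groups)
        d["image_size"] = list(self.image_size)
        d["nuclei_per_image"] = list(self.nuclei_per_image)
        d["nucleus_semi_major_range"] = list(self.nucleus_semi_major_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("groups", "image_size", "nuclei_per_image", "nucleus_semi_major_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def analytic_eccentricity(a: float, b: float) -> float:
    """e = sqrt(1 - (b/a)^2) for semi-axes a >= b > 0."""
    if not a >= b > 0:
        raise ValueError("require a >= b > 0")
    return math.sqrt(1.0 - (b / a) ** 2)


# ---------------------------------------------------------------------------
# surfaces


def generate_surface_mask(
    width: int,
    height: int,
    baseline: np.ndarray,
    roughness_amplitude: float,
    seed,
    smooth_window: int = 1,
) -> tuple[np.ndarray, dict]:
    """Binary tissue mask whose top surface is a quartic baseline plus a
    zero-mean perturbation of known mean absolute amplitude.

    ``baseline`` holds coefficients c0..c4 (row = c0 + c1 x + ... in
    pixel units, rows growing downward); the mask is filled below the
    perturbed surface with exactly one surface pixel per column.  The
    per-column perturbation is i.i.d. Gaussian, optionally smoothed with
    a short moving average (``smooth_window``) to mimic tissue-scale
    undulation, then rescaled so its expected mean absolute value equals
    ``roughness_amplitude``.  The returned truth row stores the realized
    mean absolute perturbation.
    """
    rng = _as_rng(seed)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (5,):
        raise ValueError("baseline must be 5 quartic coefficients c0..c4")
    x = np.arange(width, dtype=float)
    base = baseline[0] + baseline[1] * x + baseline[2] * x**2 + baseline[3] * x**3 + baseline[4] * x**4
    bad = np.nonzero((base < 0) | (base > height - 1))[0]
    if len(bad):
        raise ValueError(
            f"baseline curve exits image bounds at column {int(bad[0])}"
        )

    if roughness_amplitude > 0:
        # E|N(0, s^2)| = s * sqrt(2/pi)  =>  s = amplitude * sqrt(pi/2)
        pert = rng.normal(0.0, roughness_amplitude * math.sqrt(math.pi / 2.0), width)
        if smooth_window > 1:
            kernel = np.ones(smooth_window) / smooth_window
            pad = smooth_window // 2
            padded = np.pad(pert, pad, mode="reflect")
            pert = np.convolve(padded, kernel, mode="valid")[:width]
            sd = pert.std()
            if sd > 0:  # restore the target scale lost to smoothing
                pert *= roughness_amplitude * math.sqrt(math.pi / 2.0) / sd
    else:
        pert = np.zeros(width)

    surface = np.rint(base + pert).astype(int)
    bad = np.nonzero((surface < 0) | (surface > height - 1))[0]
    if len(bad):
        raise ValueError(
            f"perturbed surface exits image bounds at column {int(bad[0])}"
        )

    mask = np.zeros((height, width), dtype=np.uint8)
    rows = np.arange(height)[:, None]
    mask[rows >= surface[None, :]] = 255
    truth = {
        "amplitude_param": float(roughness_amplitude),
        "realized_amplitude": float(np.mean(np.abs(pert))),
        "baseline_c0": baseline[0],
        "baseline_c1": baseline[1],
        "baseline_c2": baseline[2],
        "baseline_c3": baseline[3],
        "baseline_c4": baseline[4],
    }
    return mask, truth


def _random_baseline(width: int, height: int, rng: np.random.Generator) -> np.ndarray:
    """Gentle random quartic baseline that stays well inside the image."""
    x_ctrl = np.linspace(0, width - 1, 5)
    for _ in range(50):
        y_ctrl = height * (0.45 + rng.uniform(-0.06, 0.06, 5))
        coeffs = np.polynomial.polynomial.polyfit(x_ctrl, y_ctrl, 4)
        x = np.arange(width)
        curve = np.polynomial.polynomial.polyval(x, coeffs)
        if curve.min() > 0.2 * height and curve.max() < 0.8 * height:
            return coeffs
    raise RuntimeError("could not draw a baseline inside image bounds")


# ---------------------------------------------------------------------------
# nuclei


#: Fourier mode numbers used for nuclear boundary irregularity.  Modes
#: k >= 3 leave the centroid and the moments ellipse nearly unchanged
#: (mode 1 would translate the object, mode 2 would alter elongation).
BOUNDARY_MODES: tuple[int, ...] = (3, 4, 5, 6)


def _ellipse_coords(
    cy: float,
    cx: float,
    a: float,
    b: float,
    phi_deg: float,
    shape: tuple[int, int],
    modes: tuple[tuple[int, float, float], ...] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (rows, cols) inside a rotated, optionally wobbled ellipse.

    phi is the major-axis angle from the x-axis (columns) with y (rows)
    increasing downward, matching the morphometry orientation convention.
    ``modes`` holds (k, amplitude, phase) triples: the boundary in the
    ellipse's normalised frame is rho = 1 + sum_k amp*cos(k*psi + phase).
    """
    phi = math.radians(phi_deg)
    inflate = 1.0 + sum(abs(alpha) for _, alpha, _ in modes)
    pad = a * inflate + 2
    r0 = max(int(math.floor(cy - pad)), 0)
    r1 = min(int(math.ceil(cy + pad)), shape[0] - 1)
    c0 = max(int(math.floor(cx - pad)), 0)
    c1 = min(int(math.ceil(cx + pad)), shape[1] - 1)
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    dx = cc - cx
    dy = rr - cy
    u = (dx * math.cos(phi) + dy * math.sin(phi)) / a
    v = (-dx * math.sin(phi) + dy * math.cos(phi)) / b
    rho = np.hypot(u, v)
    if modes:
        psi = np.arctan2(v, u)
        limit = np.ones_like(rho)
        for k, alpha, phase in modes:
            limit += alpha * np.cos(k * psi + phase)
        inside = rho <= limit
    else:
        inside = rho <= 1.0
    return rr[inside], cc[inside]


def _modes_from_record(rec: dict) -> tuple[tuple[int, float, float], ...]:
    """Boundary modes of one truth row (empty when columns are absent)."""
    modes = []
    for k in BOUNDARY_MODES:
        alpha = rec.get(f"alpha_{k}")
        if alpha is None or (isinstance(alpha, float) and math.isnan(alpha)):
            continue
        if alpha != 0.0:
            modes.append((k, float(alpha), float(rec.get(f"phase_{k}", 0.0))))
    return tuple(modes)


def place_nuclei(
    shape: tuple[int, int],
    n_nuclei: int,
    eccentricity_mean: float,
    eccentricity_sd: float,
    rng,
    min_separation: float = 4.0,
    semi_major_range: tuple[float, float] = (9.5, 10.5),
    boundary_irregularity: float = 0.05,
    max_tries_per_nucleus: int = 500,
) -> pd.DataFrame:
    """Draw non-overlapping nucleus geometries (no rendering).

    Eccentricities are Gaussian(mean, sd) truncated to [0, 0.95]; the
    semi-major axis is uniform in ``semi_major_range``; orientation is
    uniform in (-90, 90].  Each nucleus also carries a smooth boundary
    wobble (Fourier modes 3-6, fractional amplitude
    ``boundary_irregularity``), recorded per mode in the output.
    Centers are rejection-sampled so that the center distance of any
    pair exceeds the sum of their wobble-inflated semi-major axes plus
    ``min_separation``: objects can never touch.

    The recorded ``eccentricity`` is the analytic value of the base
    ellipse, sqrt(1 - (b/a)^2); modes >= 3 leave the moments ellipse
    essentially unchanged.
    """
    rng = _as_rng(rng)
    if not 0.0 <= eccentricity_mean < 1.0:
        raise ValueError("eccentricity_mean must lie in [0, 1)")
    if boundary_irregularity < 0:
        raise ValueError("boundary_irregularity must be >= 0")
    rows = []
    centers: list[tuple[float, float]] = []
    radii: list[float] = []  # wobble-inflated semi-major axes
    a_lo, a_hi = semi_major_range
    amp = boundary_irregularity
    max_inflate = 1.0 + len(BOUNDARY_MODES) * 2.5 * amp
    margin = a_hi * max_inflate + 2.0
    if shape[0] <= 2 * margin or shape[1] <= 2 * margin:
        raise ValueError("image too small for the requested nucleus size")
    for i in range(n_nuclei):
        placed = False
        for _ in range(max_tries_per_nucleus):
            a = rng.uniform(a_lo, a_hi)
            e = float(np.clip(rng.normal(eccentricity_mean, eccentricity_sd), 0.0, 0.95))
            b = a * math.sqrt(1.0 - e * e)
            phi = rng.uniform(-90.0, 90.0)
            if amp > 0:
                alphas = np.clip(
                    rng.normal(0.0, amp, len(BOUNDARY_MODES)), -2.5 * amp, 2.5 * amp
                )
                phases = rng.uniform(0.0, 2.0 * math.pi, len(BOUNDARY_MODES))
            else:
                alphas = np.zeros(len(BOUNDARY_MODES))
                phases = np.zeros(len(BOUNDARY_MODES))
            inflate = 1.0 + float(np.sum(np.abs(alphas)))
            cy = rng.uniform(margin, shape[0] - margin)
            cx = rng.uniform(margin, shape[1] - margin)
            ok = all(
                math.hypot(cy - py, cx - px) >= a * inflate + pa + min_separation
                for (py, px), pa in zip(centers, radii)
            )
            if ok:
                centers.append((cy, cx))
                radii.append(a * inflate)
                row = {
                    "nucleus_id": i + 1,
                    "center_y": cy,
                    "center_x": cx,
                    "semi_major": a,
                    "semi_minor": b,
                    "orientation_deg": phi,
                    "eccentricity": analytic_eccentricity(a, b) if b < a else 0.0,
                }
                for k, alpha, phase in zip(BOUNDARY_MODES, alphas, phases):
                    row[f"alpha_{k}"] = float(alpha)
                    row[f"phase_{k}"] = float(phase)
                rows.append(row)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {i + 1}/{n_nuclei} without violating "
                f"the {min_separation} px separation after "
                f"{max_tries_per_nucleus} tries"
            )
    columns = [
        "nucleus_id", "center_y", "center_x", "semi_major", "semi_minor",
        "orientation_deg", "eccentricity",
    ] + [f"{p}_{k}" for k in BOUNDARY_MODES for p in ("alpha", "phase")]
    return pd.DataFrame(rows, columns=columns)


def render_nuclei_image(
    shape: tuple[int, int],
    nuclei: pd.DataFrame,
    rng,
    background: float = 300.0,
    background_sd: float = 30.0,
    foreground: float = 10000.0,
    foreground_sd: float = 500.0,
) -> np.ndarray:
    """Render placed nuclei as a 16-bit DAPI-style grayscale image."""
    rng = _as_rng(rng)
    img = rng.normal(background, background_sd, shape)
    for rec in nuclei.to_dict("records"):
        rr, cc = _ellipse_coords(
            rec["center_y"], rec["center_x"], rec["semi_major"], rec["semi_minor"],
            rec["orientation_deg"], shape, _modes_from_record(rec),
        )
        img[rr, cc] = rng.normal(foreground, foreground_sd, len(rr))
    return np.clip(img, 0, 65535).astype(np.uint16)


def render_marker_image(
    shape: tuple[int, int], nuclei: pd.DataFrame
) -> np.ndarray:
    """Render the marker channel: each nucleus's programmed integrated
    intensity spread evenly over its pixels, zero background.

    The image is float32 so the programmed per-nucleus totals are exact;
    ``nuclei`` must carry a ``marker_intensity`` column.
    """
    img = np.zeros(shape, dtype=np.float64)
    for rec in nuclei.to_dict("records"):
        rr, cc = _ellipse_coords(
            rec["center_y"], rec["center_x"], rec["semi_major"], rec["semi_minor"],
            rec["orientation_deg"], shape, _modes_from_record(rec),
        )
        if len(rr) == 0:
            continue
        img[rr, cc] = rec["marker_intensity"] / len(rr)
    return img.astype(np.float32)


def generate_nuclei_image(
    n_nuclei: int,
    eccentricity_mean: float,
    eccentricity_sd: float,
    seed,
    shape: tuple[int, int] = (256, 256),
    min_separation: float = 4.0,
    semi_major_range: tuple[float, float] = (9.5, 10.5),
    boundary_irregularity: float = 0.05,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Grayscale nuclei image plus its ground-truth geometry table.

    ``n_nuclei = 0`` yields a valid background-only image and an empty
    truth table.
    """
    rng = _as_rng(seed)
    nuclei = place_nuclei(
        shape, n_nuclei, eccentricity_mean, eccentricity_sd, rng,
        min_separation=min_separation, semi_major_range=semi_major_range,
        boundary_irregularity=boundary_irregularity,
    )
    img = render_nuclei_image(shape, nuclei, rng)
    return img, nuclei


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort_truth(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the full cohort ground truth without rendering any pixels.

    Returns ``(metadata, nuclei_truth, surface_truth)``:

    - metadata: one row per image (sample_id, group, group_code, sex,
      image_id),
    - nuclei_truth: one row per nucleus with geometry, analytic
      eccentricity and the programmed marker intensity,
    - surface_truth: one row per sample with baseline coefficients and
      the realized roughness amplitude.

    Rendering (:func:`generate_cohort`) consumes these same tables, so
    the pixel path and the table path share one cohort law.
    """
    root_ss = np.random.SeedSequence(config.seed)
    meta_rows = []
    nuc_frames = []
    surf_rows = []
    H, W = config.image_size
    sexes = ("M", "F")

    sample_idx = 0
    for group in config.groups:
        code = GROUP_CODES[group]
        for s in range(config.n_samples_per_group):
            sample_id = f"{group}_{s + 1:02d}"
            ss = np.random.SeedSequence(
                entropy=root_ss.entropy, spawn_key=(sample_idx,)
            )
            rng = np.random.default_rng(ss)
            sex = sexes[s % 2]

            baseline = _random_baseline(W, H, rng)
            _, surf_truth = generate_surface_mask(
                W, H, baseline,
                config.roughness_amplitude_by_group[group],
                rng, smooth_window=config.surface_smooth_window,
            )
            surf_truth.update(
                sample_id=sample_id, group=group, group_code=code,
                mask_id=f"{sample_id}_mask",
            )
            surf_rows.append(surf_truth)

            ecc_sample_mean = float(
                np.clip(
                    rng.normal(
                        config.eccentricity_mean_by_group[group],
                        config.eccentricity_sample_sd,
                    ),
                    0.0, 0.93,
                )
            )
            intercept = config.marker_intensity_intercept_by_group[group]
            slope = config.marker_intensity_slope_vs_eccentricity

            for j in range(config.images_per_sample):
                image_id = f"{sample_id}_img{j + 1:02d}"
                n_nuc = int(rng.integers(config.nuclei_per_image[0],
                                         config.nuclei_per_image[1] + 1))
                nuclei = place_nuclei(
                    (H, W), n_nuc, ecc_sample_mean, config.eccentricity_sd, rng,
                    min_separation=config.min_nucleus_separation,
                    semi_major_range=config.nucleus_semi_major_range,
                    boundary_irregularity=config.boundary_irregularity,
                )
                noise = (
                    rng.normal(0.0, config.intensity_noise_sd, len(nuclei))
                    if config.intensity_noise_sd > 0
                    else np.zeros(len(nuclei))
                )
                nuclei["marker_intensity"] = (
                    intercept + slope * nuclei["eccentricity"] + noise
                )
                if (nuclei["marker_intensity"] <= 0).any():
                    raise ValueError(
                        "programmed marker intensity fell to <= 0; "
                        "raise the intercepts or lower the noise SD"
                    )
                nuclei.insert(0, "image_id", image_id)
                nuclei.insert(0, "sample_id", sample_id)
                nuclei["group"] = group
                nuclei["group_code"] = code
                nuc_frames.append(nuclei)
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "group_code": code,
                        "sex": sex,
                        "image_id": image_id,
                        "ecc_sample_mean": ecc_sample_mean,
                    }
                )
            sample_idx += 1

    metadata = pd.DataFrame(meta_rows)
    nuclei_truth = (
        pd.concat(nuc_frames, ignore_index=True)
        if nuc_frames
        else pd.DataFrame()
    )
    surface_truth = pd.DataFrame(surf_rows)
    return metadata, nuclei_truth, surface_truth


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> dict:
    """Generate the cohort on disk: images, masks, metadata and truth.

    Layout::

        out/
          metadata.csv          one row per image, with file paths
          truth_nuclei.csv      per-nucleus ground truth
          truth_surfaces.csv    per-sample surface ground truth
          control_marker.tif    negative-control marker image
          <sample_id>/mask.png  8-bit surface mask, one per sample
          <sample_id>/<image_id>_dapi.tif    16-bit nuclei channel
          <sample_id>/<image_id>_marker.tif  float32 marker channel

    Deterministic under a fixed config seed (bit-identical images and
    byte-identical CSVs).  Returns the main output paths.
    """
    from cartimorph.io import write_image, write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata, nuclei_truth, surface_truth = simulate_cohort_truth(config)

    H, W = config.image_size
    root_ss = np.random.SeedSequence(config.seed)
    render_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=root_ss.entropy, spawn_key=(10_000,))
    )

    # per-sample surface masks, re-rendered from the recorded truth
    mask_paths = {}
    for pos, rec in enumerate(surface_truth.to_dict("records")):
        sample_dir = out / rec["sample_id"]
        sample_dir.mkdir(exist_ok=True)
        baseline = np.array([rec[f"baseline_c{k}"] for k in range(5)])
        # the per-sample truth stream has advanced past this point, so the
        # on-disk mask is drawn from its own child stream and the recorded
        # realized amplitude is re-measured from that draw below
        mask_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root_ss.entropy, spawn_key=(20_000, pos))
        )
        mask, truth = generate_surface_mask(
            W, H, baseline, rec["amplitude_param"], mask_rng,
            smooth_window=config.surface_smooth_window,
        )
        surface_truth.loc[
            surface_truth["sample_id"] == rec["sample_id"], "realized_amplitude"
        ] = truth["realized_amplitude"]
        path = sample_dir / "mask.png"
        write_image(path, mask)
        mask_paths[rec["sample_id"]] = str(path.relative_to(out))

    dapi_paths, marker_paths = [], []
    for (sample_id, image_id), nuc in nuclei_truth.groupby(
        ["sample_id", "image_id"], sort=False
    ):
        sample_dir = out / sample_id
        dapi = render_nuclei_image((H, W), nuc, render_rng)
        marker = render_marker_image((H, W), nuc)
        dapi_path = sample_dir / f"{image_id}_dapi.tif"
        marker_path = sample_dir / f"{image_id}_marker.tif"
        write_image(dapi_path, dapi)
        write_image(marker_path, marker)
        dapi_paths.append((image_id, str(dapi_path.relative_to(out))))
        marker_paths.append((image_id, str(marker_path.relative_to(out))))

    path_map = dict(dapi_paths)
    marker_map = dict(marker_paths)
    metadata = metadata.copy()
    metadata["dapi_path"] = metadata["image_id"].map(path_map)
    metadata["marker_path"] = metadata["image_id"].map(marker_map)
    metadata["mask_path"] = metadata["sample_id"].map(mask_paths)

    # negative control: faint background only, used to set the threshold
    control = np.abs(render_rng.normal(0.02, 0.01, (H, W))).astype(np.float32)
    write_image(out / "control_marker.tif", control)

    write_table(out / "metadata.csv", metadata)
    write_table(out / "truth_nuclei.csv", nuclei_truth)
    write_table(out / "truth_surfaces.csv", surface_truth)

    return {
        "out_dir": str(out),
        "metadata": str(out / "metadata.csv"),
        "truth_nuclei": str(out / "truth_nuclei.csv"),
        "truth_surfaces": str(out / "truth_surfaces.csv"),
        "control_marker": str(out / "control_marker.tif"),
    }
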