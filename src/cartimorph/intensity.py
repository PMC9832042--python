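"""Per-cell fluorescence quantification.

Integrated density (the sum of above-threshold pixel values of one
marker channel) divided by the number of cells in the image, with the
threshold taken from a negative-control slide, random selection of
fields of view, and per-sample averaging.  Cell counts come from nuclei
segmentation of the paired DAPI channel, never from marker-channel
objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cartimorph.morphometry import LabeledNuclei


@dataclass
class CellIntensityRecord:
    """Whole-image integrated density normalised by cell count."""

    image_id: str | None
    channel: str
    integrated_density: float
    cell_count: int
    intensity_per_cell: float
    threshold: float

    def __post_init__(self) -> None:
        if self.cell_count < 1:
            raise ValueError("cell_count must be >= 1 for a valid record")
        if self.intensity_per_cell < 0:
            raise ValueError("intensity_per_cell must be >= 0")


def intensity_per_cell(
    marker: np.ndarray,
    nuclei: LabeledNuclei | int,
    threshold: float,
    channel: str = "marker",
    image_id: str | None = None,
) -> CellIntensityRecord:
    """Integrated density of one marker image divided by its cell count.

    The integrated density sums pixel values strictly above ``threshold``
    over the whole image (a per-object mode is deliberately not the
    default; whole-image density matches per-channel quantification with
    a counterstain-based cell count).
    """
    marker = np.asarray(marker, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if isinstance(nuclei, LabeledNuclei):
        if nuclei.labels.shape != marker.shape:
            raise ValueError("marker image and label image must share a shape")
        count = nuclei.count
        if image_id is None:
            image_id = nuclei.image_id
    else:
        count = int(nuclei)
    if count < 1:
        raise ValueError("no cells in image")
    density = float(marker[marker > threshold].sum())
    return CellIntensityRecord(
        image_id=image_id,
        channel=channel,
        integrated_density=density,
        cell_count=count,
        intensity_per_cell=density / count,
        threshold=float(threshold),
    )


def threshold_from_negative_control(control: np.ndarray, q: float = 0.999) -> float:
    """Signal threshold from a negative-control image.

    The threshold is the ``q`` quantile of the control's pixel
    intensities (q = 1 gives the control maximum); the same threshold is
    applied to every image of the experiment.
    """
    control = np.asarray(control, dtype=float)
    if control.size == 0:
        raise ValueError("empty control image")
    if not 0.0 <= q <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    return float(np.quantile(control, q))


def sample_images(images: list, k: int, seed) -> list:
    """Uniform random subset of ``k`` images without replacement.

    Seed-deterministic; the selection is returned in original list order.
    """
    if k > len(images):
        raise ValueError(f"cannot sample {k} from {len(images)} images")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    idx = np.sort(rng.choice(len(images), size=k, replace=False))
    return [images[i] for i in idx]


def aggregate_intensity_by_sample(
    records: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample mean of intensity_per_cell over the sampled images.

    ``records`` needs ``image_id`` and ``intensity_per_cell``;
    ``metadata`` maps ``image_id`` to ``sample_id`` (plus optional group
    columns).  n is the number of samples, never pooled images or cells.
    Samples with zero valid records are dropped with a warning.
    """
    required = {"image_id", "intensity_per_cell"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing required columns: {sorted(missing)}")
    keep = [
        c for c in ("image_id", "sample_id", "group", "group_code")
        if c in metadata.columns
    ]
    merged = records.merge(metadata[keep].drop_duplicates("image_id"),
                           on="image_id", how="left")
    if merged["sample_id"].isna().any():
        bad = sorted(merged.loc[merged["sample_id"].isna(), "image_id"].unique())
        raise ValueError(f"images not present in metadata: {bad}")
    group_cols = [c for c in ("sample_id", "group", "group_code") if c in merged.columns]
    out = (
        merged.groupby(group_cols, sort=True)["intensity_per_cell"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "intensity_per_cell", "size": "n_images"})
        .reset_index()
    )
    dropped = set(metadata["sample_id"].unique()) - set(out["sample_id"])
    if dropped:
        warnings.warn(
            f"samples with no valid intensity records dropped: {sorted(dropped)}",
            stacklevel=2,
        )
    return out
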