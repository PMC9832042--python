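"""End-to-end pipeline: simulate -> roughness -> nuclei -> intensity ->
PCA / association regressions, with a JSON report.

Each stage draws its randomness from a sub-stream spawned from the single
configured seed, so a fixed config reproduces the identical report and
any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import cartimorph
from cartimorph import io as cio
from cartimorph.intensity import (
    aggregate_intensity_by_sample,
    intensity_per_cell,
    sample_images,
    threshold_from_negative_control,
)
from cartimorph.morphometry import (
    aggregate_nuclei_by_sample,
    measure_features,
    segment_nuclei,
)
from cartimorph.roughness import roughness_by_group
from cartimorph.simulate import CohortConfig, generate_cohort
from cartimorph.stats import (
    group_separation,
    regress_marker_on_morphology,
    regress_trend,
    run_pca,
    zscore,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    ``simulate`` holds a :class:`CohortConfig` mapping when the cohort is
    generated in place; otherwise ``data_dir`` must point at an existing
    cohort directory with ``metadata.csv``.
    """

    out_dir: str = "cartimorph_out"
    data_dir: str | None = None
    seed: int = 0
    simulate: dict | None = None
    min_area: float = 50.0
    max_area: float = 5000.0
    control_quantile: float = 0.999
    images_per_sample_k: int | None = None
    pca_k_top: int = 10
    roughness_metric: str = "mad"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def _regression_block(out) -> dict:
    return {
        "params": {k: float(v) for k, v in out.params.items()},
        "bse": {k: float(v) for k, v in out.bse.items()},
        "conf_int": {k: list(map(float, v)) for k, v in out.conf_int.items()},
        "pvalues": {k: float(v) for k, v in out.pvalues.items()},
        "r_squared": out.r_squared,
        "partial_r_squared": {
            k: float(v) for k, v in out.partial_r_squared.items()
        },
        "nobs": out.nobs,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on one cohort and write the report bundle.

    Outputs under ``config.out_dir``: ``roughness.csv``,
    ``nuclei_features.csv``, ``sample_features.csv``, ``intensity.csv``,
    ``sample_intensity.csv``, ``pca_scores.csv``, ``pca_loadings.csv``,
    ``top_contributors.csv``, ``regressions.json``, ``report.json`` and
    the resolved ``config.yaml``.  Raises at the first failing stage,
    naming it; partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"warnings": []}

    # stage: simulate or locate data
    if config.simulate is not None:
        cohort_cfg = CohortConfig.from_dict(config.simulate)
        data_dir = Path(config.data_dir or out / "cohort")
        generate_cohort(cohort_cfg, data_dir)
    elif config.data_dir is not None:
        data_dir = Path(config.data_dir)
    else:
        raise ValueError("stage simulate: need either a simulate block or data_dir")

    meta_path = data_dir / "metadata.csv"
    try:
        metadata = cio.read_table(
            meta_path,
            required=("sample_id", "group", "group_code", "image_id",
                      "dapi_path", "marker_path", "mask_path"),
        )
    except (FileNotFoundError, ValueError) as exc:
        raise RuntimeError(f"stage metadata: {exc}") from exc

    resolved = config.to_dict()
    cio.write_config(out / "config.yaml", resolved)
    # hash the analysis parameters only: where outputs land is not part
    # of the scientific configuration
    hashed = {k: v for k, v in resolved.items() if k not in ("out_dir", "data_dir")}
    cfg_hash = hashlib.sha256(
        cio.yaml.safe_dump(hashed, sort_keys=True).encode()
    ).hexdigest()

    ss = np.random.SeedSequence(config.seed)
    sampling_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=(1,))
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # stage: roughness (one mask per sample)
        try:
            mask_meta = metadata.drop_duplicates("sample_id")
            masks = {
                rec["sample_id"] + "_mask": cio.read_image(data_dir / rec["mask_path"])
                for rec in mask_meta.to_dict("records")
            }
            rough_meta = mask_meta.assign(
                image_id=mask_meta["sample_id"] + "_mask"
            )[["image_id", "sample_id", "group", "group_code"]]
            rough_table, rough_trend = roughness_by_group(
                masks, rough_meta, metric=config.roughness_metric
            )
            cio.write_table(out / "roughness.csv", rough_table)
        except Exception as exc:
            raise RuntimeError(f"stage roughness: {exc}") from exc

        # stage: image sampling (k random fields of view per sample)
        k = config.images_per_sample_k
        if k is not None:
            selected = []
            for sample_id, sub in metadata.groupby("sample_id", sort=True):
                ids = sub["image_id"].tolist()
                selected.extend(sample_images(ids, min(k, len(ids)), sampling_rng))
            metadata = metadata[metadata["image_id"].isin(selected)]

        # stage: nuclei morphometry
        try:
            feature_frames = []
            labels_by_image = {}
            for rec in metadata.to_dict("records"):
                img = cio.read_image(data_dir / rec["dapi_path"])
                lab = segment_nuclei(
                    img, config.min_area, config.max_area, rec["image_id"]
                )
                labels_by_image[rec["image_id"]] = lab
                if lab.count:
                    feature_frames.append(measure_features(lab))
            if not feature_frames:
                raise ValueError("no nuclei found in any image")
            features = pd.concat(feature_frames, ignore_index=True)
            cio.write_table(out / "nuclei_features.csv", features)
            sample_features = aggregate_nuclei_by_sample(features, metadata)
            cio.write_table(out / "sample_features.csv", sample_features)
        except Exception as exc:
            raise RuntimeError(f"stage nuclei: {exc}") from exc

        # stage: intensity
        try:
            control_path = data_dir / "control_marker.tif"
            if control_path.exists():
                threshold = threshold_from_negative_control(
                    cio.read_image(control_path), config.control_quantile
                )
            else:
                threshold = 0.0
            records = []
            for rec in metadata.to_dict("records"):
                lab = labels_by_image[rec["image_id"]]
                if lab.count == 0:
                    report["warnings"].append(
                        f"image {rec['image_id']} has no cells: skipped"
                    )
                    continue
                marker = cio.read_image(data_dir / rec["marker_path"])
                r = intensity_per_cell(marker, lab, threshold, image_id=rec["image_id"])
                records.append(vars(r))
            intensity_table = pd.DataFrame(records)
            cio.write_table(out / "intensity.csv", intensity_table)
            sample_intensity = aggregate_intensity_by_sample(intensity_table, metadata)
            cio.write_table(out / "sample_intensity.csv", sample_intensity)
        except Exception as exc:
            raise RuntimeError(f"stage intensity: {exc}") from exc

        # stage: PCA (nuclei-level, for the separation plot) and ranking
        try:
            feat_cols = [c for c in features.columns
                         if c not in ("image_id", "nucleus_id")]
            z = zscore(features[feat_cols])
            pca = run_pca(z, k_top=config.pca_k_top)
            img_groups = metadata.set_index("image_id")["group"]
            nuc_groups = features["image_id"].map(img_groups).to_numpy()
            sep_all = group_separation(pca.scores, nuc_groups)
            extremes = np.isin(nuc_groups, ("young", "aged"))
            if extremes.sum() >= 6 and len(set(nuc_groups[extremes])) == 2:
                sep_extreme = group_separation(
                    pca.scores[extremes], nuc_groups[extremes]
                )
            else:
                sep_extreme = None
            cio.write_table(
                out / "pca_scores.csv",
                pca.scores.assign(group=nuc_groups).reset_index(drop=True),
            )
            cio.write_table(
                out / "pca_loadings.csv", pca.loadings.reset_index(names="feature")
            )
            top = pd.DataFrame(
                {
                    "rank": np.arange(1, len(pca.top_contributors["PC1"]) + 1),
                    "PC1": pca.top_contributors["PC1"],
                    "PC2": pca.top_contributors.get(
                        "PC2", [""] * len(pca.top_contributors["PC1"])
                    ),
                }
            )
            cio.write_table(out / "top_contributors.csv", top)
        except Exception as exc:
            raise RuntimeError(f"stage pca: {exc}") from exc

        # stage: regressions
        try:
            merged = sample_features.merge(
                sample_intensity[["sample_id", "intensity_per_cell"]],
                on="sample_id",
            ).merge(
                metadata.drop_duplicates("sample_id")[["sample_id", "group_code"]],
                on="sample_id",
            )
            ecc_trend = regress_trend(
                merged["eccentricity"].to_numpy(), merged["group_code"].to_numpy()
            )
            intensity_trend = regress_trend(
                merged["intensity_per_cell"].to_numpy(),
                merged["group_code"].to_numpy(),
            )
            marker_model = regress_marker_on_morphology(
                merged["intensity_per_cell"].to_numpy(),
                merged["eccentricity"].to_numpy(),
                merged["group_code"].to_numpy(),
            )
            regressions = {
                "roughness_age_trend": _regression_block(rough_trend),
                "eccentricity_age_trend": _regression_block(ecc_trend),
                "intensity_age_trend": _regression_block(intensity_trend),
                "marker_on_age_and_eccentricity": _regression_block(marker_model),
            }
            cio.write_json(out / "regressions.json", regressions)
        except Exception as exc:
            raise RuntimeError(f"stage regressions: {exc}") from exc

    report["warnings"].extend(str(w.message) for w in caught)
    report.update(
        {
            "provenance": {
                "config_sha256": cfg_hash,
                "seed": config.seed,
                "cartimorph_version": cartimorph.__version__,
                "n_samples": int(metadata["sample_id"].nunique()),
                "n_images": int(metadata["image_id"].nunique()),
                "n_nuclei": int(len(features)),
            },
            "roughness": {
                "per_sample_mean_R": float(rough_table["R"].mean()),
                "trend_slope": regressions["roughness_age_trend"]["params"][
                    "group_code"
                ],
                "trend_p": regressions["roughness_age_trend"]["pvalues"][
                    "group_code"
                ],
            },
            "pca": {
                "explained_variance_ratio": pca.explained_variance_ratio[:5].tolist(),
                "top_contributors_pc1": pca.top_contributors["PC1"],
                "silhouette_all_groups": sep_all["silhouette"],
                "silhouette_young_aged": (
                    sep_extreme["silhouette"] if sep_extreme else None
                ),
            },
            "intensity_threshold": float(threshold),
            "regressions": regressions,
        }
    )
    cio.write_json(out / "report.json", report)
    return report
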