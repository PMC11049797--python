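"""End-to-end orchestration: extract -> index -> summarize -> classify -> stats.

All randomness flows from one master seed through named substreams (UMAP,
splits), so a rerun with the same seed reproduces every output byte for
byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import EvalProtocol, UMAPParams, classify_by_colony
from .coloration_index import index_table, summarize_groups, validate_metadata
from .group_statistics import run_inference
from .image_io import read_image
from .profile_extraction import (
    DEFAULT_SAT_THRESHOLD,
    DEFAULT_TARGET_LENGTH,
    extract_profile,
)
from .tables import profiles_to_matrix, read_profiles, write_profiles

__all__ = ["RunConfig", "run_pipeline", "extract_profiles_from_dir"]

log = logging.getLogger("beecolor")

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    images_dir: str
    roi_table: str
    meta_table: str
    out_dir: str
    target_length: int = DEFAULT_TARGET_LENGTH
    sat_threshold: float = DEFAULT_SAT_THRESHOLD
    max_masked_fraction: float = 0.5
    label: str = "temperature"
    umap_neighbors: int = 75
    umap_dims: int = 2
    train_fraction: float = 0.75
    n_replicates: int = 10
    svm_c: float = 1.0
    fixed_split: bool = False
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_length < 2:
            raise ValueError("target_length must be >= 2")
        if not 0 < self.sat_threshold <= 1:
            raise ValueError("sat_threshold must be in (0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for p, kind in (
            (self.images_dir, "images directory"),
            (self.roi_table, "ROI table"),
            (self.meta_table, "metadata table"),
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"{kind} not found: {p}")


def _find_image(images_dir: Path, image_id: str) -> Path:
    for suffix in _IMAGE_SUFFIXES:
        candidate = images_dir / f"{image_id}{suffix}"
        if candidate.is_file():
            return candidate
    raise FileNotFoundError(f"no image file for specimen {image_id!r} in {images_dir}")


def extract_profiles_from_dir(
    images_dir: str | Path,
    rois,
    target_length: int = DEFAULT_TARGET_LENGTH,
    sat_threshold: float = DEFAULT_SAT_THRESHOLD,
    max_masked_fraction: float = 0.5,
):
    """Extract one fixed-length profile per ROI row, matching images by stem."""
    images_dir = Path(images_dir)
    profiles = []
    for roi in rois:
        path = _find_image(images_dir, roi.image_id)
        img = read_image(path)
        profiles.append(
            extract_profile(
                img,
                roi,
                target_length=target_length,
                sat_threshold=sat_threshold,
                max_masked_fraction=max_masked_fraction,
            )
        )
    return profiles


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, sort_keys=True, default=_json_default))


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and persist each stage's output under ``out_dir``.

    Outputs: config.json (echo), profiles.csv, indices.csv, summary.csv,
    metrics.csv, report.json.  Reruns with identical inputs and seed are
    byte-identical.
    """
    from .image_io import read_roi_table

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(asdict(config), out / "config.json")
    umap_seed, split_seed = (
        int(s) for s in np.random.SeedSequence(config.seed).generate_state(2) % 2**31
    )

    stage = "extract"
    try:
        rois = read_roi_table(config.roi_table)
        profiles = extract_profiles_from_dir(
            config.images_dir,
            rois,
            target_length=config.target_length,
            sat_threshold=config.sat_threshold,
            max_masked_fraction=config.max_masked_fraction,
        )
        write_profiles(profiles, out / "profiles.csv")
        log.info("extract: %d profiles of length %d", len(profiles), config.target_length)

        stage = "index"
        indices = index_table(profiles)
        indices.to_csv(out / "indices.csv", index=False)

        stage = "summarize"
        meta = validate_metadata(pd.read_csv(config.meta_table))
        summary = summarize_groups(indices, meta)
        summary.to_csv(out / "summary.csv", index=False)

        stage = "classify"
        _, X = profiles_to_matrix(profiles)
        meta_ordered = (
            indices[["specimen_id"]].merge(meta, on="specimen_id", how="left")
        )
        metrics = classify_by_colony(
            X,
            meta_ordered,
            label=config.label,
            umap_params=UMAPParams(
                n_neighbors=config.umap_neighbors,
                n_components=config.umap_dims,
                seed=umap_seed,
            ),
            protocol=EvalProtocol(
                train_fraction=config.train_fraction,
                n_replicates=config.n_replicates,
                seed=split_seed,
                C=config.svm_c,
                fixed_split=config.fixed_split,
            ),
        )
        metrics.to_csv(out / "metrics.csv", index=False)

        stage = "stats"
        report = run_inference(indices, meta, alpha=config.alpha)
        _write_json(report.to_dict(), out / "report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def load_pipeline_profiles(out_dir: str | Path):
    """Convenience: reload the profiles a previous run wrote."""
    return read_profiles(Path(out_dir) / "profiles.csv")
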