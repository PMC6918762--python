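"""End-to-end runs: scene analysis -> CSV row per image, heating CSV -> fits.

The scene pipeline mirrors the image-analysis protocol: border-margin
exclusion, gray-standard Lab conversion, filter bank, per-image K-means,
region signatures, χ² scores for the Egg–Nest / Egg–External / Nest–External
pairs, and the disruptive egg-border percentage. Output is one CSV row per
image (signatures for the four regions, border %, pair scores), with texture
label and boundary images saved alongside for inspection. Failures in one
scene flag its row and the run continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import camouflage, disruptive, heating, scene_io, texture_features

log = logging.getLogger("nestcam")

REGION_NAMES = {scene_io.EGG: "egg", scene_io.NEST: "nest",
                scene_io.INTERNAL: "internal", scene_io.EXTERNAL: "external"}


@dataclass
class RunConfig:
    """Serializable bundle of every tunable of a pipeline run."""

    seed: int = 0
    n_clusters: int = camouflage.DEFAULT_N_CLUSTERS
    margin_fraction: float = 0.02
    scales: tuple[float, ...] = texture_features.DEFAULT_SCALES
    n_orientations: int = texture_features.DEFAULT_N_ORIENTATIONS
    standardize_features: bool = False
    kmeans_restarts: int = 10
    square_mm: float = 2.0
    final_temperature_k: int = 5
    log_level: str = "INFO"
    scenes: list = field(default_factory=list)  # dicts: id/image/mask/...

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["scales"] = list(d["scales"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def csv_columns(n_clusters: int) -> list[str]:
    cols = ["image_id"]
    for name in ("egg", "nest", "internal", "external"):
        cols += [f"{name}_sig_{i:02d}" for i in range(1, n_clusters + 1)]
    cols += ["egg_border_pct", "chi2_egg_nest", "chi2_egg_external",
             "chi2_nest_external", "n_clusters", "seed", "config_hash", "error"]
    return cols


def analyze_scene(
    scene_id: str,
    scene: scene_io.RgbScene,
    mask: scene_io.RegionMask,
    std: scene_io.GrayStandard,
    config: RunConfig,
    bank: texture_features.FilterBank | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full camouflage analysis on one scene; returns the CSV row dict."""
    if bank is None:
        bank = texture_features.build_bank(config.scales, config.n_orientations)
    mask = scene_io.exclude_border(mask, config.margin_fraction)
    lab = scene_io.rgb_to_lab(scene, std, mask=mask)
    stack = texture_features.apply_bank(lab, bank,
                                        standardize=config.standardize_features)
    tex = camouflage.cluster_textures(stack, mask,
                                      n_clusters=config.n_clusters,
                                      seed=config.seed,
                                      n_init=config.kmeans_restarts)
    row: dict = {"image_id": scene_id, "n_clusters": tex.n_clusters,
                 "seed": config.seed, "config_hash": config.config_hash(),
                 "error": ""}
    for code, name in REGION_NAMES.items():
        sig = camouflage.signature(tex, mask, code)
        for i, wgt in enumerate(sig.weights, start=1):
            row[f"{name}_sig_{i:02d}"] = wgt
    row.update(camouflage.scene_scores(tex, mask))
    row["egg_border_pct"] = disruptive.disruptive_score(tex, mask).scene_value

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out / f"{scene_id}_textures.png",
                    tex.labels.astype(np.uint8))
        iio.imwrite(out / f"{scene_id}_boundaries.png",
                    tex.boundaries.astype(np.uint8) * 255)
    return row


def run_scene_pipeline(
    scene_inputs: list[tuple[str, scene_io.RgbScene, scene_io.RegionMask,
                             scene_io.GrayStandard]],
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Analyze a list of scenes into a one-row-per-image DataFrame.

    A failing scene gets a row with the error message recorded; the run
    continues with the remaining scenes.
    """
    bank = texture_features.build_bank(config.scales, config.n_orientations)
    rows = []
    for scene_id, scene, mask, std in scene_inputs:
        try:
            rows.append(analyze_scene(scene_id, scene, mask, std, config,
                                      bank=bank, out_dir=out_dir))
        except Exception as err:  # noqa: BLE001 - flagged, run continues
            log.error("scene %s failed: %s", scene_id, err)
            rows.append({"image_id": scene_id, "error": str(err)})
    df = pd.DataFrame(rows, columns=csv_columns(config.n_clusters))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "scene_report.csv", index=False)
        (out / "run_config.yaml").write_text(config.to_yaml())
    return df


def load_scene_inputs(config: RunConfig) -> list[tuple]:
    """Resolve the ``scenes`` entries of a config into loaded scene tuples.

    Each entry: ``{id, image, mask, pixel_scale, std_value}`` where
    ``std_value`` is the measured linear value of the gray-standard patch.
    """
    out = []
    for entry in config.scenes:
        scene, mask = scene_io.load_scene(entry["image"], entry["mask"],
                                          float(entry["pixel_scale"]))
        std = scene_io.GrayStandard(
            measured_value=float(entry.get("std_value", 0.18)),
            nominal_reflectance=float(entry.get("std_reflectance", 0.18)),
        )
        out.append((str(entry.get("id", Path(entry["image"]).stem)),
                    scene, mask, std))
    return out


def run_heating_pipeline(
    series_list: list[heating.HeatingSeries],
    config: RunConfig | None = None,
    reflectance: dict[str, float] | None = None,
    fit: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every replicate and summarize per material.

    Returns (per-replicate fit table, per-material summary table). Series
    that fail to fit are skipped with a warning count in the log; with
    ``fit=False`` (field protocol) only final temperatures are summarized.
    """
    k = config.final_temperature_k if config else 5
    fits: dict[tuple[str, str], heating.HeatingFit] = {}
    finals: dict[tuple[str, str], float] = {}
    fit_rows = []
    n_skipped = 0
    for s in series_list:
        key = (s.material, s.replicate)
        finals[key] = heating.summarize_final_temperature(s, k=min(k, len(s)))
        if not fit:
            continue
        try:
            f = heating.fit_heating(s)
        except (ValueError, RuntimeError) as err:
            n_skipped += 1
            log.warning("fit skipped for %s/%s: %s", s.material, s.replicate, err)
            continue
        fits[key] = f
        fit_rows.append({"material": s.material, "replicate": s.replicate,
                         "T_i": f.T_i, "T_f": f.T_f, "a": f.a, "b": f.b,
                         "Tc": f.Tc, "r2": f.r2})
    if n_skipped:
        log.warning("%d series could not be fitted", n_skipped)
    summaries = heating.summarize_materials(fits if fit else None, finals,
                                            reflectance=reflectance)
    sum_rows = [dataclasses.asdict(s) for s in summaries]
    fit_cols = ["material", "replicate", "T_i", "T_f", "a", "b", "Tc", "r2"]
    return (pd.DataFrame(fit_rows, columns=fit_cols),
            pd.DataFrame(sum_rows))


def save_run_metadata(out_dir: str | Path, config: RunConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash()}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
    (out / "run_config.yaml").write_text(config.to_yaml())
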