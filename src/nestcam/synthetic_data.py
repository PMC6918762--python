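"""Seeded synthetic nest scenes and heating curves.

Real inputs for this analysis are field photographs of ground nests (egg,
nest-cup, and microhabitat regions that differ in lightness and texture
grain) and thermocouple logs of model eggs heating under an IR lamp. The
generators here emulate the statistical structure those analyses assume —
pebble-like multi-scale texture with controllable lightness and grain,
elliptical eggs inside a nest cup, an 18%-reflectance gray standard in the
frame, and exponential heating curves with known parameters — so that every
stage of the pipeline is testable without any photograph.

Default region lightness values (egg 25.31, nest 32.28, microhabitat 28.42)
are the field means observed for unmanipulated Kentish plover nests; texture
is low-pass-filtered seeded Gaussian noise thresholded into two-tone patches,
whose grain size sets the patch scale the filter bank must resolve. All
generated parameters are stored as ground truth next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from . import scene_io
from .heating import HeatingSeries
from .scene_io import GrayStandard, LabScene, RegionMask, RgbScene

TRUTH_SCHEMA_VERSION = 1

# independent deterministic RNG streams per scene ingredient, so that adding
# material to a scene never perturbs its base geometry or textures
_STREAMS = {"geometry": 0, "egg": 1, "nest": 2, "internal": 3, "external": 4,
            "material": 5, "noise": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class RegionAppearance:
    """Lightness, chromaticity and texture of one scene region.

    ``L`` is CIE L* (0-100); ``a``/``b`` the chromatic axes (defaults are a
    sandy substrate); ``grain_px`` the pebble patch scale in pixels;
    ``contrast`` the two-tone lightness amplitude in L* units.
    """

    L: float
    a: float = 6.0
    b: float = 16.0
    grain_px: float = 5.0
    contrast: float = 3.0


#: field means of unmanipulated nests, used as generator presets
EGG_DEFAULT = RegionAppearance(L=25.31, grain_px=2.0)
NEST_DEFAULT = RegionAppearance(L=32.28, grain_px=5.0)
EXTERNAL_DEFAULT = RegionAppearance(L=28.42, grain_px=8.0)


@dataclass
class SceneSpec:
    """Parameter bundle for one synthetic nest scene."""

    size: tuple[int, int] = (256, 256)
    pixel_scale: float = 1.0  # mm per pixel
    n_eggs: int = 3
    egg_axes_px: tuple[float, float] = (33.0, 24.0)  # major, minor length
    nest_radius_px: float | None = None  # default: 0.27 * min(H, W)
    egg_ring_px: float | None = None  # egg-centre ring radius; default packs a clutch
    internal_width_px: int = 4
    egg: RegionAppearance = field(default_factory=lambda: EGG_DEFAULT)
    nest: RegionAppearance = field(default_factory=lambda: NEST_DEFAULT)
    external: RegionAppearance = field(default_factory=lambda: EXTERNAL_DEFAULT)
    internal: RegionAppearance | None = None  # defaults to external
    material: RegionAppearance | None = None  # experimental nest material
    material_fraction: float = 0.0  # fraction of nest area it covers
    exposure: float = 1.0  # global linear gain (gray card tracks it)
    standard_patch_px: int = 12
    seed: int = 0

    def resolved_nest_radius(self) -> float:
        if self.nest_radius_px is not None:
            return float(self.nest_radius_px)
        return 0.27 * min(self.size)


@dataclass
class CurveSpec:
    """Parameter bundle for one synthetic heating curve (lab protocol)."""

    T_i: float = 25.0
    T_f: float = 45.0
    Tc: float = 300.0
    interval_s: float = 15.0
    duration_s: float = 3600.0
    noise_sd: float = 0.2
    material: str = ""
    replicate: str = "0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Tc <= 0:
            raise ValueError("Tc must be positive")
        if self.duration_s < 5 * self.interval_s:
            raise ValueError("duration must cover at least 5 sampling intervals")


def _pebble_texture(shape: tuple[int, int], grain_px: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Two-tone pebble field in [-1, 1] with patches of the given grain.

    Low-pass-filtered Gaussian noise thresholded at its median (so the two
    tones cover equal areas and the mean is ~0), with a mild within-patch
    gradient so patches are not perfectly flat.
    """
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=grain_px)
    f = f - np.median(f)
    sd = f.std()
    if sd > 0:
        f = f / sd
    return 0.75 * np.sign(f) + 0.25 * np.clip(f, -1.0, 1.0)


def _ellipse_mask(shape, center, semi_major, semi_minor, angle_rad) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    y = yy - center[0]
    x = xx - center[1]
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    u = x * c + y * s
    v = -x * s + y * c
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def _build_mask(spec: SceneSpec) -> tuple[RegionMask, np.ndarray]:
    h, w = spec.size
    r_nest = spec.resolved_nest_radius()
    if r_nest + spec.internal_width_px >= min(h, w) / 2:
        raise ValueError("nest plus internal ring does not fit in the frame")
    cy, cx = h / 2.0, w / 2.0
    yy, xx = np.mgrid[:h, :w]
    rr = np.hypot(yy - cy, xx - cx)

    labels = np.full((h, w), scene_io.EXTERNAL, dtype=int)
    labels[rr <= r_nest + spec.internal_width_px] = scene_io.INTERNAL
    labels[rr <= r_nest] = scene_io.NEST

    rng = _rng(spec.seed, "geometry")
    semi_a = spec.egg_axes_px[0] / 2.0
    semi_b = spec.egg_axes_px[1] / 2.0
    if semi_a >= r_nest:
        raise ValueError("egg does not fit inside the nest")
    # eggs arranged around the cup centre, pointed ends inward like a clutch
    ring = spec.egg_ring_px if spec.egg_ring_px is not None else semi_b * 1.2
    ring = max(0.0, min(ring, r_nest - semi_a - 1))
    base_angle = rng.uniform(0, 2 * np.pi)
    inst = np.zeros((h, w), dtype=int)
    for i in range(spec.n_eggs):
        ang = base_angle + 2 * np.pi * i / max(spec.n_eggs, 1)
        ec = (cy + ring * np.sin(ang), cx + ring * np.cos(ang))
        tilt = ang + rng.normal(0, 0.1)
        m = _ellipse_mask((h, w), ec, semi_a, semi_b, tilt)
        if not m.any():
            raise ValueError("egg geometry infeasible")
        inst[m & (inst == 0)] = i + 1
    labels[inst > 0] = scene_io.EGG
    mask = RegionMask(labels=labels, egg_instances=inst)
    lengths = []
    from skimage import measure

    for p in measure.regionprops(inst):
        lengths.append(p.axis_major_length)
    mask.egg_lengths_px = np.asarray(lengths)
    return mask, inst


def make_scene(spec: SceneSpec) -> tuple[RgbScene, RegionMask, GrayStandard, dict]:
    """Render a synthetic nest scene.

    Returns the linear-RGB scene, its region mask, the gray standard the
    frame carries (a patch of known linear value in the top-left corner,
    excluded from analysis), and a ground-truth dict holding every generated
    parameter plus realized per-region statistics.
    """
    h, w = spec.size
    mask, inst = _build_mask(spec)
    internal_app = spec.internal if spec.internal is not None else spec.external

    region_apps = {
        scene_io.EGG: ("egg", spec.egg),
        scene_io.NEST: ("nest", spec.nest),
        scene_io.INTERNAL: ("internal", internal_app),
        scene_io.EXTERNAL: ("external", spec.external),
    }
    L = np.zeros((h, w))
    a = np.zeros((h, w))
    b = np.zeros((h, w))
    for code, (name, app) in region_apps.items():
        tex = _pebble_texture((h, w), app.grain_px, _rng(spec.seed, name))
        sel = mask.labels == code
        L[sel] = app.L + app.contrast * tex[sel]
        a[sel] = app.a + 0.1 * app.contrast * tex[sel]
        b[sel] = app.b + 0.2 * app.contrast * tex[sel]

    material_mask = np.zeros((h, w), dtype=bool)
    if spec.material is not None and spec.material_fraction > 0:
        mat = spec.material
        nest_sel = mask.labels == scene_io.NEST
        if spec.material_fraction >= 1.0:
            material_mask = nest_sel.copy()
        else:
            fld = ndimage.gaussian_filter(
                _rng(spec.seed, "material").standard_normal((h, w)),
                sigma=max(mat.grain_px, 2.0) * 2,
            )
            thr = np.quantile(fld[nest_sel], 1.0 - spec.material_fraction)
            material_mask = nest_sel & (fld > thr)
        tex = _pebble_texture((h, w), mat.grain_px, _rng(spec.seed, "material"))
        L[material_mask] = mat.L + mat.contrast * tex[material_mask]
        a[material_mask] = mat.a + 0.1 * mat.contrast * tex[material_mask]
        b[material_mask] = mat.b + 0.2 * mat.contrast * tex[material_mask]

    lab = np.stack([L, a, b], axis=-1)
    linear = np.clip(scene_io.lab_to_linear_rgb(lab), 0.0, 1.0)
    linear = np.clip(linear * spec.exposure, 0.0, 1.0)

    # gray standard patch in the frame corner, excluded from analysis
    p = spec.standard_patch_px
    linear[:p, :p, :] = 0.18 * spec.exposure
    labels = mask.labels.copy()
    labels[:p, :p] = scene_io.MARGIN
    inst = inst.copy()
    inst[:p, :p] = 0
    mask = RegionMask(labels=labels, egg_instances=inst,
                      egg_lengths_px=mask.egg_lengths_px)

    scene = RgbScene(pixels=linear, pixel_scale=spec.pixel_scale,
                     meta={"synthetic": True, "seed": spec.seed})
    std = GrayStandard(measured_value=0.18 * spec.exposure)

    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "spec": _spec_to_dict(spec),
        "region_target_L": {name: app.L for _, (name, app) in region_apps.items()},
        "region_mean_L": {
            name: float(L[mask.labels == code].mean())
            for code, (name, _) in region_apps.items()
            if (mask.labels == code).any()
        },
        "egg_lengths_px": [float(x) for x in mask.egg_lengths_px],
        "material_fraction_realized": (
            float(material_mask[mask.labels == scene_io.NEST].mean())
            if (mask.labels == scene_io.NEST).any() else 0.0
        ),
        "gray_standard_value": std.measured_value,
    }
    truth["material_mask"] = material_mask
    return scene, mask, std, truth


def make_two_texture_scene(
    size: tuple[int, int] = (256, 256),
    app_a: RegionAppearance | None = None,
    app_b: RegionAppearance | None = None,
    seed: int = 0,
) -> tuple[LabScene, np.ndarray]:
    """Left/right two-texture scene with known ground-truth partition.

    The left half gets ``app_a`` (default: coarse speckle), the right half
    ``app_b`` (default: fine speckle, different lightness). Returns a
    ready-to-filter LabScene (left = nest code, right = external) and the
    ground-truth binary partition.
    """
    if app_a is None:
        app_a = RegionAppearance(L=40.0, grain_px=8.0, contrast=6.0)
    if app_b is None:
        app_b = RegionAppearance(L=25.0, grain_px=2.0, contrast=6.0)
    h, w = size
    half = w // 2
    truth = np.zeros((h, w), dtype=int)
    truth[:, half:] = 1
    L = np.zeros((h, w))
    a = np.zeros((h, w))
    b = np.zeros((h, w))
    for side, app, stream in ((truth == 0, app_a, "nest"),
                              (truth == 1, app_b, "external")):
        tex = _pebble_texture((h, w), app.grain_px, _rng(seed, stream))
        L[side] = app.L + app.contrast * tex[side]
        a[side] = app.a + 0.1 * app.contrast * tex[side]
        b[side] = app.b + 0.2 * app.contrast * tex[side]
    labels = np.where(truth == 0, scene_io.NEST, scene_io.EXTERNAL)
    mask = RegionMask(labels=labels)
    lab = LabScene(L=L, a=a, b=b, pixel_scale=1.0, mask=mask)
    return lab, truth


def make_treatment_scenes(
    base: SceneSpec,
    material: RegionAppearance,
    retained_fraction: float = 0.15,
) -> dict[str, tuple[RgbScene, RegionMask, GrayStandard, dict]]:
    """Build the three per-nest photographs of the manipulation protocol.

    O — original nest; T — experimental material covering the whole nest cup;
    W — one week later, with only ``retained_fraction`` of the material left.
    Geometry and base textures are shared across the triple (same seed), so
    differences in camouflage scores are attributable to the material alone.
    """
    return {
        "O": make_scene(base),
        "T": make_scene(replace(base, material=material, material_fraction=1.0)),
        "W": make_scene(replace(base, material=material,
                                material_fraction=retained_fraction)),
    }


def make_heating_curve(spec: CurveSpec) -> tuple[HeatingSeries, dict]:
    """Sample T(t) = T_f + (T_i − T_f)·e^(−t/Tc) + Gaussian noise."""
    t = np.arange(0.0, spec.duration_s + spec.interval_s / 2.0, spec.interval_s)
    T = spec.T_f + (spec.T_i - spec.T_f) * np.exp(-t / spec.Tc)
    if spec.noise_sd > 0:
        T = T + _rng(spec.seed, "noise").normal(0.0, spec.noise_sd, size=t.shape)
    series = HeatingSeries(t=t, T=T, material=spec.material,
                           replicate=spec.replicate)
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "spec": dataclasses.asdict(spec),
        "n_records": int(len(t)),
    }
    return series, truth


def _spec_to_dict(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d


def write_scene(out_dir: str | Path, stem: str, scene: RgbScene,
                mask: RegionMask, truth: dict) -> dict[str, Path]:
    """Write a generated scene as 16-bit TIFF + label PNG + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}.tif"
    mask_path = out / f"{stem}_mask.png"
    truth_path = out / f"{stem}_truth.json"
    tifffile.imwrite(img_path, (scene.pixels * 65535.0 + 0.5).astype(np.uint16))
    iio.imwrite(mask_path, mask.labels.astype(np.uint8))
    t = dict(truth)
    mm = t.pop("material_mask", None)
    if mm is not None and np.asarray(mm).any():
        mat_path = out / f"{stem}_material.png"
        iio.imwrite(mat_path, np.asarray(mm).astype(np.uint8) * 255)
        t["material_mask_path"] = str(mat_path)
    truth_path.write_text(json.dumps(t, indent=2))
    return {"image": img_path, "mask": mask_path, "truth": truth_path}


def write_heating_csv(path: str | Path, series_list: list[HeatingSeries]) -> Path:
    """Write series to the long-format CSV the heating pipeline reads."""
    frames = [
        pd.DataFrame({"time_s": s.t, "temp_C": s.T, "material": s.material,
                      "replicate": s.replicate})
        for s in series_list
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
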