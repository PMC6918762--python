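"""Texture clustering, per-region clustering signatures, and χ² camouflage scores.

Per image, every analyzed pixel's 168-feature vector is clustered with
K-means (default 14 centers). A region's *clustering signature* is the
relative presence (%) of each texture cluster among its pixels; two regions'
signatures are compared with the χ² histogram distance

    d(g, h) = ½ Σ_i (g_i − h_i)² / (g_i + h_i),

skipping empty bins. Lower values mean the two regions share texture
structure — better background/pattern matching. On %-normalized signatures
the distance lies in [0, 100]. It is symmetric and zero iff g = h, but it is
not a metric (the triangle inequality can fail), so it is reported as a
score, never used for metric indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from . import scene_io
from .scene_io import LabScene, RegionMask
from .texture_features import FeatureStack, FilterBank, apply_bank, build_bank

DEFAULT_N_CLUSTERS = 14
DEFAULT_CANDIDATES = (6, 8, 10, 12, 14, 16, 20)


@dataclass
class TextureMap:
    """Per-pixel cluster labels in 1..n_clusters (0 = not analyzed) plus
    the binary image of texture frontiers."""

    labels: np.ndarray
    n_clusters: int
    boundaries: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class ClusterSignature:
    region: int
    weights: np.ndarray  # % per cluster, sums to 100

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class CamouflageScore:
    pair: tuple[int, int]
    value: float


def _texture_boundaries(labels: np.ndarray) -> np.ndarray:
    """Binary frontier image: 4-connected label changes between analyzed
    pixels, marked one pixel thick on the side of the lower label."""
    b = np.zeros(labels.shape, dtype=bool)
    a0, a1 = labels[:, :-1], labels[:, 1:]
    d = (a0 != a1) & (a0 > 0) & (a1 > 0)
    b[:, :-1] |= d & (a0 < a1)
    b[:, 1:] |= d & (a1 < a0)
    a0, a1 = labels[:-1, :], labels[1:, :]
    d = (a0 != a1) & (a0 > 0) & (a1 > 0)
    b[:-1, :] |= d & (a0 < a1)
    b[1:, :] |= d & (a1 < a0)
    return b


def _count_distinct_rows(X: np.ndarray, at_least: int, seed: int = 0) -> int:
    """Cheap lower-bound check that X has >= at_least distinct rows."""
    rng = np.random.default_rng(seed)
    h = X @ rng.standard_normal(X.shape[1])
    n_hash = np.unique(h).size
    if n_hash >= at_least:
        return at_least
    return np.unique(X, axis=0).shape[0]


def cluster_textures(
    stack: FeatureStack,
    mask: RegionMask,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-4,
) -> TextureMap:
    """K-means over all analyzed pixels of one image; labels 1..n_clusters.

    Clustering is per image: signatures are only ever compared within the
    image they came from. k-means++ initialization with ``n_init`` restarts;
    deterministic for a fixed seed. If the image holds fewer distinct feature
    vectors than requested clusters, the count is reduced with a warning.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    analyzed = mask.analyzed()
    X = stack.features[analyzed].astype(np.float32)
    if X.shape[0] < n_clusters:
        raise ValueError("fewer analyzed pixels than clusters")

    # distinctness is judged after quantizing at 1e-9 of the feature range so
    # that FFT round-off on a constant image does not masquerade as texture
    scale = max(float(np.abs(X).max()), np.finfo(np.float32).tiny)
    Xq = np.round(X.astype(np.float64) * (1e9 / scale))
    n_distinct = _count_distinct_rows(Xq, n_clusters)
    k = n_clusters
    if n_distinct < n_clusters:
        warnings.warn(
            f"only {n_distinct} distinct feature vectors; reducing clusters "
            f"from {n_clusters} to {n_distinct}", stacklevel=2,
        )
        k = max(1, n_distinct)

    if k == 1:
        lbl = np.ones(X.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, tol=tol, random_state=seed)
        lbl = km.fit_predict(X) + 1
    labels = np.zeros(mask.shape, dtype=int)
    labels[analyzed] = lbl
    return TextureMap(labels=labels, n_clusters=k,
                      boundaries=_texture_boundaries(labels))


def signature(tex: TextureMap, mask: RegionMask, region: int) -> ClusterSignature:
    """Relative presence (%) of each texture cluster within one region."""
    sel = mask.region_pixels(region) & (tex.labels > 0)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"region {region} has no analyzed pixels")
    counts = np.bincount(tex.labels[sel], minlength=tex.n_clusters + 1)[1:]
    return ClusterSignature(region=region, weights=100.0 * counts / n)


def chi2_distance(g: ClusterSignature | np.ndarray, h: ClusterSignature | np.ndarray,
                  half: bool = True) -> CamouflageScore:
    """χ² distance between two %-normalized signatures (lower = better match).

    ``half`` applies the conventional ½ factor; terms with g_i + h_i = 0 are
    skipped.
    """
    gr = g.region if isinstance(g, ClusterSignature) else -1
    hr = h.region if isinstance(h, ClusterSignature) else -1
    gw = np.asarray(g.weights if isinstance(g, ClusterSignature) else g, dtype=float)
    hw = np.asarray(h.weights if isinstance(h, ClusterSignature) else h, dtype=float)
    if gw.shape != hw.shape:
        raise ValueError("signatures must have the same length")
    for w in (gw, hw):
        if (w < -1e-9).any() or abs(w.sum() - 100.0) > 1e-6:
            raise ValueError("signatures must be non-negative and sum to 100")
    denom = gw + hw
    ok = denom > 0
    val = float(((gw[ok] - hw[ok]) ** 2 / denom[ok]).sum())
    if half:
        val *= 0.5
    return CamouflageScore(pair=(gr, hr), value=val)


def _signature_correlation(sig_a: np.ndarray, sig_b: np.ndarray,
                           method: str) -> float:
    if method == "pearson":
        r = stats.pearsonr(sig_a, sig_b).statistic
    elif method == "spearman":
        r = stats.spearmanr(sig_a, sig_b).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return 0.0 if np.isnan(r) else float(r)


def select_n_clusters(
    scenes: list[LabScene],
    candidates: tuple[int, ...] = DEFAULT_CANDIDATES,
    seed: int = 0,
    bank: FilterBank | None = None,
    method: str = "pearson",
    tol: float = 0.02,
) -> tuple[int, dict[int, float]]:
    """Pick the number of texture clusters by the egg/microhabitat decorrelation
    criterion.

    For each candidate count the full pipeline runs on every scene and the
    correlation between the egg and external signatures is averaged; more
    clusters decorrelate the two until the curve saturates. Returns the elbow
    choice — the smallest candidate after which the decrease falls below
    ``tol`` — together with the whole curve.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list must not be empty")
    if list(candidates) != sorted(candidates):
        raise ValueError("candidates must be sorted ascending")
    if bank is None:
        bank = build_bank()
    stacks = [apply_bank(s, bank) for s in scenes]

    curve: dict[int, float] = {}
    for k in candidates:
        rs = []
        for scene, stack in zip(scenes, stacks):
            tex = cluster_textures(stack, scene.mask, n_clusters=k, seed=seed)
            se = signature(tex, scene.mask, scene_io.EGG).weights
            sx = signature(tex, scene.mask, scene_io.EXTERNAL).weights
            rs.append(_signature_correlation(se, sx, method))
        curve[k] = float(np.mean(rs))

    cand = list(candidates)
    chosen = cand[-1]
    for i in range(len(cand) - 1):
        if curve[cand[i]] - curve[cand[i + 1]] < tol:
            chosen = cand[i]
            break
    return chosen, curve


def scene_scores(tex: TextureMap, mask: RegionMask) -> dict[str, float]:
    """χ² camouflage scores for the standard region pairs of one image.

    The internal buffer ring is clustered but never scored.
    """
    se = signature(tex, mask, scene_io.EGG)
    sn = signature(tex, mask, scene_io.NEST)
    sx = signature(tex, mask, scene_io.EXTERNAL)
    return {
        "chi2_egg_nest": chi2_distance(se, sn).value,
        "chi2_egg_external": chi2_distance(se, sx).value,
        "chi2_nest_external": chi2_distance(sn, sx).value,
    }
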