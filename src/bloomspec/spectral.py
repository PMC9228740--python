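"""Vegetation-index computation and model-input packaging.

The core feature is a signed-root normalized difference: the usual
(rho_a - rho_b) / (rho_a + rho_b) ratio, stretched by the odd map
sgn(x) * sqrt(|x|).  Because sqrt(|x|) >= |x| on [-1, 1], the stretch widens
the gap between weakly separated classes (early-stage blooms vs. water) while
preserving sign and ordering.  Applied to the (B5, B1) near-infrared / blue
pair it forms the NDVI_sqrt index; the classic NDVI is the plain ratio on
(B5, B3).

Band-pair selection scores all C(5,2) = 10 normalized-difference pairs by a
worst-case Fisher ratio across class pairs, so the chosen pair is the one
under which *no* two classes collapse onto each other.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .raster_io import BAND_IDS, LabelRaster, MultispectralScene

__all__ = [
    "IndexMap",
    "BandPairReport",
    "ModelInput",
    "normalized_difference",
    "enhance_signed_sqrt",
    "ndvi_sqrt",
    "select_band_pair",
    "to_model_input",
]


@dataclasses.dataclass(frozen=True)
class IndexMap:
    """Per-pixel vegetation-index raster in [-1, 1].

    ``valid`` is False where the index is undefined (zero denominator) or the
    source pixel was invalid; those pixels hold 0 but are excluded from all
    statistics and flagged ignore downstream.
    """

    values: np.ndarray
    band_pair: tuple[str, str]
    valid: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        m = np.asarray(self.valid, dtype=bool)
        if v.shape != m.shape or v.ndim != 2:
            raise ValueError("values and valid must be matching 2-D arrays")
        if m.any():
            inside = v[m]
            if not np.all(np.isfinite(inside)):
                raise ValueError("valid index pixels must be finite")
            if inside.min() < -1.0 - 1e-12 or inside.max() > 1.0 + 1e-12:
                raise ValueError("index values must lie in [-1, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "valid", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def normalized_difference(
    scene: MultispectralScene, band_a: str, band_b: str
) -> IndexMap:
    """Generalized normalized difference (rho_a - rho_b) / (rho_a + rho_b).

    Pixels with a zero denominator become invalid (sentinel 0).  The map is
    antisymmetric in its band arguments.
    """
    if band_a == band_b:
        raise ValueError(f"band_a and band_b must differ, both are {band_a}")
    for b in (band_a, band_b):
        if b not in BAND_IDS:
            raise ValueError(f"unknown band id {b!r}")
    a = scene.bands[band_a]
    b = scene.bands[band_b]
    denom = a + b
    ok = denom > 0.0
    if scene.valid_mask is not None:
        ok = ok & scene.valid_mask
    values = np.zeros_like(denom)
    np.divide(a - b, denom, out=values, where=denom > 0.0)
    values[~ok] = 0.0
    return IndexMap(values=values, band_pair=(band_a, band_b), valid=ok)


def enhance_signed_sqrt(index: IndexMap) -> IndexMap:
    """Signed-root stretch sgn(x) * sqrt(|x|), applied per pixel.

    Odd, strictly monotone, maps [-1, 1] onto [-1, 1], and satisfies
    |out| >= |in| so class differences can only widen.  Invalid pixels
    propagate unchanged.
    """
    out = np.sign(index.values) * np.sqrt(np.abs(index.values))
    out[~index.valid] = 0.0
    return IndexMap(values=out, band_pair=index.band_pair, valid=index.valid)


def ndvi_sqrt(scene: MultispectralScene) -> IndexMap:
    """The signed-root blue/NIR index: sgn-sqrt of the (B5, B1) ratio."""
    return enhance_signed_sqrt(normalized_difference(scene, "B5", "B1"))


@dataclasses.dataclass(frozen=True)
class ClassIndexStats:
    """Summary of one class's index distribution under one band pair."""

    mean: float
    std: float
    min: float
    max: float
    count: int


@dataclasses.dataclass(frozen=True)
class BandPairReport:
    """Separability ranking of all 10 unordered band pairs.

    ``ranking`` is sorted best-first; ``per_class`` maps a pair to per-class
    index statistics.  The separability score of a pair is the minimum over
    class pairs of |mean_i - mean_j| / pooled_std — a worst-case Fisher
    ratio, infinite when two constant classes have distinct means.
    """

    ranking: tuple[tuple[tuple[str, str], float], ...]
    per_class: dict[tuple[str, str], dict[str, ClassIndexStats]]

    @property
    def best_pair(self) -> tuple[str, str]:
        return self.ranking[0][0]


def _pair_sort_key(item: tuple[tuple[str, str], float]):
    (a, b), score = item
    # best score first; ties prefer pairs containing B5, then lower band number
    has_b5 = "B5" in (a, b)
    low = min(int(a[1]), int(b[1]))
    return (-score, not has_b5, low)


def select_band_pair(
    scenes: Sequence[tuple[MultispectralScene, LabelRaster]],
) -> BandPairReport:
    """Rank all band pairs by worst-case between-class separability.

    For every unordered pair the normalized-difference index is computed over
    all scenes; per class (ignore excluded) the index mean/spread/min/max are
    collected, and the pair's score is the smallest standardized mean gap over
    all class pairs.  Requires at least two classes with valid pixels.
    """
    if not scenes:
        raise ValueError("need at least one (scene, labels) pair")
    scheme = scenes[0][1].scheme

    pairs = [
        (a, b) for a, b in itertools.combinations(BAND_IDS, 2)
    ]
    per_class: dict[tuple[str, str], dict[str, ClassIndexStats]] = {}
    scores: dict[tuple[str, str], float] = {}

    for pair in pairs:
        samples: dict[str, list[np.ndarray]] = {}
        for scene, labels in scenes:
            idx = normalized_difference(scene, *pair)
            for ci, name in enumerate(scheme.names):
                if ci == scheme.ignore_index:
                    continue
                sel = (labels.data == ci) & idx.valid
                if sel.any():
                    samples.setdefault(name, []).append(idx.values[sel])
        stats = {}
        for name, chunks in samples.items():
            x = np.concatenate(chunks)
            stats[name] = ClassIndexStats(
                mean=float(x.mean()),
                std=float(x.std(ddof=1)) if x.size > 1 else 0.0,
                min=float(x.min()),
                max=float(x.max()),
                count=int(x.size),
            )
        per_class[pair] = stats
        if len(stats) < 2:
            raise ValueError(
                "band-pair selection needs >= 2 classes with valid pixels, "
                f"found {sorted(stats)}"
            )
        score = np.inf
        for na, nb in itertools.combinations(sorted(stats), 2):
            sa, sb = stats[na], stats[nb]
            gap = abs(sa.mean - sb.mean)
            dof = sa.count + sb.count - 2
            pooled_var = (
                ((sa.count - 1) * sa.std**2 + (sb.count - 1) * sb.std**2) / dof
                if dof > 0
                else 0.0
            )
            pooled = float(np.sqrt(pooled_var))
            if pooled == 0.0:
                s = np.inf if gap > 0 else 0.0
            else:
                s = gap / pooled
            score = min(score, s)
        scores[pair] = float(score)

    ranking = tuple(sorted(scores.items(), key=_pair_sort_key))
    return BandPairReport(ranking=ranking, per_class=per_class)


@dataclasses.dataclass(frozen=True)
class ModelInput:
    """Three-channel network input plus the ignore mask it carries."""

    data: np.ndarray  # (H, W, 3) float
    ignore_mask: np.ndarray  # (H, W) bool, True = ignore
    source_shape: tuple[int, int]


def to_model_input(
    index: IndexMap,
    target_size: tuple[int, int],
    seed: int | None = None,
    augment: bool = False,
    allow_scale: bool = True,
) -> ModelInput:
    """Package an index map as a three-channel model input of ``target_size``.

    The single index channel is replicated three times.  With ``augment`` the
    map is randomly rescaled (factor 0.8–1.2) and randomly cropped, which is
    the training-time diversity expansion; otherwise the map is
    deterministically resized (or center-cropped when it already matches /
    ``allow_scale`` is off).  Invalid pixels are set to 0 and flagged in the
    ignore mask.  Fully deterministic given ``seed``.
    """
    th, tw = target_size
    if th < 1 or tw < 1:
        raise ValueError(f"target_size must be positive, got {target_size}")
    values = index.values.copy()
    values[~index.valid] = 0.0
    invalid = (~index.valid).astype(np.float64)
    h, w = values.shape

    rng = np.random.default_rng(seed)

    def _resize(arr: np.ndarray, hh: int, ww: int) -> np.ndarray:
        return resize(arr, (hh, ww), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)

    if augment:
        f = rng.uniform(0.8, 1.2)
        sh = max(th, int(round(h * f)))
        sw = max(tw, int(round(w * f)))
        values = _resize(values, sh, sw)
        invalid = _resize(invalid, sh, sw)
        top = int(rng.integers(0, sh - th + 1))
        left = int(rng.integers(0, sw - tw + 1))
        values = values[top : top + th, left : left + tw]
        invalid = invalid[top : top + th, left : left + tw]
    elif (h, w) != (th, tw):
        if not allow_scale:
            if h < th or w < tw:
                raise ValueError(
                    f"target {target_size} larger than source {(h, w)} "
                    "with scaling disabled"
                )
            top = (h - th) // 2
            left = (w - tw) // 2
            values = values[top : top + th, left : left + tw]
            invalid = invalid[top : top + th, left : left + tw]
        else:
            values = _resize(values, th, tw)
            invalid = _resize(invalid, th, tw)

    ignore = invalid > 0.5
    values = np.clip(values, -1.0, 1.0)
    values[ignore] = 0.0
    data = np.repeat(values[:, :, None], 3, axis=2)
    return ModelInput(data=data, ignore_mask=ignore, source_shape=(h, w))
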