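"""Deterministic generator of five-band river scenes with ground truth.

Scenes emulate low-altitude multispectral imagery of a river reach: wavy
vegetated bank margins on both sides, open water, irregular flocculent bloom
patches (thresholded smoothed random fields, so shapes are blobby rather than
geometric), optional boat rectangles, specular glint disks that saturate all
bands, shadow regions that dim all bands multiplicatively, and sensor noise
(salt-and-pepper impulses plus Gaussian jitter).  Class band priors are chosen
so that bloom, water, bank and boat pixels separate cleanly in the blue (B1),
red (B3) and near-infrared (B5) bands — the qualitative reflectance ordering
of real bloom scenes (blooms: NIR-bright / blue-dark; water: the reverse) —
without claiming real radiometry.

Everything is a pure function of the config's seed: the same seed reproduces
the scene bit for bit.  The ground-truth labels are noise-free; glint pixels
keep their true underlying class (masking them is the preprocessing stage's
job, not the generator's).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .raster_io import BAND_IDS, DEFAULT_SCHEME, ClassScheme, LabelRaster, MultispectralScene

__all__ = [
    "ClassPrior",
    "SceneConfig",
    "PRESETS",
    "preset_config",
    "generate_scene",
    "generate_dataset",
]


@dataclasses.dataclass(frozen=True)
class ClassPrior:
    """Per-band mean reflectance and an iid per-pixel spread for one class."""

    means: tuple[float, float, float, float, float]  # B1..B5
    spread: float = 0.02

    def __post_init__(self) -> None:
        if len(self.means) != 5:
            raise ValueError("need one mean per band B1..B5")
        if min(self.means) < 0.0 or max(self.means) > 1.0:
            raise ValueError(f"band means must lie in [0, 1]: {self.means}")
        if self.spread < 0.0:
            raise ValueError("spread must be non-negative")


#: Band means ordered B1 (blue) .. B5 (near-infrared).
_DEFAULT_PRIORS: dict[str, ClassPrior] = {
    "water": ClassPrior((0.25, 0.18, 0.12, 0.09, 0.08), spread=0.01),
    "bloom": ClassPrior((0.06, 0.18, 0.10, 0.35, 0.55), spread=0.02),
    # bank vegetation tracks bloom closely in the red edge (B4) but less so
    # in blue/NIR, which is exactly why the (B1, B5) pair wins selection
    "bank": ClassPrior((0.15, 0.22, 0.08, 0.36, 0.40), spread=0.02),
    "boat": ClassPrior((0.45, 0.45, 0.45, 0.40, 0.35), spread=0.02),
}

#: Weak early-stage blooms: classes nearly collapse in the red band (B3), so a
#: red/NIR ratio confuses bloom with bank, while blue (B1) still separates.
_LOW_CONTRAST_PRIORS: dict[str, ClassPrior] = {
    "water": ClassPrior((0.22, 0.15, 0.12, 0.10, 0.10), spread=0.025),
    "bloom": ClassPrior((0.16, 0.14, 0.11, 0.22, 0.30), spread=0.025),
    "bank": ClassPrior((0.30, 0.20, 0.12, 0.22, 0.28), spread=0.025),
    "boat": ClassPrior((0.45, 0.45, 0.45, 0.40, 0.35), spread=0.025),
}


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Everything that shapes one synthetic scene; the seed fixes it all."""

    height: int = 96
    width: int = 96
    bloom_fraction: float = 0.3
    priors: Mapping[str, ClassPrior] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_PRIORS)
    )
    bank_fraction: float = 0.12  # of width, per side
    boat_count: int = 1
    glint_count: int = 0
    glint_radius: float = 5.0
    shadow_count: int = 0
    shadow_dim: float = 0.45
    salt_pepper_density: float = 0.02
    gaussian_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("scene must be at least 16x16")
        if not 0.0 <= self.bloom_fraction <= 1.0:
            raise ValueError("bloom_fraction must lie in [0, 1]")
        if not 0.0 <= self.bank_fraction < 0.5:
            raise ValueError("bank_fraction must lie in [0, 0.5)")
        if not 0.0 < self.shadow_dim < 1.0:
            raise ValueError("shadow_dim must lie in (0, 1)")
        if not 0.0 <= self.salt_pepper_density < 1.0:
            raise ValueError("salt_pepper_density must lie in [0, 1)")
        if self.gaussian_sigma < 0.0:
            raise ValueError("gaussian_sigma must be non-negative")
        missing = {"water", "bloom", "bank", "boat"} - set(self.priors)
        if missing:
            raise ValueError(f"priors missing classes: {sorted(missing)}")


#: The three study scenarios plus the weak-signal variant.
PRESETS: dict[str, dict] = {
    "regular": {},
    "reflection": {"glint_count": 3, "glint_radius": 5.0},
    "shadow": {"shadow_count": 2, "shadow_dim": 0.45},
    "low_contrast": {"priors": dict(_LOW_CONTRAST_PRIORS)},
}


def preset_config(name: str, **overrides) -> SceneConfig:
    """A :class:`SceneConfig` for one of the named scenario presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


def _bank_mask(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Wavy vegetated margins along the left and right edges."""
    h, w = cfg.height, cfg.width
    mask = np.zeros((h, w), dtype=bool)
    base = cfg.bank_fraction * w
    if base < 1:
        return mask
    cols = np.arange(w)
    for side in (0, 1):
        wave = gaussian_filter1d(rng.standard_normal(h), sigma=max(h / 8.0, 1.0))
        std = wave.std()
        if std > 0:
            wave = wave / std * (0.3 * base)
        edge = np.clip(base + wave, 1, w / 2 - 1)
        if side == 0:
            mask |= cols[None, :] < edge[:, None]
        else:
            mask |= cols[None, :] >= w - edge[:, None]
    return mask


def _boat_mask(
    cfg: SceneConfig, water: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    h, w = cfg.height, cfg.width
    mask = np.zeros((h, w), dtype=bool)
    rows, cols = np.nonzero(water)
    for _ in range(cfg.boat_count):
        if rows.size == 0:
            break
        bh = max(2, int(round(h * rng.uniform(0.06, 0.12))))
        bw = max(3, int(round(w * rng.uniform(0.08, 0.16))))
        k = int(rng.integers(rows.size))
        r0 = int(np.clip(rows[k] - bh // 2, 0, h - bh))
        c0 = int(np.clip(cols[k] - bw // 2, 0, w - bw))
        mask[r0 : r0 + bh, c0 : c0 + bw] = True
    return mask & water


def _bloom_mask(
    cfg: SceneConfig, water: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Irregular blob patches: top-k water pixels of a smoothed random field."""
    h, w = cfg.height, cfg.width
    k = int(round(cfg.bloom_fraction * h * w))
    if k == 0:
        return np.zeros((h, w), dtype=bool)
    n_water = int(water.sum())
    if k > n_water:
        raise ValueError(
            f"bloom_fraction {cfg.bloom_fraction} needs {k} pixels but only "
            f"{n_water} water pixels exist"
        )
    field = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 12.0)
    field = np.where(water, field, -np.inf)
    flat = np.argsort(field, axis=None)[::-1][:k]
    mask = np.zeros(h * w, dtype=bool)
    mask[flat] = True
    return mask.reshape(h, w)


def _shadow_factor(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative dimming field: 1 outside shadows, shadow_dim inside."""
    h, w = cfg.height, cfg.width
    factor = np.ones((h, w))
    ii, jj = np.indices((h, w))
    for _ in range(cfg.shadow_count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = rng.uniform(0.12, 0.3) * h
        rx = rng.uniform(0.12, 0.3) * w
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (ii - cy) * ct + (jj - cx) * st
        v = -(ii - cy) * st + (jj - cx) * ct
        inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        factor[inside] = cfg.shadow_dim
    return factor


def _glint_mask(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    mask = np.zeros((h, w), dtype=bool)
    ii, jj = np.indices((h, w))
    for _ in range(cfg.glint_count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        mask |= (ii - cy) ** 2 + (jj - cx) ** 2 <= cfg.glint_radius**2
    return mask


def generate_scene(
    config: SceneConfig, scheme: ClassScheme = DEFAULT_SCHEME
) -> tuple[MultispectralScene, LabelRaster]:
    """Generate one scene and its noise-free ground-truth labels.

    Layout order: bank margins, boat rectangles, then bloom blobs over the
    remaining water so the configured bloom fraction (of all pixels) is hit
    exactly up to rounding.  Radiometry order: class priors (+ per-class iid
    spread), multiplicative shadows, glint override toward saturation,
    salt-and-pepper impulses, Gaussian noise, clip to [0, 1].
    """
    # independent child streams so switching one component (say shadows) on
    # or off never perturbs the draws of the others
    children = np.random.SeedSequence(config.seed).spawn(5)
    rng_layout, rng_radiom, rng_shadow, rng_glint, rng_noise = (
        np.random.default_rng(c) for c in children
    )
    h, w = config.height, config.width

    bank = _bank_mask(config, rng_layout)
    water = ~bank
    boat = _boat_mask(config, water, rng_layout)
    water_open = water & ~boat
    bloom = _bloom_mask(config, water_open, rng_layout)

    labels = np.full((h, w), scheme.index("water"), dtype=np.int64)
    labels[bank] = scheme.index("bank")
    labels[boat] = scheme.index("boat")
    labels[bloom] = scheme.bloom_index

    shadow = _shadow_factor(config, rng_shadow)
    glint = _glint_mask(config, rng_glint)

    bands = {}
    for bi, band in enumerate(BAND_IDS):
        img = np.zeros((h, w))
        for name in ("water", "bloom", "bank", "boat"):
            sel = labels == scheme.index(name)
            prior = config.priors[name]
            img[sel] = prior.means[bi]
            if prior.spread > 0:
                img[sel] += prior.spread * rng_radiom.standard_normal(int(sel.sum()))
        img *= shadow
        img[glint] = 0.98  # specular saturation overrides everything
        if config.salt_pepper_density > 0:
            u = rng_noise.random((h, w))
            img[u < config.salt_pepper_density / 2] = 0.0
            img[(u >= config.salt_pepper_density / 2) & (u < config.salt_pepper_density)] = 1.0
        if config.gaussian_sigma > 0:
            img += config.gaussian_sigma * rng_noise.standard_normal((h, w))
        bands[band] = np.clip(img, 0.0, 1.0)

    scene = MultispectralScene(bands=bands)
    return scene, LabelRaster(data=labels, scheme=scheme)


def generate_dataset(
    n: int, config: SceneConfig, seed: int | None = None
) -> list[tuple[MultispectralScene, LabelRaster]]:
    """Generate ``n`` scenes with per-scene seeds derived from one master seed.

    ``seed`` defaults to the config's own seed.  Reruns with the same
    arguments reproduce the list exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    master = config.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(n) & 0x7FFFFFFF
    out = []
    for s in child_seeds:
        cfg = dataclasses.replace(config, seed=int(s))
        out.append(generate_scene(cfg))
    return out
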