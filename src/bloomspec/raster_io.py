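"""Data model and I/O for five-band multispectral scenes and label rasters.

The sensor delivers five co-registered monochrome channels: blue (B1),
green (B2), red (B3), red-edge (B4) and near-infrared (B5).  Scenes are held
as reflectance fractions in [0, 1]; raw digital numbers are rescaled on read.
Pixel coordinates are 0-based, row-major, origin at the top-left corner.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

BAND_IDS = ("B1", "B2", "B3", "B4", "B5")

__all__ = [
    "BAND_IDS",
    "MultispectralScene",
    "ClassScheme",
    "LabelRaster",
    "DEFAULT_SCHEME",
    "ShapeError",
    "FormatError",
    "ValidationError",
    "read_scene",
    "write_scene",
    "read_label_raster",
    "write_label_raster",
]


class ShapeError(ValueError):
    """Band grids or rasters disagree in shape."""


class FormatError(ValueError):
    """A file does not carry the expected number of channels/bit depth."""


class ValidationError(ValueError):
    """A raster violates its class scheme or is degenerate."""


@dataclasses.dataclass(frozen=True)
class MultispectralScene:
    """Co-registered five-band reflectance raster.

    Parameters
    ----------
    bands
        Mapping from band identifier (``B1``..``B5``) to a ``(H, W)`` float
        array of reflectance fractions in [0, 1].
    valid_mask
        Optional ``(H, W)`` boolean array; ``True`` marks usable pixels.
    """

    bands: Mapping[str, np.ndarray]
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if set(self.bands) != set(BAND_IDS):
            raise FormatError(
                f"expected exactly bands {BAND_IDS}, got {sorted(self.bands)}"
            )
        shapes = {b: np.asarray(g).shape for b, g in self.bands.items()}
        ref = shapes["B1"]
        if len(ref) != 2 or min(ref) < 1:
            raise ShapeError(f"band grids must be 2-D and non-empty, got {ref}")
        if any(s != ref for s in shapes.values()):
            raise ShapeError(f"band shapes differ: {shapes}")
        fixed = {}
        for b in BAND_IDS:
            g = np.asarray(self.bands[b], dtype=np.float64)
            if not np.all(np.isfinite(g)):
                raise ValidationError(f"band {b} contains non-finite values")
            if g.min() < 0.0 or g.max() > 1.0:
                raise ValidationError(
                    f"band {b} reflectance outside [0, 1]: "
                    f"[{g.min():.4g}, {g.max():.4g}]"
                )
            fixed[b] = g
        object.__setattr__(self, "bands", fixed)
        if self.valid_mask is not None:
            m = np.asarray(self.valid_mask, dtype=bool)
            if m.shape != ref:
                raise ShapeError("valid_mask shape does not match bands")
            object.__setattr__(self, "valid_mask", m)

    @property
    def height(self) -> int:
        return self.bands["B1"].shape[0]

    @property
    def width(self) -> int:
        return self.bands["B1"].shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["B1"].shape

    def as_array(self) -> np.ndarray:
        """Stack the five bands into a ``(5, H, W)`` array (B1..B5 order)."""
        return np.stack([self.bands[b] for b in BAND_IDS], axis=0)

    def with_mask(self, mask: np.ndarray) -> "MultispectralScene":
        """Return a copy whose valid_mask is intersected with ``mask``."""
        m = np.asarray(mask, dtype=bool)
        if self.valid_mask is not None:
            m = m & self.valid_mask
        return MultispectralScene(bands=dict(self.bands), valid_mask=m)


@dataclasses.dataclass(frozen=True)
class ClassScheme:
    """Ordered class names with designated bloom and ignore classes.

    The ignore class is excluded from every metric, from training loss and
    from pollution-area denominators.
    """

    names: tuple[str, ...]
    bloom_index: int
    ignore_index: int

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate class names: {names}")
        required = {"water", "bloom", "bank", "ignore"}
        if not required.issubset(names):
            raise ValidationError(
                f"scheme must contain at least {sorted(required)}, got {names}"
            )
        if names[self.bloom_index] != "bloom":
            raise ValidationError("bloom_index does not point at 'bloom'")
        if names[self.ignore_index] != "ignore":
            raise ValidationError("ignore_index does not point at 'ignore'")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    @property
    def n_scored(self) -> int:
        """Number of classes the model predicts (ignore is never predicted)."""
        return len(self.names) - 1

    def index(self, name: str) -> int:
        return self.names.index(name)


#: Default scheme used by the synthetic-scene generator and the CLI.
DEFAULT_SCHEME = ClassScheme(
    names=("water", "bloom", "bank", "boat", "ignore"),
    bloom_index=1,
    ignore_index=4,
)


@dataclasses.dataclass(frozen=True)
class LabelRaster:
    """Per-pixel class indices under a :class:`ClassScheme`."""

    data: np.ndarray
    scheme: ClassScheme

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2 or d.size == 0:
            raise ValidationError(f"label raster must be non-empty 2-D, got {d.shape}")
        if not np.issubdtype(d.dtype, np.integer):
            if np.any(d != np.round(d)):
                raise ValidationError("label raster must hold integers")
        d = d.astype(np.int64)
        if d.min() < 0 or d.max() >= self.scheme.n_classes:
            raise ValidationError(
                f"label values outside [0, {self.scheme.n_classes - 1}]: "
                f"[{d.min()}, {d.max()}]"
            )
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def evaluated_mask(self) -> np.ndarray:
        """Boolean mask of pixels that are not the ignore class."""
        return self.data != self.scheme.ignore_index


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _load_gray(path: Path) -> np.ndarray:
    """Load one grayscale raster (TIFF via tifffile, else imageio)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return np.asarray(arr)


def _normalize(raw: np.ndarray, dn_scale: float | None) -> np.ndarray:
    """Digital numbers -> reflectance in [0, 1].

    With an explicit ``dn_scale`` the data are divided by it.  Without one,
    float data already inside [0, 1] pass through untouched and anything else
    is min-max normalized.  The map is monotone either way; the result is
    clipped to [0, 1].
    """
    raw = np.asarray(raw, dtype=np.float64)
    if dn_scale is not None:
        if dn_scale <= 0:
            raise ValueError(f"dn_scale must be positive, got {dn_scale}")
        out = raw / float(dn_scale)
    elif raw.min() >= 0.0 and raw.max() <= 1.0:
        out = raw
    else:
        lo, hi = raw.min(), raw.max()
        out = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def read_scene(
    paths: str | Path | Sequence[str | Path],
    band_order: Sequence[str] = BAND_IDS,
    dn_scale: float | None = None,
) -> MultispectralScene:
    """Read a five-band scene from one multiband file or five per-band files.

    Parameters
    ----------
    paths
        A single multiband TIFF path, or a sequence of five grayscale paths.
    band_order
        Band identifier assigned to each channel/file, default ``B1..B5``
        (multispectral export channel order varies between tools).
    dn_scale
        Divisor converting raw digital numbers to reflectance (e.g. 65535 for
        16-bit DN).  Omit for data already expressed as reflectance.
    """
    band_order = list(band_order)
    if sorted(band_order) != sorted(BAND_IDS):
        raise FormatError(f"band_order must be a permutation of {BAND_IDS}")

    if isinstance(paths, (str, Path)):
        stack = _load_gray(Path(paths))
        if stack.ndim != 3:
            raise FormatError(f"multiband file must be 3-D, got shape {stack.shape}")
        # accept channel-first or channel-last; when both axes could hold
        # channels, the smaller one is the channel axis
        first_ok = stack.shape[0] >= 5
        last_ok = stack.shape[-1] >= 5
        if first_ok and (not last_ok or stack.shape[0] <= stack.shape[-1]):
            channels = [stack[i] for i in range(stack.shape[0])]
        elif last_ok:
            channels = [stack[..., i] for i in range(stack.shape[-1])]
        else:
            raise FormatError(
                f"multiband file has fewer than 5 channels: shape {stack.shape}"
            )
        channels = channels[: len(band_order)]
    else:
        files = [Path(p) for p in paths]
        if len(files) < 5:
            raise FormatError(f"need 5 band files, got {len(files)}")
        channels = [_load_gray(p) for p in files]

    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ShapeError(f"band shapes differ: {sorted(shapes)}")

    bands = {b: _normalize(c, dn_scale) for b, c in zip(band_order, channels)}
    return MultispectralScene(bands=bands)


def write_scene(scene: MultispectralScene, path: str | Path) -> None:
    """Write a scene as a 5-channel float32 TIFF (B1..B5 channel order)."""
    import tifffile

    tifffile.imwrite(
        Path(path),
        scene.as_array().astype(np.float32),
        photometric="minisblack",
    )


def write_label_raster(labels: LabelRaster, path: str | Path) -> None:
    """Write class indices as a single-channel 8-bit image (PNG or TIFF)."""
    if labels.scheme.n_classes > 256:
        raise ValidationError("more than 256 classes do not fit 8-bit storage")
    path = Path(path)
    data = labels.data.astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def read_label_raster(path: str | Path, scheme: ClassScheme) -> LabelRaster:
    """Read a single-channel integer image back as a validated label raster."""
    arr = _load_gray(Path(path))
    if arr.ndim != 2:
        raise ValidationError(f"label raster must be single-channel, got {arr.shape}")
    return LabelRaster(data=arr, scheme=scheme)
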