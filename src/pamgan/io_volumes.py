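"""Photoacoustic volume container, on-disk formats and en-face projections.

A PAM scan is stored as a 3D amplitude array indexed ``(y, x, z)``:
``y`` is the slow scan axis (one b-scan per index), ``x`` the fast/lateral
axis and ``z`` depth.  A b-scan is therefore the ``(x, z)`` plane.  Two
on-disk formats are supported: multi-page TIFF (uint8 grayscale, one page
per slow-scan position, rows = depth, columns = lateral) and HDF5 (dataset
``"volume"`` with pitch/modality attributes, lossless for float data).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile


class Modality(str, enum.Enum):
    """Which imaging mode (or processing stage) produced a volume."""

    AR = "AR"
    OR = "OR"
    DEEP_AR = "DEEP_AR"
    GENERATED = "GENERATED"
    TRUTH = "TRUTH"


class ValueScale(str, enum.Enum):
    FLOAT_UNIT = "float_unit"  # float in [0, 1]
    UINT8 = "uint8"            # integer in [0, 255]


class VolumeError(ValueError):
    """Invalid volume data or metadata."""


@dataclass
class PamVolume:
    """3D photoacoustic amplitude volume with physical pixel pitches.

    Parameters
    ----------
    data:
        Non-negative amplitudes, shape ``(n_y, n_x, n_z)``.
    dx, dy:
        Lateral pixel pitches in micrometres (fast and slow scan).
    dz:
        Depth pitch in micrometres.
    modality:
        Imaging mode that produced the volume.
    value_scale:
        ``float_unit`` for float amplitudes in [0, 1], ``uint8`` for 8-bit.
    """

    data: np.ndarray
    dx: float
    dy: float
    dz: float
    modality: Modality = Modality.AR
    value_scale: ValueScale = ValueScale.FLOAT_UNIT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.modality = Modality(self.modality)
        self.value_scale = ValueScale(self.value_scale)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D (y, x, z) data, got ndim={self.data.ndim}")
        if min(self.data.shape) == 0:
            raise VolumeError(f"empty volume: shape {self.data.shape}")
        for name, pitch in (("dx", self.dx), ("dy", self.dy), ("dz", self.dz)):
            if not (pitch > 0):
                raise VolumeError(f"pixel pitch {name}={pitch} must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains non-finite values")
        if self.data.min() < 0:
            raise VolumeError("volume contains negative amplitudes")
        limit = 1.0 if self.value_scale is ValueScale.FLOAT_UNIT else 255
        if self.data.max() > limit:
            raise VolumeError(
                f"amplitudes exceed {limit} for value_scale={self.value_scale.value}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_y(self) -> int:
        return self.data.shape[0]

    def bscan(self, y: int) -> np.ndarray:
        """The b-scan (x, z plane) at slow-scan index ``y``."""
        return self.data[y]

    def with_data(self, data: np.ndarray, **changes) -> "PamVolume":
        """Copy of this volume with new data (metadata preserved)."""
        return replace(self, data=data, **changes)


@dataclass
class MapImage:
    """Maximum-amplitude projection with the depth of each maximum."""

    amplitude: np.ndarray   # (n_y, n_x) per-column depth maxima
    depth_index: np.ndarray  # (n_y, n_x) int index of the maximum, ties -> shallowest
    dz: float = 1.0

    def depth_um(self) -> np.ndarray:
        return self.depth_index * self.dz


def max_amplitude_projection(vol: PamVolume) -> MapImage:
    """En-face MAP: per-(y, x) maximum over depth, ties broken toward z=0.

    The MAP is the standard en-face rendering of a PAM volume: each lateral
    position shows the strongest absorber in its A-line, and the argmax
    depth feeds the depth-encoded rendering.
    """
    amplitude = vol.data.max(axis=2)
    depth_index = vol.data.argmax(axis=2)  # np.argmax returns the first (shallowest) tie
    return MapImage(amplitude=amplitude, depth_index=depth_index, dz=vol.dz)


def depth_encoded_map(vol: PamVolume, colormap_bins: int = 256, cmap: str = "jet") -> np.ndarray:
    """Depth-encoded MAP: hue from the argmax depth, brightness from amplitude.

    Returns a float RGB image in [0, 1] of shape ``(n_y, n_x, 3)``.
    Deterministic for a fixed input.
    """
    if colormap_bins < 2:
        raise VolumeError("colormap_bins must be >= 2")
    import matplotlib

    proj = max_amplitude_projection(vol)
    n_z = vol.data.shape[2]
    # Bin depth indices into colormap entries; single-slice volumes map to bin 0.
    if n_z > 1:
        bins = (proj.depth_index * (colormap_bins - 1)) // (n_z - 1)
    else:
        bins = np.zeros_like(proj.depth_index)
    lut = matplotlib.colormaps[cmap](np.linspace(0.0, 1.0, colormap_bins))[:, :3]
    rgb = lut[bins]
    amp = proj.amplitude.astype(np.float64)
    if vol.value_scale is ValueScale.UINT8:
        amp = amp / 255.0
    return rgb * amp[..., None]


def _check_meta(dx: float, dy: float, dz: float) -> None:
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise VolumeError(f"pixel pitches must be positive, got dx={dx} dy={dy} dz={dz}")


def write_volume(vol: PamVolume, path: str | Path, format: str | None = None) -> None:
    """Write a volume to multi-page TIFF or HDF5.

    TIFF: one uint8 page per slow-scan index, rows = depth z, columns =
    lateral x (b-scan display convention); float volumes are scaled to the
    8-bit range and tagged so the scale survives the round trip.
    HDF5: dataset ``"volume"`` stored at full precision with ``dx``/``dy``/
    ``dz``/``modality``/``value_scale`` attributes.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff_stack":
        # page k = slow-scan y=k; each page transposed (z rows, x cols).
        pages = np.transpose(vol.data, (0, 2, 1))
        if vol.value_scale is ValueScale.UINT8:
            pages = pages.astype(np.uint8)
            scaled = 0
        else:
            pages = np.round(pages * 255.0).astype(np.uint8)
            scaled = 1
        desc = (
            f"pamgan dx={vol.dx} dy={vol.dy} dz={vol.dz} "
            f"modality={vol.modality.value} float_scaled={scaled}"
        )
        tifffile.imwrite(path, pages, photometric="minisblack", description=desc)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=vol.data)
            ds.attrs["dx"] = vol.dx
            ds.attrs["dy"] = vol.dy
            ds.attrs["dz"] = vol.dz
            ds.attrs["modality"] = vol.modality.value
            ds.attrs["value_scale"] = vol.value_scale.value
    else:
        raise VolumeError(f"unknown format {fmt!r} (use 'tiff_stack' or 'hdf5')")


def read_volume(
    path: str | Path,
    format: str | None = None,
    meta: dict | None = None,
) -> PamVolume:
    """Read a volume written by :func:`write_volume`.

    ``meta`` may supply/override ``dx``/``dy``/``dz``/``modality`` for TIFF
    stacks from other sources that carry no metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    meta = dict(meta or {})
    if fmt == "tiff_stack":
        try:
            with tifffile.TiffFile(path) as tf:
                pages = tf.asarray()
                desc = tf.pages[0].description or ""
        except (tifffile.TiffFileError, ValueError) as exc:
            raise VolumeError(f"unreadable TIFF {path}: {exc}") from exc
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise VolumeError(f"TIFF pages do not form a stack: shape {pages.shape}")
        tags = _parse_desc(desc)
        tags.update(meta)
        data = np.transpose(pages, (0, 2, 1))  # (y, z, x) -> (y, x, z)
        scale = ValueScale.UINT8
        if int(tags.get("float_scaled", 0)):
            data = data.astype(np.float64) / 255.0
            scale = ValueScale.FLOAT_UNIT
        dx = float(tags.get("dx", 1.0))
        dy = float(tags.get("dy", 1.0))
        dz = float(tags.get("dz", 1.0))
        _check_meta(dx, dy, dz)
        return PamVolume(
            data=data, dx=dx, dy=dy, dz=dz,
            modality=Modality(tags.get("modality", "AR")),
            value_scale=ValueScale(tags.get("value_scale", scale)),
        )
    if fmt == "hdf5":
        try:
            with h5py.File(path, "r") as f:
                ds = f["volume"]
                data = ds[()]
                tags = {k: ds.attrs[k] for k in ("dx", "dy", "dz", "modality", "value_scale")}
        except (OSError, KeyError) as exc:
            raise VolumeError(f"unreadable HDF5 {path}: {exc}") from exc
        tags.update(meta)
        dx, dy, dz = float(tags["dx"]), float(tags["dy"]), float(tags["dz"])
        _check_meta(dx, dy, dz)
        return PamVolume(
            data=data, dx=dx, dy=dy, dz=dz,
            modality=Modality(str(tags["modality"])),
            value_scale=ValueScale(str(tags["value_scale"])),
        )
    raise VolumeError(f"unknown format {fmt!r}")


def save_png(image: np.ndarray, path: str | Path) -> None:
    """Export a 2D grayscale or RGB float image in [0, 1] as 8-bit PNG."""
    arr = np.asarray(image, dtype=np.float64)
    arr = np.clip(arr, 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "tiff_stack"
    if suffix in {".h5", ".hdf5"}:
        return "hdf5"
    raise VolumeError(f"cannot infer volume format from suffix {suffix!r}")


def _parse_desc(desc: str) -> dict:
    tags: dict = {}
    if not desc.startswith("pamgan "):
        return tags
    for token in desc.split()[1:]:
        if "=" in token:
            key, value = token.split("=", 1)
            tags[key] = value
    return tags
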