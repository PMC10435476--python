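"""B-scan preprocessing: normalization, A-line filtering, patching, datasets.

The chain mirrors standard PAM practice: amplitudes are normalized once per
volume (so relative amplitude across depth is preserved), A-lines are
bandpass-filtered to the transducer band and envelope-detected, b-scans are
tiled into fixed-size patches in deterministic raster order (no random
jitter, so paired tiles stay co-registered), and patches are assembled into
paired (same coordinates in co-registered AR/OR volumes) or unpaired
(decoupled, shuffled pools) datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import signal

from .io_volumes import PamVolume, ValueScale


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class BandSpec:
    """Transducer passband for A-line bandpass filtering.

    Defaults cover the 50 MHz transducer of the dual AR/OR system with an
    80% fractional band (10-90 MHz); the 5 MHz deep-AR transducer uses
    ``BandSpec.deep_ar()`` (1-9 MHz).
    """

    low_mhz: float = 10.0
    high_mhz: float = 90.0
    sample_rate_mhz: float = 250.0
    order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.low_mhz < self.high_mhz < self.sample_rate_mhz / 2):
            raise PreprocessError(
                f"band ({self.low_mhz}, {self.high_mhz}) MHz must satisfy "
                f"0 < low < high < Nyquist ({self.sample_rate_mhz / 2} MHz)"
            )

    @classmethod
    def deep_ar(cls, sample_rate_mhz: float = 50.0) -> "BandSpec":
        return cls(low_mhz=1.0, high_mhz=9.0, sample_rate_mhz=sample_rate_mhz)


@dataclass(frozen=True)
class BScanPatch:
    """A fixed-size tile of a b-scan with its source coordinates."""

    pixels: np.ndarray        # (patch, patch) in the source value scale
    origin: tuple[int, int]   # (x0, z0) in b-scan coordinates
    source_index: int = 0     # slow-scan index y

    def __post_init__(self) -> None:
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise PreprocessError(f"negative patch origin {self.origin}")


@dataclass
class PatchSet:
    patches: list[BScanPatch]
    source_shape: tuple[int, int]  # (n_x, n_z)
    patch_size: int
    stride: int

    def __len__(self) -> int:
        return len(self.patches)

    def origins(self) -> list[tuple[int, int]]:
        return [p.origin for p in self.patches]


@dataclass
class PairedDataset:
    """Aligned (AR, OR) patch tuples sharing origin and slow-scan index."""

    pairs: list[tuple[BScanPatch, BScanPatch]]

    def __len__(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.stack([p.pixels for p, _ in self.pairs])
        o = np.stack([o.pixels for _, o in self.pairs])
        return a, o


@dataclass
class UnpairedDataset:
    """Two decoupled patch pools (domain A = AR, domain O = OR)."""

    pool_a: list[BScanPatch]
    pool_o: list[BScanPatch]

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.stack([p.pixels for p in self.pool_a]),
            np.stack([p.pixels for p in self.pool_o]),
        )


def normalize_volume(vol: PamVolume) -> PamVolume:
    """Divide the whole volume by its global maximum (new max = 1.0).

    Normalization is global, not per-slice: relative amplitude between
    depths and b-scans carries the physical attenuation signature and must
    survive preprocessing.
    """
    data = vol.data.astype(np.float64)
    peak = data.max()
    if peak <= 0:
        raise PreprocessError("cannot normalize an all-zero volume")
    return vol.with_data(data / peak, value_scale=ValueScale.FLOAT_UNIT)


def bandpass_envelope(alines: np.ndarray, band: BandSpec) -> np.ndarray:
    """Zero-phase bandpass then analytic-signal envelope, per A-line.

    ``alines`` has depth along the last axis.  Filtering is a
    forward-backward Butterworth (no group delay, so the depth axis is not
    shifted and AR/OR pairing survives); the envelope is the magnitude of
    the analytic signal.  Output is non-negative with the input shape.
    """
    alines = np.asarray(alines, dtype=np.float64)
    n = alines.shape[-1]
    if n <= 3 * band.order:
        raise PreprocessError(
            f"A-line length {n} too short for order-{band.order} filtering"
        )
    nyq = band.sample_rate_mhz / 2.0
    sos = signal.butter(
        band.order, [band.low_mhz / nyq, band.high_mhz / nyq], btype="bandpass",
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, alines, axis=-1)
    return np.abs(signal.hilbert(filtered, axis=-1))


def to_uint8(data: np.ndarray) -> np.ndarray:
    """Map [0, 1] float amplitudes to uint8 with round-half-up."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise PreprocessError("to_uint8 input must lie in [0, 1]")
    return np.floor(arr * 255.0 + 0.5).astype(np.uint8)


def from_uint8(data: np.ndarray) -> np.ndarray:
    return np.asarray(data, dtype=np.float64) / 255.0


def _tile_starts(extent: int, patch: int, stride: int) -> list[int]:
    """Raster-order tile starts; the last tile is shifted inward to end at the border."""
    if patch > extent:
        raise PreprocessError(f"patch size {patch} exceeds extent {extent}")
    starts = list(range(0, extent - patch + 1, stride))
    if starts[-1] != extent - patch:
        starts.append(extent - patch)
    return starts


def extract_patches(
    bscan: np.ndarray,
    patch_size: int = 256,
    stride: int | None = None,
    source_index: int = 0,
) -> PatchSet:
    """Tile a b-scan into ``patch_size`` squares in deterministic raster order.

    No random jitter: calling twice yields identical tiles, which is what
    keeps AR/OR patch pairs co-registered.  Edge tiles are shifted inward so
    they end exactly at the border (every tile holds real data); b-scans
    smaller than ``patch_size`` are zero-padded up to it first.  Every
    source pixel is covered by at least one tile.
    """
    if patch_size <= 0:
        raise PreprocessError(f"patch_size must be positive, got {patch_size}")
    stride = stride or patch_size
    if stride <= 0:
        raise PreprocessError(f"stride must be positive, got {stride}")
    bscan = np.asarray(bscan)
    n_x, n_z = bscan.shape
    if n_x < patch_size or n_z < patch_size:
        padded = np.zeros((max(n_x, patch_size), max(n_z, patch_size)), dtype=bscan.dtype)
        padded[:n_x, :n_z] = bscan
        bscan = padded
        n_x, n_z = bscan.shape
    patches = [
        BScanPatch(
            pixels=bscan[x0 : x0 + patch_size, z0 : z0 + patch_size].copy(),
            origin=(x0, z0),
            source_index=source_index,
        )
        for x0 in _tile_starts(n_x, patch_size, stride)
        for z0 in _tile_starts(n_z, patch_size, stride)
    ]
    return PatchSet(
        patches=patches, source_shape=(n_x, n_z), patch_size=patch_size, stride=stride
    )


def _volume_patches(vol: PamVolume, patch_size: int, stride: int | None) -> list[BScanPatch]:
    out: list[BScanPatch] = []
    for y in range(vol.n_y):
        out.extend(extract_patches(vol.bscan(y), patch_size, stride, source_index=y).patches)
    return out


def build_paired(
    ar_vol: PamVolume,
    or_vol: PamVolume,
    patch_size: int = 256,
    stride: int | None = None,
) -> PairedDataset:
    """Aligned (AR, OR) tuples from co-registered volumes — the cGAN input."""
    if ar_vol.shape != or_vol.shape:
        raise PreprocessError(
            f"AR/OR shape mismatch: {ar_vol.shape} vs {or_vol.shape} (not co-registered)"
        )
    if (ar_vol.dx, ar_vol.dy, ar_vol.dz) != (or_vol.dx, or_vol.dy, or_vol.dz):
        raise PreprocessError("AR/OR pixel pitches differ (not co-registered)")
    a_patches = _volume_patches(ar_vol, patch_size, stride)
    o_patches = _volume_patches(or_vol, patch_size, stride)
    pairs = list(zip(a_patches, o_patches))
    for pa, po in pairs:
        assert pa.origin == po.origin and pa.source_index == po.source_index
    return PairedDataset(pairs=pairs)


def build_unpaired(
    ar_vol: PamVolume,
    or_vol: PamVolume,
    patch_size: int = 256,
    stride: int | None = None,
    seed: int = 0,
) -> UnpairedDataset:
    """Two independently shuffled patch pools — the CycleGAN input.

    The shuffles are decoupled (different substreams per domain) and
    deterministic given ``seed``.
    """
    rng_a = np.random.default_rng([seed, 0xA])
    rng_o = np.random.default_rng([seed, 0x0])
    pool_a = _volume_patches(ar_vol, patch_size, stride)
    pool_o = _volume_patches(or_vol, patch_size, stride)
    return UnpairedDataset(
        pool_a=[pool_a[i] for i in rng_a.permutation(len(pool_a))],
        pool_o=[pool_o[i] for i in rng_o.permutation(len(pool_o))],
    )


def preprocess_volume(
    vol: PamVolume,
    band: BandSpec | None = None,
    apply_bandpass: bool = True,
) -> PamVolume:
    """Full per-volume chain: (bandpass+envelope) then global normalization."""
    data = vol.data.astype(np.float64)
    if apply_bandpass and band is not None:
        data = bandpass_envelope(data, band)  # depth is the last axis of (y, x, z)
    out = vol.with_data(data, value_scale=ValueScale.FLOAT_UNIT)
    return normalize_volume(out)


# ---------------------------------------------------------------------------
# On-disk dataset persistence (HDF5 groups "paired/A|O", "unpaired/A|O")

def _save_pool(group: h5py.Group, patches: list[BScanPatch]) -> None:
    group.create_dataset("pixels", data=np.stack([p.pixels for p in patches]))
    group.create_dataset("origin", data=np.array([p.origin for p in patches]))
    group.create_dataset("source_index", data=np.array([p.source_index for p in patches]))


def _load_pool(group: h5py.Group) -> list[BScanPatch]:
    pixels = group["pixels"][()]
    origins = group["origin"][()]
    sources = group["source_index"][()]
    return [
        BScanPatch(pixels=pixels[i], origin=tuple(int(v) for v in origins[i]),
                   source_index=int(sources[i]))
        for i in range(len(pixels))
    ]


def save_dataset(dataset: PairedDataset | UnpairedDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        if isinstance(dataset, PairedDataset):
            grp = f.create_group("paired")
            _save_pool(grp.create_group("A"), [a for a, _ in dataset.pairs])
            _save_pool(grp.create_group("O"), [o for _, o in dataset.pairs])
        else:
            grp = f.create_group("unpaired")
            _save_pool(grp.create_group("A"), dataset.pool_a)
            _save_pool(grp.create_group("O"), dataset.pool_o)


def load_dataset(path: str | Path) -> PairedDataset | UnpairedDataset:
    with h5py.File(path, "r") as f:
        if "paired" in f:
            a = _load_pool(f["paired/A"])
            o = _load_pool(f["paired/O"])
            return PairedDataset(pairs=list(zip(a, o)))
        if "unpaired" in f:
            return UnpairedDataset(
                pool_a=_load_pool(f["unpaired/A"]),
                pool_o=_load_pool(f["unpaired/O"]),
            )
    raise PreprocessError(f"{path} holds neither a paired nor an unpaired dataset")
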