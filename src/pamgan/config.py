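"""Run configuration: one YAML file drives the whole pipeline.

A config gathers the phantom/PSF/noise blocks of the simulator, the
preprocessing geometry, the network and optimizer settings, and the
evaluation ROIs.  One global seed is expanded per stage through a stable
hash, so a single integer reproduces the full run.  Unknown keys warn
rather than error (forward compatibility); invalid values are collected
into a validation report naming each offending field.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gan_models import DiscriminatorSpec, GeneratorSpec
from .metrics import Roi
from .phantom import (
    AR_NOISE,
    AR_PSF,
    OR_NOISE,
    OR_PSF,
    NoiseModel,
    PhantomSpec,
    Pitches,
    PsfModel,
)
from .preprocess import BandSpec
from .training import TrainConfig


class ConfigError(ValueError):
    def __init__(self, errors: list[str]) -> None:
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))
        self.errors = errors


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (< 2^31)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class PreprocessConfig:
    patch_size: int = 64
    stride: int | None = None
    apply_bandpass: bool = False
    band: BandSpec | None = None


@dataclass(frozen=True)
class EvaluateConfig:
    """ROIs (0-based half-open bounds) and the FWHM profile line."""

    signal_roi: tuple[int, int, int, int] | None = None
    noise_roi: tuple[int, int, int, int] | None = None
    profile_axis: str = "lateral"
    profile_index: int | None = None
    source: str = "map"  # {"map", "bscan"}: which image the metrics are read from
    bscan_index: int = 0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    log_level: str = "INFO"
    n_volumes: int = 2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    pitches: Pitches = field(default_factory=Pitches)
    psf_ar: PsfModel = AR_PSF
    psf_or: PsfModel = OR_PSF
    noise_ar: NoiseModel = AR_NOISE
    noise_or: NoiseModel = OR_NOISE
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    mode: str = "cgan"  # {"cgan", "cyclegan"}
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def signal_roi(self) -> Roi | None:
        if self.evaluate.signal_roi is None:
            return None
        return Roi(*self.evaluate.signal_roi, role="signal")

    def noise_roi(self) -> Roi | None:
        if self.evaluate.noise_roi is None:
            return None
        return Roi(*self.evaluate.noise_roi, role="background")


_SECTION_TYPES = {
    "phantom": PhantomSpec,
    "pitches": Pitches,
    "psf_ar": PsfModel,
    "psf_or": PsfModel,
    "noise_ar": NoiseModel,
    "noise_or": NoiseModel,
    "preprocess": PreprocessConfig,
    "generator": GeneratorSpec,
    "discriminator": DiscriminatorSpec,
    "train": TrainConfig,
    "evaluate": EvaluateConfig,
}
_SCALARS = {"seed", "out_dir", "log_level", "n_volumes", "mode"}


def _build_section(cls, raw: dict, section: str, errors: list[str], warnings: list[str]):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in names:
            warnings.append(f"{section}.{key}: unknown key ignored")
            continue
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    if section == "preprocess" and isinstance(kwargs.get("band"), dict):
        try:
            kwargs["band"] = BandSpec(**kwargs["band"])
        except (TypeError, ValueError) as exc:
            errors.append(f"preprocess.band: {exc}")
            kwargs.pop("band")
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def parse_config(raw: dict) -> tuple[RunConfig | None, list[str], list[str]]:
    """Build a RunConfig from a parsed YAML mapping.

    Returns ``(config_or_None, errors, warnings)``; the config is None
    whenever errors are present.
    """
    errors: list[str] = []
    warnings: list[str] = []
    kwargs: dict = {}
    for key, value in (raw or {}).items():
        if key in _SCALARS:
            kwargs[key] = value
        elif key in _SECTION_TYPES:
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a mapping")
                continue
            section = _build_section(_SECTION_TYPES[key], value, key, errors, warnings)
            if section is not None:
                kwargs[key] = section
        else:
            warnings.append(f"{key}: unknown key ignored")
    if kwargs.get("mode", "cgan") not in ("cgan", "cyclegan"):
        errors.append(f"mode: must be 'cgan' or 'cyclegan', got {kwargs['mode']!r}")
    try:
        cfg = RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
        cfg = None
    if errors:
        return None, errors, warnings
    return cfg, errors, warnings


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; raises ConfigError listing violations."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    cfg, errors, warnings = parse_config(raw or {})
    for w in warnings:
        import logging

        logging.getLogger("pamgan").warning("config: %s", w)
    if cfg is None:
        raise ConfigError(errors)
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    """Round-trippable plain-dict form of a config (tuples as lists)."""
    return _sanitize(dataclasses.asdict(cfg))


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float):
        if obj == float("inf"):
            return "inf"
        if obj == float("-inf"):
            return "-inf"
    return obj
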