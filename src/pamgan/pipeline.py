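"""Pipeline stages: simulate -> preprocess -> train -> enhance -> evaluate.

Each stage reads its prerequisites from the run directory, writes its
artifact plus a provenance JSON (parameters, derived seeds, input/output
content hashes), and is deterministic under the run's global seed.
Deleting a downstream artifact never touches an upstream one; a missing
prerequisite raises :class:`DependencyError` naming the stage to run
first.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import reconstruct
from .config import RunConfig, config_to_dict, _sanitize
from .io_volumes import (
    depth_encoded_map,
    max_amplitude_projection,
    read_volume,
    save_png,
    write_volume,
)
from .metrics import compare_images
from .phantom import make_dataset
from .preprocess import (
    build_paired,
    build_unpaired,
    load_dataset,
    normalize_volume,
    preprocess_volume,
    save_dataset,
)
from .training import checkpoint, restore, train_cgan, train_cyclegan

log = logging.getLogger("pamgan")

STAGES = ("simulate", "preprocess", "train", "enhance", "evaluate")


class DependencyError(RuntimeError):
    def __init__(self, stage: str, missing: Path, needed_stage: str) -> None:
        super().__init__(
            f"stage '{stage}' needs {missing}; run stage '{needed_stage}' first"
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_provenance(stage_dir: Path, stage: str, params: dict,
                      inputs: list[Path], outputs: list[Path]) -> None:
    record = {
        "stage": stage,
        "params": _sanitize(params),
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p): _sha256(p) for p in outputs},
        "wall_seconds": params.pop("_wall_seconds", None),
    }
    (stage_dir / "provenance.json").write_text(json.dumps(record, indent=2))


def _require(stage: str, path: Path, needed: str) -> Path:
    if not path.exists():
        raise DependencyError(stage, path, needed)
    return path


def stage_simulate(cfg: RunConfig, out_dir: Path) -> list[Path]:
    t0 = time.perf_counter()
    stage_dir = out_dir / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("simulate")
    pairs, provenance = make_dataset(
        cfg.phantom, cfg.psf_ar, cfg.psf_or, cfg.noise_ar, cfg.noise_or,
        n_volumes=cfg.n_volumes, pitches=cfg.pitches, seed=seed,
    )
    outputs = []
    for i, pair in enumerate(pairs):
        for tag, vol in (("truth", pair.truth), ("ar", pair.ar), ("or", pair.or_)):
            path = stage_dir / f"{tag}_{i}.h5"
            write_volume(vol, path, "hdf5")
            outputs.append(path)
    provenance["_wall_seconds"] = time.perf_counter() - t0
    _write_provenance(stage_dir, "simulate", provenance, [], outputs)
    log.info("simulate: wrote %d volumes to %s", len(outputs), stage_dir)
    return outputs


def stage_preprocess(cfg: RunConfig, out_dir: Path) -> list[Path]:
    t0 = time.perf_counter()
    stage_dir = out_dir / "preprocess"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim_dir = out_dir / "simulate"
    _require("preprocess", sim_dir / "ar_0.h5", "simulate")
    pcfg = cfg.preprocess
    seed = cfg.stage_seed("preprocess")
    paired_pairs = []
    unpaired = None
    inputs = []
    i = 0
    while (sim_dir / f"ar_{i}.h5").exists():
        ar_path, or_path = sim_dir / f"ar_{i}.h5", sim_dir / f"or_{i}.h5"
        inputs += [ar_path, or_path]
        ar = preprocess_volume(read_volume(ar_path), pcfg.band, pcfg.apply_bandpass)
        orv = preprocess_volume(read_volume(or_path), pcfg.band, pcfg.apply_bandpass)
        paired_pairs.extend(
            build_paired(ar, orv, pcfg.patch_size, pcfg.stride).pairs
        )
        up = build_unpaired(ar, orv, pcfg.patch_size, pcfg.stride, seed=seed + i)
        if unpaired is None:
            unpaired = up
        else:
            unpaired.pool_a.extend(up.pool_a)
            unpaired.pool_o.extend(up.pool_o)
        i += 1
    from .preprocess import PairedDataset

    paired = PairedDataset(pairs=paired_pairs)
    paired_path = stage_dir / "paired.h5"
    unpaired_path = stage_dir / "unpaired.h5"
    save_dataset(paired, paired_path)
    save_dataset(unpaired, unpaired_path)
    params = {"preprocess": dataclasses.asdict(pcfg), "seed": seed,
              "n_pairs": len(paired), "_wall_seconds": time.perf_counter() - t0}
    _write_provenance(stage_dir, "preprocess", params, inputs,
                      [paired_path, unpaired_path])
    log.info("preprocess: %d pairs -> %s", len(paired), stage_dir)
    return [paired_path, unpaired_path]


def stage_train(cfg: RunConfig, out_dir: Path) -> Path:
    t0 = time.perf_counter()
    stage_dir = out_dir / "train"
    stage_dir.mkdir(parents=True, exist_ok=True)
    pre_dir = out_dir / "preprocess"
    name = "paired.h5" if cfg.mode == "cgan" else "unpaired.h5"
    data_path = _require("train", pre_dir / name, "preprocess")
    data = load_dataset(data_path)
    tcfg = dataclasses.replace(cfg.train, seed=cfg.stage_seed("train"))
    log_fn = lambda rec: log.info(
        "train[%s] epoch %d: adv %.4f l1/cyc %.4f d %.4f lr %.2e",
        cfg.mode, rec.epoch, rec.loss_g_adv, rec.loss_l1, rec.loss_d, rec.lr,
    )
    if cfg.mode == "cgan":
        model = train_cgan(data, cfg.generator, cfg.discriminator, tcfg, log_fn)
    else:
        dspec = dataclasses.replace(cfg.discriminator, in_channels=1)
        model = train_cyclegan(data, cfg.generator, dspec, tcfg, log_fn)
    ckpt = stage_dir / f"{cfg.mode}.npz"
    checkpoint(model, ckpt)
    (stage_dir / "history.csv").write_text(model.history.to_csv())
    params = {"mode": cfg.mode, "train": dataclasses.asdict(tcfg),
              "generator": dataclasses.asdict(cfg.generator),
              "discriminator": dataclasses.asdict(cfg.discriminator),
              "_wall_seconds": time.perf_counter() - t0}
    _write_provenance(stage_dir, "train", params, [data_path],
                      [ckpt, stage_dir / "history.csv"])
    log.info("train: checkpoint %s", ckpt)
    return ckpt


def stage_enhance(cfg: RunConfig, out_dir: Path) -> list[Path]:
    t0 = time.perf_counter()
    stage_dir = out_dir / "enhance"
    stage_dir.mkdir(parents=True, exist_ok=True)
    ckpt = _require("enhance", out_dir / "train" / f"{cfg.mode}.npz", "train")
    model = restore(ckpt)
    sim_dir = out_dir / "simulate"
    _require("enhance", sim_dir / "ar_0.h5", "simulate")
    outputs = []
    inputs = [ckpt]
    i = 0
    while (sim_dir / f"ar_{i}.h5").exists():
        ar_path = sim_dir / f"ar_{i}.h5"
        inputs.append(ar_path)
        ar = normalize_volume(read_volume(ar_path))
        enhanced = reconstruct.enhance_volume(
            ar, model, patch_size=cfg.preprocess.patch_size,
        )
        out_path = stage_dir / f"generated_{i}.h5"
        write_volume(enhanced, out_path, "hdf5")
        outputs.append(out_path)
        proj = max_amplitude_projection(enhanced)
        save_png(proj.amplitude, stage_dir / f"generated_{i}_map.png")
        save_png(depth_encoded_map(enhanced), stage_dir / f"generated_{i}_depthmap.png")
        i += 1
    params = {"mode": cfg.mode, "patch_size": cfg.preprocess.patch_size,
              "_wall_seconds": time.perf_counter() - t0}
    _write_provenance(stage_dir, "enhance", params, inputs, outputs)
    log.info("enhance: wrote %d volumes", len(outputs))
    return outputs


def stage_evaluate(cfg: RunConfig, out_dir: Path) -> Path:
    t0 = time.perf_counter()
    stage_dir = out_dir / "evaluate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim_dir = out_dir / "simulate"
    gen_path = _require("evaluate", out_dir / "enhance" / "generated_0.h5", "enhance")
    ar = normalize_volume(read_volume(_require("evaluate", sim_dir / "ar_0.h5", "simulate")))
    orv = normalize_volume(read_volume(sim_dir / "or_0.h5"))
    gen = read_volume(gen_path)
    ecfg = cfg.evaluate
    if ecfg.source == "map":
        images = {
            "AR": max_amplitude_projection(ar).amplitude,
            "GENERATED": max_amplitude_projection(gen).amplitude,
            "OR": max_amplitude_projection(orv).amplitude,
        }
        pitch = cfg.pitches.dx
    else:
        y = ecfg.bscan_index
        images = {"AR": ar.bscan(y), "GENERATED": gen.bscan(y), "OR": orv.bscan(y)}
        pitch = cfg.pitches.dx if ecfg.profile_axis == "lateral" else cfg.pitches.dz
    profile = None
    if ecfg.profile_index is not None:
        profile = (ecfg.profile_axis, ecfg.profile_index, pitch)
    report = compare_images(
        images, signal_roi=cfg.signal_roi(), noise_roi=cfg.noise_roi(),
        profile=profile, reference="OR",
    )
    csv_path = stage_dir / "metrics.csv"
    csv_path.write_text(report.to_csv())
    params = {"evaluate": dataclasses.asdict(ecfg),
              "_wall_seconds": time.perf_counter() - t0}
    _write_provenance(stage_dir, "evaluate", params, [gen_path], [csv_path])
    log.info("evaluate: metrics at %s", csv_path)
    return csv_path


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "enhance": stage_enhance,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in pipeline order; returns the run directory."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(json.dumps(config_to_dict(cfg), indent=2))
    for stage in stages:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    for stage in STAGES:
        if stage in stages:
            _STAGE_FN[stage](cfg, out_dir)
    return out_dir
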