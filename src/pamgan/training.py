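"""Adversarial training of the AR->OR translation networks.

Two regimes, matching how the training data can be prepared:

* paired (semi-supervised): one generator G and one conditioned patch
  discriminator optimize the conditional-adversarial objective
  ``E[log D(A,O)] + E[log(1 - D(A,G(A)))]`` plus a weighted L1 term
  ``||O - G(A)||_1`` that anchors the output to the paired target;
* unpaired (unsupervised): forward and backward generators (G: A->O,
  Gb: O->A) with one unconditioned discriminator per domain, adversarial
  terms in both directions and cycle-consistency L1 penalties
  ``||Gb(G(A)) - A||_1 + ||G(Gb(O)) - O||_1``.

Optimization is Adam (betas (0.5, 0.999), batch size 1 by default) with a
step learning-rate schedule: the initial rate 2e-4 is multiplied by the
decay factor 0.5 at each listed epoch.  Training is a pure function of
(datasets, specs, config): the same seed reproduces parameters bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .gan_models import (
    Discriminator,
    DiscriminatorSpec,
    Generator,
    GeneratorSpec,
    build_discriminator,
    build_generator,
)
from .preprocess import PairedDataset, UnpairedDataset


class TrainingError(RuntimeError):
    pass


class TrainingDivergence(TrainingError):
    """Loss became non-finite; carries the epoch where it happened."""

    def __init__(self, epoch: int, term: str) -> None:
        super().__init__(f"non-finite {term} loss at epoch {epoch}")
        self.epoch = epoch


class CheckpointError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (full-scale defaults).

    ``l1_weight`` multiplies the paired L1 (or the cycle term weight is
    ``cycle_weight``); ``gan_weight`` the adversarial term.  The default
    profile weights L1 heavily (adversarial-to-L1 ratio 0.01); the literal
    inverse profile is available by setting ``l1_weight=0.01,
    gan_weight=1``.
    """

    epochs: int = 200
    lr: float = 2e-4
    lr_decay_factor: float = 0.5
    lr_decay_epochs: tuple[int, ...] = (100, 150)
    l1_weight: float = 100.0
    cycle_weight: float = 10.0
    gan_weight: float = 1.0
    batch_size: int = 1
    seed: int = 0
    betas: tuple[float, float] = (0.5, 0.999)
    adv_loss: str = "bce"  # {"bce", "lsgan"}

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not (0 < self.lr_decay_factor <= 1):
            raise ValueError("lr_decay_factor must lie in (0, 1]")
        if min(self.l1_weight, self.cycle_weight, self.gan_weight) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        object.__setattr__(self, "lr_decay_epochs", tuple(self.lr_decay_epochs))
        object.__setattr__(self, "betas", tuple(self.betas))

    def lr_at(self, epoch: int) -> float:
        """Closed-form schedule: decay fires at each listed (0-based) epoch."""
        n = sum(1 for d in self.lr_decay_epochs if d <= epoch)
        return self.lr * self.lr_decay_factor**n


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    loss_g_adv: float
    loss_l1: float          # paired L1 or summed cycle loss
    loss_d: float
    wall_seconds: float
    loss_cycle_a: float | None = None
    loss_cycle_o: float | None = None


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def lrs(self) -> list[float]:
        return [r.lr for r in self.records]

    def to_csv(self) -> str:
        cols = ["epoch", "lr", "loss_g_adv", "loss_l1", "loss_d",
                "wall_seconds", "loss_cycle_a", "loss_cycle_o"]
        lines = [",".join(cols)]
        for r in self.records:
            lines.append(",".join(
                "" if getattr(r, c) is None else repr(getattr(r, c)) for c in cols
            ))
        return "\n".join(lines) + "\n"


@dataclass
class TrainedModel:
    """Trained networks plus the exact recipe that produced them."""

    kind: str  # {"cgan", "cyclegan"}
    generators: dict[str, Generator]
    discriminators: dict[str, Discriminator]
    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    config: TrainConfig
    history: TrainHistory
    final_epoch: int

    @property
    def generator(self) -> Generator:
        """The forward (A -> O) generator."""
        return self.generators["G"]


def _as_float_batches(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    return arr.astype(nn.DTYPE)


def _adv(cfg: TrainConfig):
    return nn.bce_loss if cfg.adv_loss == "bce" else nn.lsgan_loss


def _check_finite(value: float, epoch: int, term: str) -> None:
    if not np.isfinite(value):
        raise TrainingDivergence(epoch, term)


def train_cgan(
    data: PairedDataset,
    gen_spec: GeneratorSpec,
    disc_spec: DiscriminatorSpec,
    cfg: TrainConfig,
    log_fn=None,
) -> TrainedModel:
    """Paired conditional-adversarial training (one G, one conditioned D)."""
    if len(data) == 0:
        raise ValueError("empty paired dataset")
    if disc_spec.in_channels != 2:
        raise ValueError("conditioned discriminator needs in_channels=2")
    a_all = _as_float_batches(data.arrays()[0])[:, None]
    o_all = _as_float_batches(data.arrays()[1])[:, None]
    gen = build_generator(gen_spec, seed=cfg.seed)
    disc = build_discriminator(disc_spec, seed=cfg.seed + 1)
    opt_g = nn.Adam(gen.params(), lr=cfg.lr, betas=cfg.betas)
    opt_d = nn.Adam(disc.params(), lr=cfg.lr, betas=cfg.betas)
    adv = _adv(cfg)
    history = TrainHistory()
    n = len(a_all)
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        lr = cfg.lr_at(epoch)
        opt_g.lr = opt_d.lr = lr
        order = np.random.default_rng([cfg.seed, 0xE0, epoch]).permutation(n)
        sums = np.zeros(3)  # adv, l1, d
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            a, o = a_all[idx], o_all[idx]
            fake, tape_g = gen.forward(a)

            # --- discriminator step (fake detached)
            opt_d.zero_grad()
            p_real, tape_r = disc.forward(np.concatenate([a, o], axis=1))
            loss_r, g_r = adv(p_real, 1.0)
            disc.backward(tape_r, 0.5 * g_r)
            p_fake, tape_f = disc.forward(np.concatenate([a, fake], axis=1))
            loss_f, g_f = adv(p_fake, 0.0)
            disc.backward(tape_f, 0.5 * g_f)
            loss_d = 0.5 * (loss_r + loss_f)
            _check_finite(loss_d, epoch, "discriminator")
            opt_d.step()

            # --- generator step (adversarial through D + weighted L1)
            opt_g.zero_grad()
            opt_d.zero_grad()  # D accumulates grads below; discard them
            p_fake2, tape_f2 = disc.forward(np.concatenate([a, fake], axis=1))
            loss_adv, g_adv = adv(p_fake2, 1.0)
            d_concat = disc.backward(tape_f2, cfg.gan_weight * g_adv)
            loss_l1, g_l1 = nn.l1_loss(fake, o)
            _check_finite(loss_adv + loss_l1, epoch, "generator")
            d_fake = d_concat[:, 1:2] + cfg.l1_weight * g_l1
            gen.backward(tape_g, d_fake)
            opt_g.step()
            opt_d.zero_grad()

            sums += (loss_adv, loss_l1, loss_d)
            n_batches += 1
        rec = EpochRecord(
            epoch=epoch, lr=lr,
            loss_g_adv=sums[0] / n_batches, loss_l1=sums[1] / n_batches,
            loss_d=sums[2] / n_batches, wall_seconds=time.perf_counter() - t0,
        )
        history.records.append(rec)
        if log_fn:
            log_fn(rec)
    return TrainedModel(
        kind="cgan", generators={"G": gen}, discriminators={"D": disc},
        gen_spec=gen_spec, disc_spec=disc_spec, config=cfg, history=history,
        final_epoch=cfg.epochs - 1,
    )


def train_cyclegan(
    data: UnpairedDataset,
    gen_spec: GeneratorSpec,
    disc_spec: DiscriminatorSpec,
    cfg: TrainConfig,
    log_fn=None,
) -> TrainedModel:
    """Unpaired bidirectional training (G, Gb, one discriminator per domain)."""
    if not data.pool_a or not data.pool_o:
        raise ValueError("both unpaired pools must be non-empty")
    if disc_spec.in_channels != 1:
        disc_spec = dataclasses.replace(disc_spec, in_channels=1)
    a_pool = _as_float_batches(data.arrays()[0])[:, None]
    o_pool = _as_float_batches(data.arrays()[1])[:, None]
    g_fw = build_generator(gen_spec, seed=cfg.seed)          # A -> O
    g_bw = build_generator(gen_spec, seed=cfg.seed + 1)      # O -> A
    d_o = build_discriminator(disc_spec, seed=cfg.seed + 2)  # judges domain O
    d_a = build_discriminator(disc_spec, seed=cfg.seed + 3)  # judges domain A
    opt_g = nn.Adam(g_fw.params() + g_bw.params(), lr=cfg.lr, betas=cfg.betas)
    opt_d = nn.Adam(d_o.params() + d_a.params(), lr=cfg.lr, betas=cfg.betas)
    adv = _adv(cfg)
    history = TrainHistory()
    n = min(len(a_pool), len(o_pool))
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        lr = cfg.lr_at(epoch)
        opt_g.lr = opt_d.lr = lr
        rng = np.random.default_rng([cfg.seed, 0xCE, epoch])
        order_a = rng.permutation(len(a_pool))[:n]
        order_o = rng.permutation(len(o_pool))[:n]
        sums = np.zeros(4)  # adv, cyc_a, cyc_o, d
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            a = a_pool[order_a[start : start + cfg.batch_size]]
            o = o_pool[order_o[start : start + cfg.batch_size]]
            fake_o, t_fw1 = g_fw.forward(a)
            rec_a, t_bw1 = g_bw.forward(fake_o)
            fake_a, t_bw2 = g_bw.forward(o)
            rec_o, t_fw2 = g_fw.forward(fake_a)

            # --- discriminators (fakes detached)
            opt_d.zero_grad()
            loss_d = 0.0
            for d_net, real, fake in ((d_o, o, fake_o), (d_a, a, fake_a)):
                p_r, t_r = d_net.forward(real)
                l_r, g_r = adv(p_r, 1.0)
                d_net.backward(t_r, 0.5 * g_r)
                p_f, t_f = d_net.forward(fake)
                l_f, g_f = adv(p_f, 0.0)
                d_net.backward(t_f, 0.5 * g_f)
                loss_d += 0.5 * (l_r + l_f)
            _check_finite(loss_d, epoch, "discriminator")
            opt_d.step()

            # --- generators: adversarial both ways + cycle terms
            opt_g.zero_grad()
            opt_d.zero_grad()
            p_o, t_po = d_o.forward(fake_o)
            loss_adv_o, g_o = adv(p_o, 1.0)
            d_fake_o = d_o.backward(t_po, cfg.gan_weight * g_o)
            p_a, t_pa = d_a.forward(fake_a)
            loss_adv_a, g_a = adv(p_a, 1.0)
            d_fake_a = d_a.backward(t_pa, cfg.gan_weight * g_a)
            loss_cyc_a, g_rec_a = nn.l1_loss(rec_a, a)
            loss_cyc_o, g_rec_o = nn.l1_loss(rec_o, o)
            _check_finite(loss_adv_o + loss_adv_a + loss_cyc_a + loss_cyc_o,
                          epoch, "generator")
            # cycle gradients flow back through both generators
            d_fake_o = d_fake_o + g_bw.backward(t_bw1, cfg.cycle_weight * g_rec_a)
            d_fake_a = d_fake_a + g_fw.backward(t_fw2, cfg.cycle_weight * g_rec_o)
            g_fw.backward(t_fw1, d_fake_o)
            g_bw.backward(t_bw2, d_fake_a)
            opt_g.step()
            opt_d.zero_grad()

            sums += (loss_adv_o + loss_adv_a, loss_cyc_a, loss_cyc_o, loss_d)
            n_batches += 1
        rec = EpochRecord(
            epoch=epoch, lr=lr,
            loss_g_adv=sums[0] / n_batches,
            loss_l1=(sums[1] + sums[2]) / n_batches,
            loss_d=sums[3] / n_batches,
            wall_seconds=time.perf_counter() - t0,
            loss_cycle_a=sums[1] / n_batches, loss_cycle_o=sums[2] / n_batches,
        )
        history.records.append(rec)
        if log_fn:
            log_fn(rec)
    return TrainedModel(
        kind="cyclegan",
        generators={"G": g_fw, "G_back": g_bw},
        discriminators={"D_O": d_o, "D_A": d_a},
        gen_spec=gen_spec, disc_spec=disc_spec, config=cfg, history=history,
        final_epoch=cfg.epochs - 1,
    )


# ---------------------------------------------------------------------------
# checkpointing

def checkpoint(model: TrainedModel, path: str | Path) -> None:
    """Serialize networks + specs + history into one .npz file."""
    arrays: dict[str, np.ndarray] = {}
    for name, g in model.generators.items():
        for i, arr in enumerate(nn.get_state(g.net)):
            arrays[f"gen/{name}/{i}"] = arr
    for name, d in model.discriminators.items():
        for i, arr in enumerate(nn.get_state(d.net)):
            arrays[f"disc/{name}/{i}"] = arr
    meta = {
        "kind": model.kind,
        "gen_spec": dataclasses.asdict(model.gen_spec),
        "disc_spec": dataclasses.asdict(model.disc_spec),
        "config": dataclasses.asdict(model.config),
        "final_epoch": model.final_epoch,
        "gen_seeds": {k: g.seed for k, g in model.generators.items()},
        "disc_seeds": {k: d.seed for k, d in model.discriminators.items()},
        "history": [dataclasses.asdict(r) for r in model.history.records],
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def restore(path: str | Path, gen_spec: GeneratorSpec | None = None) -> TrainedModel:
    """Rebuild a trained model from a checkpoint file.

    Passing ``gen_spec`` asserts the expected topology; a mismatch with the
    stored spec raises :class:`CheckpointError`.
    """
    try:
        with np.load(Path(path)) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except (OSError, ValueError, KeyError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if "meta" not in arrays:
        raise CheckpointError(f"checkpoint {path} has no metadata block")
    try:
        meta = json.loads(arrays.pop("meta").tobytes().decode())
    except json.JSONDecodeError as exc:
        raise CheckpointError(f"corrupt metadata in {path}: {exc}") from exc
    stored_gspec = GeneratorSpec(**meta["gen_spec"])
    if gen_spec is not None and gen_spec != stored_gspec:
        raise CheckpointError(
            f"generator spec mismatch: checkpoint has {stored_gspec}, expected {gen_spec}"
        )
    dspec = DiscriminatorSpec(**meta["disc_spec"])
    cfg = TrainConfig(**meta["config"])
    generators = {}
    for name, seed in meta["gen_seeds"].items():
        g = build_generator(stored_gspec, seed=seed)
        state = _collect(arrays, f"gen/{name}/")
        try:
            nn.set_state(g.net, state)
        except ValueError as exc:
            raise CheckpointError(f"generator {name}: {exc}") from exc
        generators[name] = g
    discriminators = {}
    for name, seed in meta["disc_seeds"].items():
        d = build_discriminator(dspec, seed=seed)
        try:
            nn.set_state(d.net, _collect(arrays, f"disc/{name}/"))
        except ValueError as exc:
            raise CheckpointError(f"discriminator {name}: {exc}") from exc
        discriminators[name] = d
    history = TrainHistory(records=[EpochRecord(**r) for r in meta["history"]])
    return TrainedModel(
        kind=meta["kind"], generators=generators, discriminators=discriminators,
        gen_spec=stored_gspec, disc_spec=dspec, config=cfg, history=history,
        final_epoch=int(meta["final_epoch"]),
    )


def _collect(arrays: dict[str, np.ndarray], prefix: str) -> list[np.ndarray]:
    keys = sorted((k for k in arrays if k.startswith(prefix)),
                  key=lambda k: int(k.rsplit("/", 1)[1]))
    return [arrays[k] for k in keys]
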