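"""Adversarial training of the forecasting GAN.

The entry point is :class:`BloomForecastModel`, built from windowed samples
and a :class:`TrainConfig`; :meth:`BloomForecastModel.fit` runs alternating
discriminator/generator updates and returns a :class:`BloomForecastResults`
carrying the loss history, the best-validation checkpoint and prediction
helpers.

Losses follow the conditional-GAN convention: with D(y|h) the mean patch
probability of frame y given the 30-frame history h,

    L_D = ½·[BCE(D(real|h), 1) + BCE(D(fake|h), 0)]
    L_G = BCE(D(fake|h), 1) + λ_L1 · mean|fake − real|

Frames are normalised per channel from [0, 255] to [−1, 1] before the
network and denormalised (and snapped to the unified palette) on output.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor, no_grad
from .core import ColorScale, Frame, snap_to_palette
from .network import (Discriminator, DiscriminatorConfig, Generator,
                      GeneratorConfig, CamConvGruParams)
from .nn import Adam

__all__ = ["TrainConfig", "gan_losses", "BloomForecastModel",
           "BloomForecastResults", "normalize_frames", "denormalize"]

log = logging.getLogger(__name__)

_EPS = 1e-7  # probability clamp for BCE


def normalize_frames(frames) -> np.ndarray:
    """Stack frames into (T, 3, H, W) float32 scaled to [−1, 1]."""
    arr = np.stack([f.pixels if isinstance(f, Frame) else f for f in frames])
    return (arr.astype(np.float32) / 127.5 - 1.0).transpose(0, 3, 1, 2)


def denormalize(arr: np.ndarray) -> np.ndarray:
    """(3, H, W) in [−1, 1] -> (H, W, 3) uint8."""
    img = np.clip((arr + 1.0) * 127.5, 0, 255)
    return np.rint(img).astype(np.uint8).transpose(1, 2, 0)


def _bce(prob: Tensor, target: float) -> Tensor:
    p = prob.clip(_EPS, 1.0 - _EPS)
    if target == 1.0:
        return -(p.log().mean())
    if target == 0.0:
        return -((1.0 - p).log().mean())
    return -((target * p.log() + (1.0 - target) * (1.0 - p).log()).mean())


def gan_losses(real: Tensor, fake: Tensor, history: Tensor,
               discriminator: Discriminator, l1_weight: float = 100.0):
    """Generator and discriminator losses for one (history, real, fake) triple.

    Returns ``(g_loss, d_loss)`` tensors.  The discriminator loss treats the
    generated frame as a constant (detached); the generator loss backprops
    through the discriminator into the generator.
    """
    d_real, _ = discriminator(real, history)
    d_fake_det, _ = discriminator(fake.detach(), history)
    d_loss = 0.5 * (_bce(d_real, 1.0) + _bce(d_fake_det, 0.0))
    d_fake, _ = discriminator(fake, history)
    g_loss = _bce(d_fake, 1.0) + l1_weight * (fake - real).abs().mean()
    return g_loss, d_loss


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (Adam, learning rate 0.001)."""
    learning_rate: float = 0.001
    beta1: float = 0.5
    beta2: float = 0.999
    l1_weight: float = 100.0
    batch_size: int = 1
    epochs: int = 1
    iterations: int | None = None   # overrides epochs when set
    seed: int = 0
    device: str = "cpu"
    val_fraction: float = 0.1       # chronological tail held out

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.l1_weight < 0:
            raise ValueError("l1_weight must be >= 0")


@dataclass
class BloomForecastResults:
    """Fitted-model results: loss history, checkpoint, prediction."""

    generator: Generator
    discriminator: Discriminator
    config: TrainConfig
    history: pd.DataFrame          # per-iteration losses
    best_val_l1: float
    scale: ColorScale | None = None

    @property
    def losses(self) -> pd.DataFrame:
        return self.history

    def predict_array(self, history_frames: np.ndarray) -> np.ndarray:
        """(30, 3, H, W) normalised history -> (3, H, W) in [−1, 1]."""
        self.generator.eval()
        with no_grad():
            out = self.generator(Tensor(history_frames[None]))
        self.generator.train()
        return out.data[0]

    def predict(self, history: list[Frame]) -> Frame:
        """Forecast the frame one day after the last history frame.

        The generator output is denormalised to RGB and snapped to the
        unified palette so every pixel is a legal concentration grade.
        """
        x = normalize_frames(history)
        raw = denormalize(self.predict_array(x))
        last = history[-1]
        if self.scale is not None:
            lake = last.lake_mask
            pixels = last.pixels.copy() if lake.shape == raw.shape[:2] else raw.copy()
            pixels[lake] = snap_to_palette(raw[lake].astype(np.float64),
                                           self.scale.colors)
            if lake.shape == raw.shape[:2] and not lake.all():
                pixels[~lake] = last.pixels[~lake]
        else:
            pixels = raw
        h, w = pixels.shape[:2]
        return Frame(last.date + _dt.timedelta(days=1), pixels,
                     np.zeros((h, w), bool), last.lake_mask.copy())

    def summary(self) -> str:
        h = self.history
        lines = [
            "Adversarial forecast model",
            "==========================",
            f"generator parameters:     {self.generator.num_parameters():,}",
            f"discriminator parameters: {self.discriminator.num_parameters():,}",
            f"iterations:               {len(h)}",
            f"final generator loss:     {h['g_loss'].iloc[-1]:.4f}",
            f"final discriminator loss: {h['d_loss'].iloc[-1]:.4f}",
            f"first/final mean |err|:   {h['l1'].iloc[0]:.4f} / {h['l1'].iloc[-1]:.4f}",
            f"best validation |err|:    {self.best_val_l1:.4f}",
        ]
        return "\n".join(lines)

    def plot_losses(self, ax=None):
        """Plot generator/discriminator losses and training L1 per iteration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        h = self.history
        ax.plot(h["iteration"], h["g_loss"], label="generator loss")
        ax.plot(h["iteration"], h["d_loss"], label="discriminator loss")
        ax2 = ax.twinx()
        ax2.plot(h["iteration"], h["l1"], color="k", alpha=0.5,
                 label="training L1")
        ax.set_xlabel("iteration")
        ax.set_ylabel("adversarial loss")
        ax2.set_ylabel("mean |fake − real|")
        ax.legend(loc="upper right")
        return ax

    def save(self, path) -> None:
        """Persist weights + configs + loss history (.npz plus .json sidecar)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = {"G:" + k: v for k, v in self.generator.state_dict().items()}
        state.update({"D:" + k: v for k, v in self.discriminator.state_dict().items()})
        np.savez_compressed(path, **state)
        meta = {
            "train_config": asdict(self.config),
            "generator_config": _gen_cfg_dict(self.generator.config),
            "discriminator_config": asdict(self.discriminator.config),
            "best_val_l1": self.best_val_l1,
            "scale": (self.scale.to_dataframe().to_dict("records")
                      if self.scale is not None else None),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
        self.history.to_csv(Path(str(path) + ".losses.csv"), index=False)

    @classmethod
    def load(cls, path) -> "BloomForecastResults":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        gcfg = _gen_cfg_from_dict(meta["generator_config"])
        dcfg = DiscriminatorConfig(**{**meta["discriminator_config"],
                                      "conv_channels": tuple(
                                          meta["discriminator_config"]["conv_channels"])})
        tcfg = TrainConfig(**meta["train_config"])
        gen = Generator(gcfg, seed=tcfg.seed)
        disc = Discriminator(dcfg, seed=tcfg.seed)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            state = dict(z)
        gen.load_state_dict({k[2:]: v for k, v in state.items() if k.startswith("G:")})
        disc.load_state_dict({k[2:]: v for k, v in state.items() if k.startswith("D:")})
        scale = (ColorScale.from_dataframe(pd.DataFrame(meta["scale"]))
                 if meta.get("scale") else None)
        losses_path = Path(str(path) + ".losses.csv")
        history = pd.read_csv(losses_path) if losses_path.exists() else pd.DataFrame()
        return cls(gen, disc, tcfg, history, meta["best_val_l1"], scale)


def _gen_cfg_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["gru"] = asdict(cfg.gru)
    return d


def _gen_cfg_from_dict(d: dict) -> GeneratorConfig:
    gru = CamConvGruParams(**d["gru"])
    rest = {k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d.items() if k != "gru"}
    return GeneratorConfig(gru=gru, **rest)


class BloomForecastModel:
    """Conditional-GAN forecaster over windowed daily frame samples.

    Parameters
    ----------
    samples : sequence of WindowedSample
        Thirty-frame histories with their next-day targets.
    config : TrainConfig
    generator_config, discriminator_config : architecture hyperparameters.
    scale : ColorScale, optional
        Unified palette used to snap predictions to legal grades.
    """

    def __init__(self, samples, config: TrainConfig = TrainConfig(),
                 generator_config: GeneratorConfig | None = None,
                 discriminator_config: DiscriminatorConfig | None = None,
                 scale: ColorScale | None = None):
        samples = list(samples)
        if not samples:
            raise ValueError("at least one training sample is required")
        self.samples = samples
        self.config = config
        self.scale = scale
        input_len = len(samples[0].inputs)
        self.generator_config = generator_config or GeneratorConfig(input_len=input_len)
        self.discriminator_config = (discriminator_config or
                                     DiscriminatorConfig(label_frames=input_len))
        self.generator = Generator(self.generator_config, seed=config.seed)
        self.discriminator = Discriminator(self.discriminator_config, seed=config.seed)

    # -- data plumbing -------------------------------------------------------

    def _tensorize(self, sample):
        hist = normalize_frames(sample.inputs)[None]          # (1, T, 3, H, W)
        target = normalize_frames([sample.target])            # (1, 3, H, W)
        return Tensor(hist), Tensor(target)

    def _split(self):
        n = len(self.samples)
        n_val = int(round(n * self.config.val_fraction))
        n_val = min(n_val, n - 1)
        return self.samples[:n - n_val], self.samples[n - n_val:]

    def _validation_l1(self, val_samples) -> float:
        if not val_samples:
            return float("nan")
        self.generator.eval()
        errs = []
        with no_grad():
            for s in val_samples:
                hist, target = self._tensorize(s)
                fake = self.generator(hist)
                errs.append(float(np.abs(fake.data - target.data).mean()))
        self.generator.train()
        return float(np.mean(errs))

    # -- fitting -------------------------------------------------------------

    def fit(self, log_every: int = 50) -> BloomForecastResults:
        """Alternating D/G optimisation; returns results with the
        best-validation-L1 generator weights restored."""
        cfg = self.config
        train_samples, val_samples = self._split()
        opt_g = Adam(self.generator.parameters(), lr=cfg.learning_rate,
                     betas=(cfg.beta1, cfg.beta2))
        opt_d = Adam(self.discriminator.parameters(), lr=cfg.learning_rate,
                     betas=(cfg.beta1, cfg.beta2))
        order_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))

        if cfg.iterations is not None:
            total = cfg.iterations
        else:
            total = cfg.epochs * len(train_samples)

        rows = []
        best_val = float("inf")
        best_state = None
        it = 0
        while it < total:
            order = order_rng.permutation(len(train_samples))
            for idx in order:
                if it >= total:
                    break
                hist, target = self._tensorize(train_samples[idx])

                fake = self.generator(hist)

                # discriminator step (generator output treated as constant)
                d_real, _ = self.discriminator(target, hist)
                d_fake_det, _ = self.discriminator(fake.detach(), hist)
                d_loss = 0.5 * (_bce(d_real, 1.0) + _bce(d_fake_det, 0.0))
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()

                # generator step against the updated discriminator
                d_fake, _ = self.discriminator(fake, hist)
                g_loss = _bce(d_fake, 1.0) + cfg.l1_weight * (fake - target).abs().mean()
                if not (np.isfinite(g_loss.item()) and np.isfinite(d_loss.item())):
                    raise FloatingPointError(
                        f"non-finite loss at iteration {it}: "
                        f"G={g_loss.item()} D={d_loss.item()}")
                opt_g.zero_grad()
                self.discriminator.zero_grad()
                g_loss.backward()
                opt_g.step()

                l1 = float(np.abs(fake.data - target.data).mean())
                rows.append({"iteration": it + 1, "g_loss": g_loss.item(),
                             "d_loss": d_loss.item(), "l1": l1})
                it += 1
                if log_every and it % log_every == 0:
                    log.info("iter %d/%d  G %.4f  D %.4f  L1 %.4f",
                             it, total, g_loss.item(), d_loss.item(), l1)
            # end of pass: validate and checkpoint the best generator
            val_l1 = self._validation_l1(val_samples)
            if np.isnan(val_l1):
                val_l1 = rows[-1]["l1"]
            if val_l1 < best_val:
                best_val = val_l1
                best_state = self.generator.state_dict()

        if best_state is not None:
            final_val = self._validation_l1(val_samples)
            if np.isnan(final_val):
                final_val = rows[-1]["l1"]
            if final_val < best_val:
                best_val = final_val
            else:
                self.generator.load_state_dict(best_state)

        history = pd.DataFrame(rows)
        return BloomForecastResults(self.generator, self.discriminator, cfg,
                                    history, best_val, self.scale)
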