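"""Decoder (generator) g: latent space -> image space.

The decoder inverts the frozen embedding: latent vectors of training images
are computed once with the finalized embedding CNN, and the decoder is
trained by mean-squared-error reconstruction of the corresponding
standardized images. Its outputs therefore live in the standardized
intensity domain and tend toward the mean of all images embedding nearby —
they look blurry by design, which is what makes path lengths through decoded
image space smooth.

The latent vector enters as a small spatial map (sqrt(n) x sqrt(n), one
channel) with no dense layer in front, which limits the decoder's capacity
to memorize individuals. Two stride-1 convolutions are followed by stride-2
transposed convolutions up to the working resolution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .datamodel import Dataset
from .embedding import EmbeddingModel, _standardize_batch
from .nn import Adam, Conv2D, ConvTranspose2D, ReLU, Reshape, Sequential

__all__ = ["DecoderConfig", "DecoderModel", "train_decoder", "decode"]


@dataclass
class DecoderConfig:
    learning_rate: float = 1e-4
    max_steps: int = 10000
    batch_size: int = 16
    holdout_fraction: float = 0.1
    eval_every: int = 250
    seed: int = 0
    base_channels: int = 128
    min_channels: int = 32
    upsample_kernel: int = 2  # 2 = non-overlapping (fast); 4 = overlapping
    final_conv: bool = False  # optional 3x3 smoothing conv at full resolution

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class DecoderModel:
    """Convolutional generator from n-vectors to standardized images."""

    def __init__(self, n: int, image_shape, config: Optional[DecoderConfig] = None,
                 rng: Optional[np.random.Generator] = None):
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise ValueError(f"latent dimension {n} must be a perfect square to form the entry map")
        h, w, c = image_shape
        if h != w or h % side or (h // side) & (h // side - 1):
            raise ValueError(f"image shape {image_shape} must be square with side = {side} * 2^k")
        self.n = n
        self.image_shape = tuple(image_shape)
        self.config = config or DecoderConfig()
        rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        n_up = int(np.log2(h // side))
        ch = self.config.base_channels
        layers = [
            Reshape((1, side, side)),
            Conv2D(1, ch, k=3, stride=1, pad=1, rng=rng),
            ReLU(),
            Conv2D(ch, ch, k=3, stride=1, pad=1, rng=rng),
            ReLU(),
        ]
        cin = ch
        ku = self.config.upsample_kernel
        kpad = 1 if ku == 4 else 0
        use_final = self.config.final_conv
        for i in range(n_up):
            last = i == n_up - 1
            if last and not use_final:
                cout = c  # blockwise upsample straight to image channels
            else:
                cout = max(self.config.min_channels, ch // (2 ** (i + 1)))
            layers.append(ConvTranspose2D(cin, cout, k=ku, stride=2, pad=kpad, rng=rng))
            if not (last and not use_final):
                layers.append(ReLU())
            cin = cout
        if use_final:
            layers.append(Conv2D(cin, c, k=3, stride=1, pad=1, rng=rng))
        self.net = Sequential(layers)
        self.training_log: dict = {"step_loss": [], "holdout_mse": [], "best_step": None}

    # -- inference -------------------------------------------------------------
    def decode(self, z: np.ndarray) -> np.ndarray:
        """Latent (n,) or (N, n) -> standardized-domain image(s) (…, H, W, C)."""
        z = np.asarray(z, dtype=np.float32)
        single = z.ndim == 1
        if single:
            z = z[None, :]
        if z.shape[1] != self.n:
            raise ValueError(f"expected latent dimension {self.n}, got {z.shape[1]}")
        if not np.isfinite(z).all():
            raise FloatingPointError("non-finite latent vector")
        out = self.net.forward(z)  # (N, C, H, W)
        out = out.transpose(0, 2, 3, 1)
        return out[0] if single else out

    def decode_flat(self, z: np.ndarray) -> np.ndarray:
        """(N, n) -> flattened images (N, H*W*C); caches for :meth:`vjp`."""
        out = self.net.forward(np.asarray(z, dtype=np.float32))
        return out.reshape(out.shape[0], -1)

    def vjp(self, dflat: np.ndarray) -> np.ndarray:
        """Backprop image-space gradients (N, H*W*C) of the last
        :meth:`decode_flat` call to latent gradients (N, n).

        Parameter gradients are skipped — path optimization only moves
        latent vertices, never decoder weights."""
        h, w, c = self.image_shape
        dy = dflat.reshape(dflat.shape[0], c, h, w).astype(np.float32)
        return self.net.backward(dy, param_grads=False)

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        arrays = {name: layer.params[key] for name, layer, key in self.net.named_params()}
        meta = {
            "n": self.n,
            "image_shape": list(self.image_shape),
            "config": asdict(self.config),
            "training_log": self.training_log,
        }
        np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DecoderModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(meta["n"], tuple(meta["image_shape"]), DecoderConfig(**meta["config"]))
            for name, layer, key in model.net.named_params():
                layer.params[key][...] = data[name]
        model.training_log = meta["training_log"]
        return model


def decode(model: DecoderModel, z: np.ndarray) -> np.ndarray:
    return model.decode(z)


def train_decoder(embedding_model: EmbeddingModel, train: Dataset, config: Optional[DecoderConfig] = None,
                  init_model: Optional[DecoderModel] = None) -> DecoderModel:
    """Fit the decoder by MSE reconstruction of the training images.

    The embedding CNN is frozen; each training image's latent point is
    computed once up front. A small fraction of images is held out and the
    returned model carries the parameters with the best held-out MSE.
    ``init_model`` warm-starts from an existing decoder of the same
    architecture (e.g. to continue training a selection probe).
    """
    config = config or DecoderConfig()
    rng = np.random.default_rng(config.seed)
    x_std = _standardize_batch(train.images_array())  # (N, U, H, W, C)
    n_seq, u = x_std.shape[:2]
    flat = x_std.reshape((n_seq * u,) + x_std.shape[2:])
    z_all = embedding_model.embed_images(flat)
    targets = np.ascontiguousarray(flat.transpose(0, 3, 1, 2), dtype=np.float32)

    n_img = z_all.shape[0]
    order = rng.permutation(n_img)
    n_hold = max(1, int(round(config.holdout_fraction * n_img)))
    hold_idx, fit_idx = order[:n_hold], order[n_hold:]

    model = DecoderModel(embedding_model.config.n, train.image_shape, config, rng=rng)
    if init_model is not None:
        for (name, layer, key), (_, src_layer, src_key) in zip(
            model.net.named_params(), init_model.net.named_params()
        ):
            layer.params[key][...] = src_layer.params[src_key]
    opt = Adam(list(model.net.named_params()), lr=config.learning_rate)
    log = model.training_log
    best = {"mse": np.inf, "snap": None, "step": None}

    def holdout_mse() -> float:
        total = 0.0
        for start in range(0, len(hold_idx), 256):
            idx = hold_idx[start : start + 256]
            out = model.net.forward(z_all[idx])
            total += float(((out - targets[idx]) ** 2).sum())
        return total / (len(hold_idx) * targets[0].size)

    step = 0
    while step < config.max_steps:
        for start in range(0, len(fit_idx), config.batch_size):
            idx = fit_idx[start : start + config.batch_size]
            out = model.net.forward(z_all[idx])
            diff = out - targets[idx]
            loss = float((diff**2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite reconstruction loss at step {step}")
            log["step_loss"].append(loss)
            model.net.backward((2.0 / diff.size) * diff)
            opt.step()
            step += 1
            if step % config.eval_every == 0 or step >= config.max_steps:
                mse = holdout_mse()
                log["holdout_mse"].append([step, mse])
                if mse < best["mse"]:
                    best.update(
                        mse=mse,
                        snap={name: layer.params[key].copy() for name, layer, key in model.net.named_params()},
                        step=step,
                    )
            if step >= config.max_steps:
                break
        fit_idx = rng.permutation(fit_idx)

    if best["snap"] is not None:
        for name, layer, key in model.net.named_params():
            layer.params[key][...] = best["snap"][name]
        log["best_step"] = best["step"]
    return model
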