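"""The four-stage convolutional architecture.

The model reads a multi-channel genome image and produces a prediction in
four stages:

1. **Encoder** — strided 3x3 convolution blocks compress the image into a
   latent vector ``L`` (default length 128).
2. **Decoder** — transposed convolutions reconstruct an image of the input
   shape from ``L``.  The reconstruction is *not* penalized by any loss;
   the network is free to redraw the genome in whatever form helps the
   prediction.
3. **Extractor** — convolution + max-pooling blocks mine the reconstructed
   image for predictive features.
4. **Head** — the extracted features are flattened, concatenated with ``L``
   (so the head sees the genome both before and after reconstruction), and
   passed through dense layers to a softmax (classification) or linear
   (regression) output.

Exact layer counts and kernel sizes are configurable; the architectural
contract is the stage structure and the twice-used latent vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from omicsimage.autodiff import (
    DTYPE,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    LeakyReLU,
    Linear,
    MaxPool2d,
    Param,
    Sequential,
    conv_out_size,
    softmax,
)

HEADS = ("binary", "multiclass", "regression")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_widths`` are the channel counts of the strided encoder blocks
    (mirrored by the decoder); ``extractor_widths`` the channel counts of
    the conv+pool extractor blocks.  Defaults are sized for desk-scale
    images (a few thousand genes) and train in minutes on one CPU.
    """

    image_height: int
    image_width: int
    image_channels: int
    latent_dim: int = 128
    head: str = "binary"
    n_classes: int = 2
    encoder_widths: tuple[int, ...] = (8, 16, 32, 64)
    extractor_widths: tuple[int, ...] = (8, 16, 32)
    head_hidden: int = 64
    batchnorm: bool = True
    leaky_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.head == "multiclass" and self.n_classes < 2:
            raise ValueError("multiclass head needs n_classes >= 2")
        if min(self.image_height, self.image_width, self.image_channels) < 1:
            raise ValueError("image dimensions must be positive")

    @property
    def out_dim(self) -> int:
        if self.head == "binary":
            return 2
        if self.head == "multiclass":
            return self.n_classes
        return 1


@dataclass
class ForwardOutput:
    """Prediction, latent vector and (unpenalized) reconstruction."""

    prediction: np.ndarray  # probabilities (B, k) or scalars (B,)
    logits: np.ndarray
    latent: np.ndarray
    reconstruction: np.ndarray


class GenomeNet:
    """Encoder -> latent -> decoder -> extractor -> dense head."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.image_channels
        h, w = config.image_height, config.image_width

        # Encoder: strided conv blocks; record spatial sizes for the decoder.
        sizes = [(h, w)]
        enc_layers: list[Layer] = []
        widths = list(config.encoder_widths)
        prev = c
        for width in widths:
            enc_layers.append(Conv2d(prev, width, k=3, stride=2, pad=1, rng=rng))
            if config.batchnorm:
                enc_layers.append(BatchNorm2d(width))
            enc_layers.append(LeakyReLU(config.leaky_alpha))
            h2 = conv_out_size(sizes[-1][0], 3, 2, 1)
            w2 = conv_out_size(sizes[-1][1], 3, 2, 1)
            if h2 < 1 or w2 < 1:
                raise ValueError("image too small for the encoder block stack")
            sizes.append((h2, w2))
            prev = width
        self.encoder = Sequential(enc_layers)
        self._enc_sizes = sizes
        self._enc_flat = widths[-1] * sizes[-1][0] * sizes[-1][1]
        self.to_latent = Linear(self._enc_flat, config.latent_dim, rng=rng)

        # Decoder: dense back to the encoder's final feature map, then
        # mirrored transposed convs whose output sizes invert the encoder.
        self.from_latent = Linear(config.latent_dim, self._enc_flat, rng=rng)
        self.dec_act = LeakyReLU(config.leaky_alpha)
        dec_layers: list[Layer] = []
        chain = [c] + widths  # channel counts at sizes[0..len]
        for i in range(len(widths), 0, -1):
            convt = ConvTranspose2d(chain[i], chain[i - 1], k=3, stride=2, pad=1, rng=rng)
            convt.out_hw = sizes[i - 1]
            dec_layers.append(convt)
            if i > 1:  # hidden decoder blocks get norm + nonlinearity
                if config.batchnorm:
                    dec_layers.append(BatchNorm2d(chain[i - 1]))
                dec_layers.append(LeakyReLU(config.leaky_alpha))
        self.decoder = Sequential(dec_layers)

        # Extractor: conv + max-pool blocks on the reconstruction.
        ext_layers: list[Layer] = []
        prev = c
        eh, ew = h, w
        for width in config.extractor_widths:
            ext_layers.append(Conv2d(prev, width, k=3, stride=1, pad=1, rng=rng))
            if config.batchnorm:
                ext_layers.append(BatchNorm2d(width))
            ext_layers.append(LeakyReLU(config.leaky_alpha))
            ext_layers.append(MaxPool2d())
            eh = max(eh // 2, 1)
            ew = max(ew // 2, 1)
            prev = width
        self.extractor = Sequential(ext_layers)
        self._ext_flat = prev * eh * ew

        self.head = Sequential(
            [
                Linear(self._ext_flat + config.latent_dim, config.head_hidden, rng=rng),
                LeakyReLU(config.leaky_alpha),
                Linear(config.head_hidden, config.out_dim, rng=rng),
            ]
        )

        self._cache: dict | None = None

    # -- parameters -------------------------------------------------------

    def parameters(self) -> list[Param]:
        return (
            self.encoder.params()
            + self.to_latent.params()
            + self.from_latent.params()
            + self.decoder.params()
            + self.extractor.params()
            + self.head.params()
        )

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    # -- forward / backward ----------------------------------------------

    def forward(
        self, x: np.ndarray, train: bool = False, zero_latent_at_head: bool = False
    ) -> ForwardOutput:
        cfg = self.config
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.shape[1:] != (cfg.image_channels, cfg.image_height, cfg.image_width):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match config "
                f"({cfg.image_channels}, {cfg.image_height}, {cfg.image_width})"
            )
        b = x.shape[0]
        enc = self.encoder.forward(x, train=train)
        latent = self.to_latent.forward(enc.reshape(b, -1), train=train)
        dec_in = self.dec_act.forward(self.from_latent.forward(latent, train=train), train=train)
        c_last = cfg.encoder_widths[-1]
        h_last, w_last = self._enc_sizes[-1]
        recon = self.decoder.forward(dec_in.reshape(b, c_last, h_last, w_last), train=train)
        feat = self.extractor.forward(recon, train=train)
        latent_for_head = np.zeros_like(latent) if zero_latent_at_head else latent
        head_in = np.concatenate([feat.reshape(b, -1), latent_for_head], axis=1)
        logits = self.head.forward(head_in, train=train)
        if cfg.head == "regression":
            prediction = logits[:, 0].astype(np.float64)
        else:
            prediction = softmax(logits.astype(np.float64))
        self._cache = {
            "b": b,
            "enc_shape": enc.shape,
            "feat_shape": feat.shape,
            "zero_latent": zero_latent_at_head,
        }
        return ForwardOutput(prediction, logits, latent, recon)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate from the head logits all the way to the input image.

        Accumulates parameter gradients and returns dLoss/dInput.
        """
        if self._cache is None:
            raise RuntimeError("forward must be called before backward")
        cache = self._cache
        b = cache["b"]
        dhead_in = self.head.backward(dlogits.astype(DTYPE))
        dfeat = dhead_in[:, : self._ext_flat].reshape(cache["feat_shape"])
        dlat_head = dhead_in[:, self._ext_flat :]
        if cache["zero_latent"]:
            dlat_head = np.zeros_like(dlat_head)
        drecon = self.extractor.backward(dfeat)
        ddec_in = self.decoder.backward(drecon).reshape(b, -1)
        dlat_dec = self.from_latent.backward(self.dec_act.backward(ddec_in))
        dlat = dlat_head + dlat_dec
        denc = self.to_latent.backward(dlat).reshape(cache["enc_shape"])
        return self.encoder.backward(denc)

    def output_and_input_grad(
        self, x: np.ndarray, target: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Scalar model output F per sample and its gradient dF/dx.

        For classification F is the logit of each sample's ``target`` class;
        for regression F is the predicted value.  Runs in evaluation mode;
        parameter gradients accumulated as a side effect are cleared.
        """
        out = self.forward(x, train=False)
        b = x.shape[0]
        dlogits = np.zeros_like(out.logits)
        if self.config.head == "regression":
            f = out.logits[:, 0].astype(np.float64)
            dlogits[:, 0] = 1.0
        else:
            if target is None:
                raise ValueError("classification output requires a target class index")
            target = np.asarray(target, dtype=int)
            f = out.logits[np.arange(b), target].astype(np.float64)
            dlogits[np.arange(b), target] = 1.0
        dx = self.backward(dlogits)
        self.zero_grad()
        return f, dx.astype(np.float64)

    # -- persistence ------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for layer in self._bn_layers():
            arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def _bn_layers(self) -> list[BatchNorm2d]:
        out = []
        for seq in (self.encoder, self.decoder, self.extractor):
            out.extend(l for l in seq.layers if isinstance(l, BatchNorm2d))
        return out

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        current = self.state_arrays()
        if len(current) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(current, state):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


def build_model(config: ModelConfig, seed: int = 0) -> GenomeNet:
    """Construct a :class:`GenomeNet` with seed-reproducible initial weights."""
    return GenomeNet(config, seed=seed)


def save_checkpoint(
    model: GenomeNet, path: str | Path, layout_hash: str | None = None
) -> None:
    path = Path(path)
    state = model.get_state()
    np.savez_compressed(path, **{f"arr_{i}": a for i, a in enumerate(state)})
    meta = {"config": asdict(model.config), "layout_hash": layout_hash, "n_arrays": len(state)}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(
    path: str | Path, expect_layout_hash: str | None = None
) -> tuple[GenomeNet, str | None]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    if expect_layout_hash is not None and meta["layout_hash"] != expect_layout_hash:
        raise ValueError(
            f"checkpoint was trained on layout {meta['layout_hash']}, "
            f"got {expect_layout_hash}: refusing to attribute across layouts"
        )
    cfg_dict = dict(meta["config"])
    cfg_dict["encoder_widths"] = tuple(cfg_dict["encoder_widths"])
    cfg_dict["extractor_widths"] = tuple(cfg_dict["extractor_widths"])
    config = ModelConfig(**cfg_dict)
    model = GenomeNet(config, seed=0)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as d:
        state = [d[f"arr_{i}"] for i in range(meta["n_arrays"])]
    model.set_state(state)
    return model, meta["layout_hash"]
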