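"""The affinity-regression architectures.

Four families map a voxel grid (or an ordered grid sequence) to one scalar
prediction on the pK scale, with a linear (unsquashed) regression head:

``cnn``
    A plain 3-D CNN: stacked conv + ReLU + average-pool stages, global
    average pooling, and a fully connected head.
``dense_cnn``
    The same trunk organised as dense blocks: each layer inside a block
    receives the concatenation of the block input and all previous layer
    outputs (so a block grows the channel count by ``layers * growth``),
    with 1x1x1 transition convolutions (channel compression) followed by a
    spatial downsample between blocks.
``lrcn``
    A long-term recurrent convolutional network: a shared CNN encoder embeds
    every frame, an LSTM consumes the embeddings step by step, and the head
    reads the final hidden state.
``convlstm``
    Stacked convolutional LSTM layers unrolled over the frames; the final
    hidden state is pooled spatially and passed through the head.

Exact layer counts and widths are configuration, not code; the defaults
below are desk-scale and documented in ``ModelConfig``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn
from .errors import GridbindError
from .featurize import N_CHANNELS
from .nn import Tensor
from .nn import autodiff as ad

FAMILIES = ("cnn", "dense_cnn", "lrcn", "convlstm")


def dense_block_out_channels(in_channels: int, layers: int, growth: int) -> int:
    """Channels leaving a dense block: ``in_channels + layers * growth``."""
    return in_channels + layers * growth


def transition_out_channels(in_channels: int, compression: float) -> int:
    """Channels leaving a transition: ``floor(in_channels * compression)``."""
    return int(np.floor(in_channels * compression))


@dataclass
class ModelConfig:
    """Hyperparameters for every architecture family.

    Only the fields relevant to ``family`` are used.  ``conv_channels`` /
    ``conv_strides`` define the plain-CNN trunk (also the LRCN encoder);
    the dense-block spec applies to ``dense_cnn``; the recurrent spec to
    ``lrcn`` (``lstm_hidden``) and ``convlstm`` (``hidden_channels``,
    ``kernel_edge``, ``n_recurrent_layers``).
    """

    family: str = "cnn"
    in_channels: int = N_CHANNELS
    grid_edge: int = 25
    # plain CNN trunk (and LRCN per-frame encoder)
    conv_channels: tuple = (16, 32)
    conv_strides: tuple = (2, 2)
    conv_kernels: tuple = (3, 3)
    input_pool: int = 2
    # dense-block spec
    n_blocks: int = 3
    layers_per_block: int = 4
    growth: int = 16
    stem_channels: int = 32
    compression: float = 0.5
    # recurrent spec
    hidden_channels: int = 16
    kernel_edge: int = 3
    n_recurrent_layers: int = 2
    lstm_hidden: int = 64
    # head
    head_widths: tuple = (64,)
    dropout: float = 0.0
    temporal_readout: str = "last"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise GridbindError(f"unknown model family {self.family!r}; choose from {FAMILIES}")
        self.conv_channels = tuple(self.conv_channels)
        self.conv_strides = tuple(self.conv_strides)
        self.conv_kernels = tuple(self.conv_kernels)
        self.head_widths = tuple(self.head_widths)
        widths = self.conv_channels + self.head_widths + (
            self.hidden_channels, self.lstm_hidden, self.growth, self.stem_channels)
        if any(w < 1 for w in widths):
            raise GridbindError("all layer widths must be >= 1")
        if len(self.conv_strides) != len(self.conv_channels) or \
                len(self.conv_kernels) != len(self.conv_channels):
            raise GridbindError("conv_strides/conv_kernels must match conv_channels in length")
        if self.kernel_edge % 2 == 0 or any(k % 2 == 0 for k in self.conv_kernels):
            raise GridbindError("convolution kernel edges must be odd")
        if self.input_pool < 1:
            raise GridbindError("input_pool must be >= 1")
        if self.n_blocks < 0 or self.layers_per_block < 0:
            raise GridbindError("dense-block counts must be >= 0")
        if not 0.0 < self.compression <= 1.0:
            raise GridbindError("compression must be in (0, 1]")
        if self.temporal_readout not in ("last", "mean"):
            raise GridbindError("temporal_readout must be 'last' or 'mean'")

    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


class _Head(nn.Module):
    """Fully connected regression head ending in one linear unit."""

    def __init__(self, in_features: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        dtype = cfg.np_dtype()
        self.layers = []
        cur = in_features
        for w in cfg.head_widths:
            self.layers.append(nn.Linear(cur, w, rng, dtype=dtype))
            cur = w
        self.dropout = nn.Dropout(cfg.dropout, rng) if cfg.dropout > 0 else None
        self.out = nn.Linear(cur, 1, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        for lin in self.layers:
            x = nn.relu(lin(x))
            if self.dropout is not None:
                x = self.dropout(x)
        return self.out(x).reshape(-1)


class _ConvTrunk(nn.Module):
    """Optional input pooling, conv + ReLU (+ stride) stages, global mean pool.

    ``input_pool`` coarsens the grid (e.g. 1 Å -> 2 Å voxels) before the
    first convolution; feature sums are preserved up to the pooling factor
    and the effective receptive field in Å grows accordingly.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        dtype = cfg.np_dtype()
        self.input_pool = cfg.input_pool
        self.convs = []
        cur = cfg.in_channels
        for ch, stride, k in zip(cfg.conv_channels, cfg.conv_strides, cfg.conv_kernels):
            self.convs.append(nn.Conv3d(cur, ch, k, rng, stride=stride, padding=k // 2,
                                        dtype=dtype))
            cur = ch
        self.out_features = cur

    def forward(self, x: Tensor) -> Tensor:
        if self.input_pool > 1:
            x = nn.avg_pool3d(x, self.input_pool)
        for conv in self.convs:
            x = nn.relu(conv(x))
        return nn.global_mean_pool(x)


class _AffinityModel(nn.Module):
    """Shared scaffolding: config storage and the numpy-in/numpy-out predict."""

    expects_sequence = False

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.config = cfg
        # affine output transform (set by the trainer from the training-label
        # distribution so the network regresses a standardized target)
        self.output_mean = 0.0
        self.output_scale = 1.0

    def set_output_transform(self, mean: float, scale: float) -> None:
        if scale <= 0:
            raise GridbindError("output scale must be positive")
        self.output_mean, self.output_scale = float(mean), float(scale)

    def _untransform(self, raw):
        if self.output_scale == 1.0 and self.output_mean == 0.0:
            return raw
        return ad.add(ad.mul(raw, self.output_scale), self.output_mean)

    def _check_grid_shape(self, shape: tuple) -> None:
        cfg = self.config
        expected = (cfg.in_channels, cfg.grid_edge, cfg.grid_edge, cfg.grid_edge)
        if tuple(shape) != expected:
            raise GridbindError(f"{cfg.family}: expected per-sample input shape {expected}, "
                                f"got {tuple(shape)}")

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Deterministic eval-mode predictions for a batch of inputs."""
        was_training = self.training
        self.eval()
        try:
            outs = []
            with nn.no_grad():
                for lo in range(0, x.shape[0], batch_size):
                    xb = np.ascontiguousarray(x[lo:lo + batch_size], dtype=self.config.np_dtype())
                    outs.append(self.forward(Tensor(xb)).data)
            return np.concatenate(outs)
        finally:
            if was_training:
                self.train()


class Cnn3d(_AffinityModel):
    """Plain 3-D CNN on a single voxel grid: (N, C, D, D, D) -> (N,)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.trunk = _ConvTrunk(cfg, rng)
        self.head = _Head(self.trunk.out_features, cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        if len(x.shape) != 5:
            raise GridbindError(f"cnn: expected a (N, C, D, D, D) batch, got shape {x.shape}")
        self._check_grid_shape(x.shape[1:])
        return self._untransform(self.head(self.trunk(x)))


class DenseBlock(nn.Module):
    """``layers`` convolutions, each fed the concatenation of everything before it."""

    def __init__(self, in_channels: int, layers: int, growth: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.convs = []
        cur = in_channels
        for _ in range(layers):
            self.convs.append(nn.Conv3d(cur, growth, 3, rng, padding=1, dtype=dtype))
            cur += growth
        self.out_channels = cur

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for conv in self.convs:
            inp = feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)
            feats.append(nn.relu(conv(inp)))
        return feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)


class Transition(nn.Module):
    """1x1x1 channel compression followed by a factor-2 spatial downsample."""

    def __init__(self, in_channels: int, compression: float,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.out_channels = transition_out_channels(in_channels, compression)
        self.conv = nn.Conv3d(in_channels, self.out_channels, 1, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return nn.avg_pool3d(nn.relu(self.conv(x)), 2)


class DenseCnn3d(_AffinityModel):
    """Dense-block 3-D CNN on a single voxel grid."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        dtype = cfg.np_dtype()
        self.stem = nn.Conv3d(cfg.in_channels, cfg.stem_channels, 3, rng, padding=1,
                              stride=2, dtype=dtype)
        self.blocks = []
        self.transitions = []
        cur = cfg.stem_channels
        for b in range(cfg.n_blocks):
            block = DenseBlock(cur, cfg.layers_per_block, cfg.growth, rng, dtype=dtype)
            self.blocks.append(block)
            cur = block.out_channels
            if b < cfg.n_blocks - 1:
                tr = Transition(cur, cfg.compression, rng, dtype=dtype)
                self.transitions.append(tr)
                cur = tr.out_channels
        self.head = _Head(cur, cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        if len(x.shape) != 5:
            raise GridbindError(f"dense_cnn: expected a (N, C, D, D, D) batch, got shape {x.shape}")
        self._check_grid_shape(x.shape[1:])
        x = nn.relu(self.stem(x))
        for b, block in enumerate(self.blocks):
            x = block(x)
            if b < len(self.transitions):
                x = self.transitions[b](x)
        return self._untransform(self.head(nn.global_mean_pool(x)))


class Lrcn(_AffinityModel):
    """Shared CNN encoder per frame + LSTM over the frame embeddings."""

    expects_sequence = True

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.encoder = _ConvTrunk(cfg, rng)
        self.lstm = nn.LSTMCell(self.encoder.out_features, cfg.lstm_hidden, rng,
                                dtype=cfg.np_dtype())
        self.head = _Head(cfg.lstm_hidden, cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        if len(x.shape) != 6:
            raise GridbindError(f"lrcn: expected a (N, T, C, D, D, D) batch, got shape {x.shape}")
        self._check_grid_shape(x.shape[2:])
        N, T = x.shape[0], x.shape[1]
        h, c = self.lstm.init_state(N, dtype=x.dtype)
        hs = []
        for t in range(T):
            emb = self.encoder(x[:, t])
            h, c = self.lstm(emb, h, c)
            hs.append(h)
        if self.config.temporal_readout == "mean":
            stacked = nn.concat([ad.reshape(hh, (N, 1, -1)) for hh in hs], axis=1)
            h = ad.tmean(stacked, axis=1)
        return self._untransform(self.head(h))


class ConvLstmNet(_AffinityModel):
    """Stacked ConvLSTM layers unrolled over the frames."""

    expects_sequence = True

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        dtype = cfg.np_dtype()
        self.cells = []
        cur = cfg.in_channels
        for _ in range(cfg.n_recurrent_layers):
            self.cells.append(nn.ConvLSTMCell(cur, cfg.hidden_channels, cfg.kernel_edge,
                                              rng, dtype=dtype))
            cur = cfg.hidden_channels
        self.head = _Head(cfg.hidden_channels, cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        if len(x.shape) != 6:
            raise GridbindError(f"convlstm: expected a (N, T, C, D, D, D) batch, got shape {x.shape}")
        self._check_grid_shape(x.shape[2:])
        N, T = x.shape[0], x.shape[1]
        spatial = x.shape[3:]
        inputs = [x[:, t] for t in range(T)]
        last_states = []
        for cell in self.cells:
            h, c = cell.init_state(N, spatial, dtype=x.dtype)
            outputs = []
            for t in range(T):
                h, c = cell(inputs[t], h, c)
                outputs.append(h)
            inputs = outputs
            last_states.append(outputs)
        outputs = last_states[-1]
        if self.config.temporal_readout == "mean":
            pooled = [nn.global_mean_pool(hh) for hh in outputs]
            stacked = nn.concat([ad.reshape(p, (N, 1, -1)) for p in pooled], axis=1)
            feat = ad.tmean(stacked, axis=1)
        else:
            feat = nn.global_mean_pool(outputs[-1])
        return self._untransform(self.head(feat))


_FAMILY_CLASSES = {"cnn": Cnn3d, "dense_cnn": DenseCnn3d, "lrcn": Lrcn, "convlstm": ConvLstmNet}


def build_model(cfg: ModelConfig, seed: int = 0) -> _AffinityModel:
    """Instantiate a model with seeded parameter initialisation."""
    rng = np.random.default_rng(seed)
    return _FAMILY_CLASSES[cfg.family](cfg, rng)


def save_checkpoint(model: _AffinityModel, path) -> None:
    """Single-file archive: config as JSON plus named parameter arrays."""
    arrays = {"param/" + k: v for k, v in model.state_dict().items()}
    np.savez(path, __config__=np.bytes_(model.config.to_json().encode()),
             __output_transform__=np.array([model.output_mean, model.output_scale]),
             **arrays)


def load_checkpoint(path, seed: int = 0) -> _AffinityModel:
    with np.load(path) as archive:
        cfg = ModelConfig.from_json(bytes(archive["__config__"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")}
        transform = archive["__output_transform__"] if "__output_transform__" in archive.files else None
    model = build_model(cfg, seed=seed)
    model.load_state_dict(state)
    if transform is not None:
        model.set_output_transform(float(transform[0]), float(transform[1]))
    return model


def describe_model(model: _AffinityModel) -> str:
    """Human-readable layer/parameter table."""
    buf = io.StringIO()
    cfg = model.config
    buf.write(f"family: {cfg.family}\n")
    buf.write(f"{'parameter':<40s} {'shape':<24s} {'count':>10s}\n")
    total = 0
    for name, p in model.named_parameters():
        buf.write(f"{name:<40s} {str(p.data.shape):<24s} {p.data.size:>10d}\n")
        total += p.data.size
    buf.write(f"{'total':<40s} {'':<24s} {total:>10d}\n")
    return buf.getvalue()
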