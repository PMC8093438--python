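"""The dual-stream ("Siamese") 3D CNN for masked-volume binary classification.

Topology: the same masked volume enters two parallel convolutional streams;
after two blocks per stream the activation maps are concatenated along the
channel axis (the *concatenate* layer), an add-block supplies a residual
connection, and a trunk of standard / separable / grouped convolutional
blocks reduces dimensionality before two fully connected blocks ending in a
4-dimensional feature vector and a logistic output.

Each convolutional block is convolution -> batch normalization -> ELU ->
max-pooling (where enabled) -> dropout; FC blocks are fully connected ->
batch normalization -> ELU -> dropout.  Weights use He initialization; an L2
penalty applies to all convolutional and fully connected weights.

Exact channel widths are not fixed: the model is config-driven with two
presets, ``desk`` (24^3-ish phantoms, CPU-trainable in minutes) and ``mni``
(91x109x91 MNI-152-sized grids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    DT,
    BatchNorm,
    Conv3D,
    Dense,
    Dropout,
    ELU,
    Flatten,
    GroupedConv3D,
    Layer,
    MaxPool3D,
    SeparableConv3D,
)

__all__ = ["BlockSpec", "CnnConfig", "TMaskCNN", "build_cnn", "CONCAT_LAYER"]

CONCAT_LAYER = "concatenate"


@dataclass(frozen=True)
class BlockSpec:
    """One trunk block: kind in {conv, separable_conv, grouped_conv}."""

    kind: str
    out_channels: int
    kernel: int = 3
    pool: bool = True
    groups: int = 1
    stride: int = 1  # only stride 1 is supported; downsampling is by pooling

    def __post_init__(self):
        if self.kind not in ("conv", "separable_conv", "grouped_conv"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported; use pool=True to downsample")


@dataclass(frozen=True)
class CnnConfig:
    input_shape: tuple[int, int, int] = (24, 24, 24)
    stream_channels: tuple[int, ...] = (4, 4)  # two blocks per stream
    trunk_blocks: tuple[BlockSpec, ...] = (
        BlockSpec("separable_conv", 8, pool=True),
        BlockSpec("grouped_conv", 8, groups=2, pool=False),
    )
    fc_sizes: tuple[int, int] = (16, 4)
    dropout_rate: float = 0.1
    l2_penalty: float = 5e-5
    share_stream_weights: bool = False

    def __post_init__(self):
        if self.fc_sizes[-1] != 4:
            raise ValueError("final feature dimension must be 4 before the logistic output")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be non-negative")
        if len(self.stream_channels) != 2:
            raise ValueError("each stream has exactly two blocks before the concatenation")

    @staticmethod
    def preset(name: str, input_shape=None) -> "CnnConfig":
        if name == "desk":
            return CnnConfig(input_shape=tuple(input_shape or (24, 24, 24)))
        if name == "mni":
            return CnnConfig(
                input_shape=tuple(input_shape or (91, 109, 91)),
                stream_channels=(8, 8),
                trunk_blocks=(
                    BlockSpec("separable_conv", 16, pool=True),
                    BlockSpec("grouped_conv", 16, groups=4, pool=True),
                    BlockSpec("separable_conv", 16, pool=True),
                ),
                fc_sizes=(32, 4),
            )
        raise ValueError(f"unknown preset {name!r}")


class _Block:
    """conv/FC block: ordered layers sharing one forward/backward pipeline."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training, rng):
        for lay in self.layers:
            x = lay.forward(x, training, rng)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


def _conv_block(spec: BlockSpec, in_ch: int, dropout: float, rng) -> _Block:
    if spec.kind == "conv":
        conv: Layer = Conv3D(in_ch, spec.out_channels, spec.kernel, rng)
    elif spec.kind == "separable_conv":
        conv = SeparableConv3D(in_ch, spec.out_channels, spec.kernel, rng)
    else:
        conv = GroupedConv3D(in_ch, spec.out_channels, spec.kernel, spec.groups, rng)
    layers: list[Layer] = [conv, BatchNorm(spec.out_channels), ELU()]
    if spec.pool:
        layers.append(MaxPool3D())
    layers.append(Dropout(dropout))
    return _Block(layers)


def _fc_block(in_f: int, out_f: int, dropout: float, rng) -> _Block:
    return _Block([Dense(in_f, out_f, rng), BatchNorm(out_f, spatial=False), ELU(), Dropout(dropout)])


class TMaskCNN:
    """Dual-stream 3D CNN with a logistic output.

    Use :func:`build_cnn` to construct.  ``forward``/``backward`` expose the
    activations and loss gradient at the concatenate layer for grad-CAM.
    """

    def __init__(self, config: CnnConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.dropout_rate

        def make_stream():
            blocks = []
            in_ch = 1
            for ch in config.stream_channels:
                blocks.append(_conv_block(BlockSpec("conv", ch, pool=True), in_ch, d, rng))
                in_ch = ch
            return blocks

        self.stream_a = make_stream()
        self.stream_b = self.stream_a if config.share_stream_weights else make_stream()
        concat_ch = 2 * config.stream_channels[-1]
        # residual path of the add-block: conv block without pooling
        self.res_block = _conv_block(BlockSpec("conv", concat_ch, pool=False), concat_ch, d, rng)

        in_ch = concat_ch
        self.trunk = []
        spatial = [s // 2 ** len(config.stream_channels) for s in config.input_shape]
        for spec in config.trunk_blocks:
            self.trunk.append(_conv_block(spec, in_ch, d, rng))
            in_ch = spec.out_channels
            if spec.pool:
                spatial = [s // 2 for s in spatial]
        if min(spatial) < 1:
            raise ValueError("configuration error: spatial dimensions collapse below 1")
        flat = in_ch * int(np.prod(spatial))
        self.flatten = Flatten()
        self.fc1 = _fc_block(flat, config.fc_sizes[0], d, rng)
        self.fc2 = _fc_block(config.fc_sizes[0], config.fc_sizes[1], d, rng)
        self.logit_layer = Dense(config.fc_sizes[1], 1, rng)
        self.concat_activation: np.ndarray | None = None
        self.concat_gradient: np.ndarray | None = None

    # ---- structure -------------------------------------------------
    def _unique_blocks(self) -> list[_Block]:
        blocks = list(self.stream_a)
        if self.stream_b is not self.stream_a:
            blocks += self.stream_b
        blocks += [self.res_block, *self.trunk, self.fc1, self.fc2]
        blocks.append(_Block([self.logit_layer]))
        return blocks

    def layers(self) -> list[Layer]:
        return [lay for b in self._unique_blocks() for lay in b.layers]

    @property
    def n_params(self) -> int:
        return sum(lay.n_params for lay in self.layers())

    @property
    def concat_channels(self) -> int:
        return 2 * self.config.stream_channels[-1]

    def get_state(self) -> list[dict[str, np.ndarray]]:
        state = []
        for lay in self.layers():
            s = {k: v.copy() for k, v in lay.params.items()}
            if isinstance(lay, BatchNorm):
                s["__rm"] = lay.running_mean.copy()
                s["__rv"] = lay.running_var.copy()
            state.append(s)
        return state

    def set_state(self, state) -> None:
        for lay, s in zip(self.layers(), state, strict=True):
            for k in lay.params:
                lay.params[k] = s[k].copy()
            if isinstance(lay, BatchNorm):
                lay.running_mean = s["__rm"].copy()
                lay.running_var = s["__rv"].copy()

    # ---- forward / backward ----------------------------------------
    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Return the per-subject logit; x is (N, 1, D, H, W) float32."""
        x = np.asarray(x, dtype=DT)
        ha = x
        for b in self.stream_a:
            ha = b.forward(ha, training, rng)
        if self.stream_b is self.stream_a:
            hb = ha
        else:
            hb = x
            for b in self.stream_b:
                hb = b.forward(hb, training, rng)
        concat = np.concatenate([ha, hb], axis=1)
        self.concat_activation = concat
        h = concat + self.res_block.forward(concat, training, rng)  # add-block
        for b in self.trunk:
            h = b.forward(h, training, rng)
        h = self.flatten.forward(h, training, rng)
        h = self.fc1.forward(h, training, rng)
        self.feature_vector = h = self.fc2.forward(h, training, rng)
        return self.logit_layer.forward(h, training, rng)[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logit); fills every layer's grads and
        records the gradient at the concatenate layer."""
        dy = self.logit_layer.backward(dlogit[:, None])
        dy = self.fc2.backward(dy)
        dy = self.fc1.backward(dy)
        dy = self.flatten.backward(dy)
        for b in reversed(self.trunk):
            dy = b.backward(dy)
        dconcat = dy + self.res_block.backward(dy)  # add-block fans out
        self.concat_gradient = dconcat
        c = self.config.stream_channels[-1]
        da, db = dconcat[:, :c], dconcat[:, c:]
        if self.stream_b is self.stream_a:
            da = da + db
        else:
            for b in reversed(self.stream_b):
                db = b.backward(db)
        for b in reversed(self.stream_a):
            da = b.backward(da)

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Class-1 probabilities in inference mode (dropout off, batch-norm
        running statistics); deterministic and batching-invariant."""
        x = np.asarray(x, dtype=DT)
        probs = []
        for i in range(0, x.shape[0], batch_size):
            logit = self.forward(x[i : i + batch_size], training=False)
            probs.append(_sigmoid(logit))
        return np.concatenate(probs)

    # ---- loss -------------------------------------------------------
    def loss_and_backward(self, x, y, training: bool = True, rng=None) -> tuple[float, np.ndarray]:
        """Mean binary cross-entropy + L2 penalty; runs the backward pass."""
        y = np.asarray(y, dtype=DT)
        logit = self.forward(x, training=training, rng=rng)
        p = _sigmoid(logit)
        eps = 1e-7
        pc = np.clip(p, eps, 1 - eps)
        loss = -float(np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
        l2 = self.config.l2_penalty
        if l2 > 0:
            loss += l2 * sum(
                float((lay.params[name] ** 2).sum())
                for lay in self.layers()
                for name in lay.l2_param_names
            )
        self.backward((p - y) / len(y))
        if l2 > 0:
            for lay in self.layers():
                for name in lay.l2_param_names:
                    lay.grads[name] = lay.grads[name] + 2 * l2 * lay.params[name]
        return loss, p

    def evaluate_loss(self, x, y, batch_size: int = 16) -> float:
        """Cross-entropy (no L2 term) in inference mode."""
        p = self.predict_proba(x, batch_size=batch_size)
        eps = 1e-7
        pc = np.clip(p, eps, 1 - eps)
        y = np.asarray(y, dtype=np.float64)
        return -float(np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def build_cnn(config: CnnConfig, seed: int = 0) -> TMaskCNN:
    """Construct the dual-stream CNN with He-initialized weights."""
    return TMaskCNN(config, seed=seed)
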