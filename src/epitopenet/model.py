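"""The two-branch epitope classifier.

Architecture: an embedding layer (21-token vocabulary, codes 0-20) feeds
two parallel feature extractors whose outputs are concatenated and pushed
through a 64/9/1 dense head ending in a sigmoid:

* branch 1 — a bidirectional LSTM over the L residue positions, pooled by
  feed-forward attention: each hidden state h_t is scored by a learnable
  function a(h_t), the scores are softmax-normalized into weights
  alpha_t = exp(e_t) / sum_k exp(e_k), and the branch output is the
  context vector c = sum_t alpha_t h_t;
* branch 2 — one 1-D convolution per kernel width ("scale", default
  11/13/15), each followed by ReLU and global max pooling, capturing
  sequence composition at several window sizes.

Either branch can be disabled (and individual CNN scales dropped) to form
the five ablation variants; at least one branch must remain.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor
from .seqio import EncodedBatch

logger = logging.getLogger("epitopenet")

ABLATION_VARIANTS = (
    "delete_bilstm",
    "delete_scale1",
    "delete_scale1_2",
    "delete_multiscale_cnn",
    "delete_attention",
)

STAGES = ("embedding", "bilstm", "attention", "cnn", "combined")


class ConfigError(ValueError):
    """A ModelConfig violates its invariants."""


@dataclass
class ModelConfig:
    """Every architectural and training hyperparameter in one record.

    Architectural defaults follow the published design where stated
    (L=25, three CNN scales 11/13/15, dense head 64/9/1); widths and the
    training recipe are package defaults chosen for reproducibility.
    """

    L: int = 25
    vocab_size: int = 21
    embed_dim: int = 64
    lstm_units: int = 64
    cnn_scales: tuple[int, ...] = (11, 13, 15)
    cnn_filters: int = 64
    dense_sizes: tuple[int, ...] = (64, 9, 1)
    dropout_rate: float = 0.3
    use_bilstm: bool = True
    use_attention: bool = True
    active_scales: Optional[tuple[int, ...]] = None
    seed: int = 0
    # training recipe
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    patience: int = 10

    def __post_init__(self) -> None:
        self.cnn_scales = tuple(self.cnn_scales)
        self.dense_sizes = tuple(self.dense_sizes)
        if self.active_scales is None:
            self.active_scales = self.cnn_scales
        self.active_scales = tuple(self.active_scales)
        if self.L < 1:
            raise ConfigError("L must be >= 1")
        if list(self.cnn_scales) != sorted(set(self.cnn_scales)):
            raise ConfigError("cnn_scales must be strictly increasing")
        if any(s > self.L for s in self.cnn_scales):
            raise ConfigError("every CNN scale must be <= L")
        if not set(self.active_scales) <= set(self.cnn_scales):
            raise ConfigError("active_scales must be a subset of cnn_scales")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if not self.use_bilstm and not self.active_scales:
            raise ConfigError(
                "at least one branch must be enabled (Bi-LSTM or CNN)"
            )
        if self.dense_sizes[-1] != 1:
            raise ConfigError("final dense layer must have exactly 1 neuron")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls.from_dict(json.loads(text))


def ablate(config: ModelConfig, variant: str) -> ModelConfig:
    """Return the configuration of one ablation variant.

    ``delete_bilstm`` removes the recurrent branch (taking its attention
    pooling with it); ``delete_scale1`` / ``delete_scale1_2`` drop the one
    or two smallest convolution kernels; ``delete_multiscale_cnn`` removes
    the CNN branch; ``delete_attention`` keeps the Bi-LSTM but replaces
    attention pooling with the concatenated final forward/backward hidden
    states.  Idempotent; everything else is unchanged.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(
            f"unknown ablation variant {variant!r}; choose from {ABLATION_VARIANTS}"
        )
    if variant == "delete_bilstm":
        if not config.active_scales:
            raise ConfigError("cannot delete the Bi-LSTM branch: no CNN branch left")
        return replace(config, use_bilstm=False)
    if variant == "delete_attention":
        return replace(config, use_attention=False)
    drop = {"delete_scale1": 1, "delete_scale1_2": 2, "delete_multiscale_cnn": None}[
        variant
    ]
    scales = () if drop is None else tuple(sorted(config.active_scales))[drop:]
    if not scales and not config.use_bilstm:
        raise ConfigError("ablation would leave no branch enabled")
    return replace(config, active_scales=scales)


@dataclass
class AttentionState:
    """All intermediate quantities of one feed-forward attention pass."""

    hidden_states: np.ndarray  # (T, D)
    scores: np.ndarray         # (T,)
    weights: np.ndarray        # (T,)
    context: np.ndarray        # (D,)


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Softmax-normalize attention scores: alpha_t = exp(e_t) / sum exp(e_k)."""
    e = np.asarray(scores, dtype=np.float64)
    z = np.exp(e - e.max())
    return z / z.sum()


def feed_forward_attention(
    h: np.ndarray, w: np.ndarray, b: float = 0.0
) -> AttentionState:
    """Pool a (T, D) hidden-state matrix with feed-forward attention.

    The learnable scorer is a single affine map to a scalar followed by
    tanh: e_t = tanh(h_t . w + b).  Scores are softmax-normalized and the
    context vector is the weighted sum of the hidden states, so it always
    lies in the convex hull of the rows of h.
    """
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] < 1 or h.shape[1] < 1:
        raise ValueError("h must be a (T, D) matrix with T, D >= 1")
    if not np.isfinite(h).all():
        raise FloatingPointError("non-finite hidden states")
    e = np.tanh(h @ np.asarray(w, dtype=np.float64) + b)
    alpha = attention_weights(e)
    c = alpha @ h
    return AttentionState(hidden_states=h, scores=e, weights=alpha, context=c)


class EpitopeClassifier:
    """Define-by-run network mapping integer-coded peptides to probabilities.

    All weights are float64 NumPy arrays initialized from ``config.seed``;
    two builds from the same config are bit-identical.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self._params: list[Parameter] = []
        rng = np.random.default_rng(config.seed)
        c = config
        E, H, F = c.embed_dim, c.lstm_units, c.cnn_filters

        self.embed = self._add(
            rng.normal(0.0, 0.05, size=(c.vocab_size, E)), "embedding"
        )
        if c.use_bilstm:
            self.lstm = {}
            for d in ("fwd", "bwd"):
                Wx = ag.glorot_uniform(rng, (E, 4 * H), E, 4 * H)
                Wh = ag.glorot_uniform(rng, (H, 4 * H), H, 4 * H)
                b = np.zeros(4 * H)
                b[H : 2 * H] = 1.0  # forget-gate bias
                self.lstm[d] = (
                    self._add(Wx, f"lstm_{d}_Wx"),
                    self._add(Wh, f"lstm_{d}_Wh"),
                    self._add(b, f"lstm_{d}_b"),
                )
            if c.use_attention:
                self.att_w = self._add(
                    ag.glorot_uniform(rng, (2 * H, 1), 2 * H, 1), "att_w"
                )
                self.att_b = self._add(np.zeros(1), "att_b")
        self.convs = {}
        for k in c.active_scales:
            w = ag.glorot_uniform(rng, (k, E, F), k * E, F)
            self.convs[k] = (
                self._add(w, f"conv{k}_w"),
                self._add(np.zeros(F), f"conv{k}_b"),
            )
        width = self.combined_width
        self.dense = []
        for i, size in enumerate(c.dense_sizes):
            W = ag.glorot_uniform(rng, (width, size), width, size)
            self.dense.append(
                (self._add(W, f"dense{i}_W"), self._add(np.zeros(size), f"dense{i}_b"))
            )
            width = size

    def _add(self, data: np.ndarray, name: str) -> Parameter:
        p = Parameter(data, name=name)
        self._params.append(p)
        return p

    # -- introspection -----------------------------------------------------

    @property
    def combined_width(self) -> int:
        c = self.config
        width = 0
        if c.use_bilstm:
            width += 2 * c.lstm_units
        width += len(c.active_scales) * c.cnn_filters
        return width

    def parameters(self) -> list[Parameter]:
        return list(self._params)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self._params))

    # -- forward pass ------------------------------------------------------

    def _lstm_direction(self, steps: list[Tensor], direction: str) -> list[Tensor]:
        """Run one LSTM direction over a list of (n, E) timestep tensors."""
        Wx, Wh, b = self.lstm[direction]
        H = self.config.lstm_units
        n = steps[0].shape[0]
        h = Tensor(np.zeros((n, H)))
        cell = Tensor(np.zeros((n, H)))
        order = steps if direction == "fwd" else list(reversed(steps))
        outs: list[Tensor] = []
        for x_t in order:
            gates = ag.add(ag.add(ag.matmul(x_t, Wx), ag.matmul(h, Wh)), b)
            i = ag.sigmoid(ag.slice_axis1(gates, 0, H))
            f = ag.sigmoid(ag.slice_axis1(gates, H, 2 * H))
            g = ag.tanh(ag.slice_axis1(gates, 2 * H, 3 * H))
            o = ag.sigmoid(ag.slice_axis1(gates, 3 * H, 4 * H))
            cell = ag.add(ag.mul(f, cell), ag.mul(i, g))
            h = ag.mul(o, ag.tanh(cell))
            outs.append(h)
        if direction == "bwd":
            outs = list(reversed(outs))
        return outs

    def forward(
        self,
        codes: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> dict[str, Tensor]:
        """Run the network; returns logits, probabilities and stage taps."""
        codes = np.asarray(codes, dtype=np.int64)
        if codes.ndim != 2 or codes.shape[1] != self.config.L:
            raise ValueError(f"expected an (n, {self.config.L}) integer batch")
        c = self.config
        n, L = codes.shape
        taps: dict[str, Tensor] = {}

        emb = ag.embedding(self.embed, codes)  # (n, L, E)
        taps["embedding"] = emb
        branches: list[Tensor] = []

        if c.use_bilstm:
            steps = [ag.timestep(emb, t) for t in range(L)]
            fwd = self._lstm_direction(steps, "fwd")
            bwd = self._lstm_direction(steps, "bwd")
            hs = ag.stack(
                [ag.concat([f, bkw], axis=1) for f, bkw in zip(fwd, bwd)], axis=1
            )  # (n, T, 2H)
            taps["bilstm"] = hs
            if c.use_attention:
                D = 2 * c.lstm_units
                flat = ag.reshape(hs, (n * L, D))
                e = ag.tanh(ag.add(ag.matmul(flat, self.att_w), self.att_b))
                e = ag.reshape(e, (n, L))
                alpha = ag.softmax(e, axis=1)
                alpha3 = ag.reshape(alpha, (n, L, 1))
                ctx = ag.sum_along(ag.mul(alpha3, hs), axis=1)  # (n, 2H)
                taps["attention"] = ctx
                branches.append(ctx)
            else:
                summary = ag.concat([fwd[-1], bwd[0]], axis=1)
                branches.append(summary)

        if c.active_scales:
            pooled = []
            for k in c.active_scales:
                w, b = self.convs[k]
                conv = ag.relu(ag.conv1d_same(emb, w, b))  # (n, L, F)
                pooled.append(ag.max_along(conv, axis=1))  # (n, F)
            cnn_out = ag.concat(pooled, axis=1)
            taps["cnn"] = cnn_out
            branches.append(cnn_out)

        combined = branches[0] if len(branches) == 1 else ag.concat(branches, axis=1)
        taps["combined"] = combined

        x = combined
        if train and c.dropout_rate > 0:
            if rng is None:
                raise ValueError("training forward pass requires an rng for dropout")
            x = ag.dropout(x, c.dropout_rate, rng)
        for i, (W, b) in enumerate(self.dense):
            x = ag.add(ag.matmul(x, W), b)
            if i < len(self.dense) - 1:
                x = ag.relu(x)
        logits = ag.reshape(x, (n,))
        taps["logits"] = logits
        taps["probability"] = ag.sigmoid(logits)
        return taps

    def predict_proba(self, batch: EncodedBatch | np.ndarray) -> np.ndarray:
        codes = batch.codes if isinstance(batch, EncodedBatch) else batch
        return self.forward(codes)["probability"].data

    # -- persistence -------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self._params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        if len(weights) != len(self._params):
            raise ValueError("weight count mismatch")
        for p, w in zip(self._params, weights):
            if p.data.shape != w.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.data = np.asarray(w, dtype=np.float64).copy()

    def save(self, path: str | Path) -> None:
        """Save a self-describing checkpoint (weights + embedded config)."""
        arrays = {f"param_{i}": p.data for i, p in enumerate(self._params)}
        np.savez(path, config=np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EpitopeClassifier":
        with np.load(path) as data:
            config = ModelConfig.from_json(bytes(data["config"]).decode())
            net = cls(config)
            weights = [data[f"param_{i}"] for i in range(len(net._params))]
        net.set_weights(weights)
        return net


def forward_with_taps(
    network: EpitopeClassifier, batch: EncodedBatch | np.ndarray, stage: str
) -> np.ndarray:
    """Per-sample activations at a named stage, flattened to one row each.

    Stages: ``embedding`` (n x L*E), ``bilstm`` (n x L*2H), ``attention``
    (n x 2H context vectors), ``cnn`` (n x scales*F pooled features),
    ``combined`` (n x concatenated branch widths).  Requesting a stage the
    (possibly ablated) network does not contain raises a ``ValueError``
    naming the stage.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    codes = batch.codes if isinstance(batch, EncodedBatch) else batch
    taps = network.forward(codes)
    if stage not in taps:
        raise ValueError(
            f"stage {stage!r} is absent in this network (ablated configuration)"
        )
    act = taps[stage].data
    return act.reshape(act.shape[0], -1)
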