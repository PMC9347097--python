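"""Multi-scaled self-attention regressor for drug–target binding affinity.

Two token streams — a segmented SMILES string and a segmented protein
sequence — are embedded (token + learned position embeddings), passed
through stacks of *multi-scaled* self-attention blocks, and fused by a
feed-forward interaction stack into one scalar affinity.

The multi-scaled block is a Transformer encoder block whose heads attend
through different *windows*: head ``h`` adds a banded mask ``M^h`` to its
scaled dot-product logits so that query ``i`` sees only keys ``j`` with
``i − m^h ≤ j ≤ i + m^h``.  A head with ``m = 0`` copies its value vectors;
a head with ``m ≥ l − 1`` is ordinary global attention; intermediate
windows capture local chemical patterns at different scales.  Head outputs
are concatenated (head width ``e / N``, so no output projection is needed),
followed by residual + LayerNorm and a single ReLU feed-forward layer of
width ``e`` with its own residual + LayerNorm.

Everything runs on the float64 autodiff tape in :mod:`msadta._autograd`;
training is Adam on mean squared error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._autograd import Adam, Tensor, concat, take_rows

NEG_INF = -1e9  # large finite stand-in for -inf so softmax never sees NaN

__all__ = [
    "ModelConfig",
    "BandMask",
    "HeadParams",
    "build_band_mask",
    "attention_head",
    "layer_norm",
    "DTAModel",
    "TrainedRun",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "NEG_INF",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class ModelConfig:
    """Hyper-parameters of the affinity model.

    ``window_sizes`` lists the per-head attention half-widths ``m^h``; when
    there are more heads than windows the list cycles.  ``ffn_hidden`` gives
    the interaction-stack layer widths, last entry 1 (the scalar affinity).
    ``e_p`` defaults to ``e_d``.
    """

    l_d: int = 80
    l_p: int = 800
    e_d: int = 128
    e_p: int | None = None
    n_heads: int = 4
    window_sizes: tuple[int, ...] = (0, 1, 2, 3)
    L_d: int = 2
    L_p: int = 2
    ffn_hidden: tuple[int, ...] = (1024, 1024, 512, 1)
    dropout: float = 0.1
    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 32
    aggregation: str = "flatten"  # flatten | mean | max

    def __post_init__(self) -> None:
        if self.e_p is None:
            self.e_p = self.e_d
        self.window_sizes = tuple(int(m) for m in self.window_sizes)
        self.ffn_hidden = tuple(int(h) for h in self.ffn_hidden)
        for name in ("l_d", "l_p", "e_d", "e_p", "n_heads", "L_d", "L_p", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for e, tag in ((self.e_d, "e_d"), (self.e_p, "e_p")):
            if e % self.n_heads != 0:
                raise ValueError(f"n_heads must divide {tag} ({self.n_heads} vs {e})")
        if not self.window_sizes:
            raise ValueError("window_sizes must be non-empty")
        if any(m < 0 for m in self.window_sizes):
            raise ValueError("window sizes must be >= 0")
        if len(self.window_sizes) > self.n_heads:
            raise ValueError("more window sizes than heads")
        if self.ffn_hidden[-1] != 1:
            raise ValueError("last interaction layer must have width 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.aggregation not in {"flatten", "mean", "max"}:
            raise ValueError(f"unknown aggregation: {self.aggregation!r}")

    def head_window(self, h: int) -> int:
        return self.window_sizes[h % len(self.window_sizes)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_sizes"] = list(self.window_sizes)
        d["ffn_hidden"] = list(self.ffn_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def preset(cls, name: str) -> "ModelConfig":
        """Load a shipped preset: ``kiba``, ``davis`` or ``tiny``."""
        from importlib import resources

        ref = resources.files("msadta") / "configs" / f"{name}.yaml"
        if not ref.is_file():
            raise ValueError(f"unknown preset: {name!r}")
        return cls.from_dict(yaml.safe_load(ref.read_text()))


# --------------------------------------------------------------------------
# attention primitives
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class BandMask:
    """Additive attention mask that opens a band of half-width ``window_m``."""

    matrix: np.ndarray
    window_m: int


@dataclass
class HeadParams:
    """Projection matrices of one attention head (each ``e × d_h``)."""

    W_Q: Tensor
    W_K: Tensor
    W_V: Tensor

    @property
    def d_h(self) -> int:
        return self.W_Q.shape[1]


def build_band_mask(l: int, m: int) -> BandMask:
    """Mask with 0 where ``(i − m) ≤ j ≤ (i + m)`` and −∞ elsewhere.

    The diagonal is always open, so every query attends at least to itself.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if m < 0:
        raise ValueError("m must be >= 0")
    i = np.arange(l)[:, None]
    j = np.arange(l)[None, :]
    inside = np.abs(i - j) <= m
    return BandMask(matrix=np.where(inside, 0.0, NEG_INF), window_m=m)


def attention_head(
    E: Tensor | np.ndarray,
    params: HeadParams,
    mask: BandMask | np.ndarray,
    attn_dropout: np.ndarray | None = None,
) -> Tensor:
    """One masked scaled-dot-product attention head.

    ``softmax(Q Kᵀ / √d_h + M) V`` with the additive mask applied after the
    √d_h scaling.  Rows whose mask blocks every key (possible once padding
    masks are folded in) output exactly zero.
    """
    E = Tensor.wrap(E)
    if isinstance(mask, BandMask):
        mask = mask.matrix
    if E.shape[-1] != params.W_Q.shape[0]:
        raise ValueError(
            f"embedding width {E.shape[-1]} does not match projection "
            f"fan-in {params.W_Q.shape[0]}"
        )
    if mask.shape[-1] != E.shape[-2]:
        raise ValueError("mask size does not match sequence length")
    Q = E @ params.W_Q
    K = E @ params.W_K
    V = E @ params.W_V
    scores = (Q @ K.transpose_last2()) * (1.0 / np.sqrt(params.d_h)) + Tensor(mask)
    A = scores.softmax(axis=-1)
    if attn_dropout is not None:
        A = A * Tensor(attn_dropout)
    out = A @ V
    row_open = (mask.max(axis=-1, keepdims=True) > NEG_INF / 2).astype(float)
    if not np.all(row_open):
        out = out * Tensor(row_open)
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred * ((var + eps) ** -0.5) * gamma + beta


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------
class DTAModel:
    """Two multi-scaled self-attention encoders + interaction stack.

    Parameters
    ----------
    config:
        Hyper-parameters; see :class:`ModelConfig`.
    n_drug_tokens, n_protein_tokens:
        Embedding-table row counts, i.e. the full id range of each
        vocabulary including the pad and unknown ids
        (:attr:`msadta.bpe.Vocabulary.n_ids`).
    seed:
        Parameter-initialisation seed.
    """

    def __init__(
        self,
        config: ModelConfig,
        n_drug_tokens: int,
        n_protein_tokens: int,
        seed: int = 0,
    ):
        self.config = config
        self.n_drug_tokens = int(n_drug_tokens)
        self.n_protein_tokens = int(n_protein_tokens)
        self.y_mean = 0.0
        self.y_std = 1.0
        self._params: dict[str, Tensor] = {}
        rng = np.random.default_rng([seed, 23])
        self._build_encoder("drug", self.n_drug_tokens, config.l_d, config.e_d, config.L_d, rng)
        self._build_encoder(
            "protein", self.n_protein_tokens, config.l_p, config.e_p, config.L_p, rng
        )
        self._build_interaction(rng)
        self._band = {
            "drug": [build_band_mask(config.l_d, config.head_window(h)).matrix
                     for h in range(config.n_heads)],
            "protein": [build_band_mask(config.l_p, config.head_window(h)).matrix
                        for h in range(config.n_heads)],
        }

    # -- parameter construction ------------------------------------------
    def _param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def _glorot(self, rng, fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    def _build_encoder(self, side, n_tokens, l, e, n_blocks, rng) -> None:
        self._param(f"{side}.tok_emb", rng.normal(0.0, 0.1, size=(n_tokens, e)))
        self._param(f"{side}.pos_emb", rng.normal(0.0, 0.1, size=(l, e)))
        d_h = e // self.config.n_heads
        for b in range(n_blocks):
            pre = f"{side}.block{b}"
            for h in range(self.config.n_heads):
                for w in ("W_Q", "W_K", "W_V"):
                    self._param(f"{pre}.head{h}.{w}", self._glorot(rng, e, d_h))
            self._param(f"{pre}.ln1.gamma", np.ones(e))
            self._param(f"{pre}.ln1.beta", np.zeros(e))
            self._param(f"{pre}.ffn.W", self._glorot(rng, e, e))
            self._param(f"{pre}.ffn.b", np.zeros(e))
            self._param(f"{pre}.ln2.gamma", np.ones(e))
            self._param(f"{pre}.ln2.beta", np.zeros(e))

    def _interaction_in_dim(self) -> int:
        cfg = self.config
        if cfg.aggregation == "flatten":
            return cfg.l_d * cfg.e_d + cfg.l_p * cfg.e_p
        return cfg.e_d + cfg.e_p

    def _build_interaction(self, rng) -> None:
        widths = (self._interaction_in_dim(),) + self.config.ffn_hidden
        for i in range(len(widths) - 1):
            self._param(f"inter.W{i}", self._glorot(rng, widths[i], widths[i + 1]))
            self._param(f"inter.b{i}", np.zeros(widths[i + 1]))

    # -- introspection ----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self._params.values()))

    # -- forward pieces ---------------------------------------------------
    def _dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        p = self.config.dropout
        if not train or p == 0.0:
            return x
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def embed(self, ids: np.ndarray, side: str) -> Tensor:
        """Token + position embedding: row i is ``tok[ids[i]] + pos[i]``."""
        ids = np.asarray(ids, dtype=np.int64)
        n_tokens = self.n_drug_tokens if side == "drug" else self.n_protein_tokens
        if ids.min() < 0 or ids.max() >= n_tokens:
            raise ValueError(
                f"{side} ids out of range [0, {n_tokens}): "
                f"found [{ids.min()}, {ids.max()}]"
            )
        return take_rows(self._params[f"{side}.tok_emb"], ids) + self._params[f"{side}.pos_emb"]

    def _block(self, E: Tensor, side: str, b: int, keypad: np.ndarray,
               train: bool, rng) -> Tensor:
        cfg = self.config
        pre = f"{side}.block{b}"
        heads = []
        for h in range(cfg.n_heads):
            mask = self._band[side][h] + keypad  # (B, l, l) via broadcast
            drop = None
            if train and cfg.dropout > 0:
                shape = mask.shape if mask.ndim == 3 else (1,) + mask.shape
                drop = (rng.random(shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            params = HeadParams(
                W_Q=self._params[f"{pre}.head{h}.W_Q"],
                W_K=self._params[f"{pre}.head{h}.W_K"],
                W_V=self._params[f"{pre}.head{h}.W_V"],
            )
            heads.append(attention_head(E, params, mask, attn_dropout=drop))
        Z = layer_norm(
            concat(heads, axis=-1) + E,
            self._params[f"{pre}.ln1.gamma"],
            self._params[f"{pre}.ln1.beta"],
        )
        F = (Z @ self._params[f"{pre}.ffn.W"] + self._params[f"{pre}.ffn.b"]).relu()
        return layer_norm(
            Z + F,
            self._params[f"{pre}.ln2.gamma"],
            self._params[f"{pre}.ln2.beta"],
        )

    def encode_side(self, ids: np.ndarray, side: str, train: bool = False,
                    rng=None) -> Tensor:
        """Run one encoder stack; returns the (B, l, e) deep representation."""
        ids = np.atleast_2d(np.asarray(ids, dtype=np.int64))
        n_blocks = self.config.L_d if side == "drug" else self.config.L_p
        E = self._dropout(self.embed(ids, side), train, rng)
        keypad = np.where(ids == 0, NEG_INF, 0.0)[:, None, :]
        for b in range(n_blocks):
            E = self._block(E, side, b, keypad, train, rng)
        return E

    def _aggregate(self, R: Tensor) -> Tensor:
        B, l, e = R.shape
        mode = self.config.aggregation
        if mode == "flatten":
            return R.reshape(B, l * e)
        if mode == "mean":
            return R.mean(axis=1)
        return R.max(axis=1)

    def interaction_forward(self, R_d: Tensor, R_p: Tensor, train: bool = False,
                            rng=None) -> Tensor:
        """Fuse the two deep representations into one scalar per pair."""
        x = concat([self._aggregate(R_d), self._aggregate(R_p)], axis=-1)
        n_layers = len(self.config.ffn_hidden)
        for i in range(n_layers):
            x = x @ self._params[f"inter.W{i}"] + self._params[f"inter.b{i}"]
            if i < n_layers - 1:
                x = self._dropout(x.relu(), train, rng)
        return x.reshape(x.shape[0])

    def forward(self, drug_ids: np.ndarray, protein_ids: np.ndarray,
                train: bool = False, rng=None) -> Tensor:
        """Predicted affinity (standardised scale) for a batch of pairs."""
        R_d = self.encode_side(drug_ids, "drug", train, rng)
        R_p = self.encode_side(protein_ids, "protein", train, rng)
        return self.interaction_forward(R_d, R_p, train, rng)

    # -- training / inference ---------------------------------------------
    def fit(
        self,
        drug_ids: np.ndarray,
        protein_ids: np.ndarray,
        y: np.ndarray,
        seed: int = 0,
        epochs: int | None = None,
        callback=None,
    ) -> list[float]:
        """Adam optimisation of MSE; returns the per-epoch loss trace.

        Targets are standardised to zero mean / unit variance on this
        training set (statistics are stored on the model and undone by
        :meth:`predict`); the recorded trace is on the original scale.
        """
        cfg = self.config
        y = np.asarray(y, dtype=float)
        n = y.size
        if n == 0:
            raise ValueError("empty training set")
        epochs = cfg.epochs if epochs is None else epochs
        self.y_mean = float(y.mean())
        sd = float(y.std())
        self.y_std = sd if sd > 0 else 1.0
        yz = (y - self.y_mean) / self.y_std
        rng = np.random.default_rng([seed, 101])
        opt = Adam(self.parameters(), lr=cfg.learning_rate)
        trace: list[float] = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                pred = self.forward(drug_ids[sel], protein_ids[sel], train=True, rng=rng)
                err = pred - Tensor(yz[sel])
                loss = (err * err).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch starting {start}; lower the learning rate"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * sel.size
            trace.append(total / n * self.y_std**2)
            if callback is not None:
                callback(epoch, trace[-1])
        return trace

    def predict(self, drug_ids: np.ndarray, protein_ids: np.ndarray,
                batch_size: int = 64) -> np.ndarray:
        """Affinity predictions on the original target scale."""
        drug_ids = np.atleast_2d(drug_ids)
        protein_ids = np.atleast_2d(protein_ids)
        outs = []
        for start in range(0, drug_ids.shape[0], batch_size):
            out = self.forward(
                drug_ids[start : start + batch_size],
                protein_ids[start : start + batch_size],
                train=False,
            )
            outs.append(out.data)
        return self.y_mean + self.y_std * np.concatenate(outs)


# --------------------------------------------------------------------------
# dataset-level training pipeline
# --------------------------------------------------------------------------
@dataclass
class TrainedRun:
    """A trained model together with everything needed to reuse it."""

    model: DTAModel
    trace: list[float]
    drug_vocab: "object"
    protein_vocab: "object"
    encoded_drugs: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    encoded_proteins: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def encode_dataset(dataset, config: ModelConfig, threshold_drug: int,
                   threshold_protein: int):
    """Train BPE on the dataset's own sequences and encode every entity."""
    from . import bpe

    vocab_d = bpe.build_vocabulary(
        bpe.train_bpe(list(dataset.drugs.values()), threshold_drug)
    )
    vocab_p = bpe.build_vocabulary(
        bpe.train_bpe(list(dataset.proteins.values()), threshold_protein)
    )
    xd = {
        k: bpe.encode_string(s, vocab_d, config.l_d).ids
        for k, s in dataset.drugs.items()
    }
    xp = {
        k: bpe.encode_string(s, vocab_p, config.l_p).ids
        for k, s in dataset.proteins.items()
    }
    return vocab_d, vocab_p, xd, xp


def triples_to_arrays(dataset, xd: dict, xp: dict,
                      indices: Sequence[int] | None = None):
    idx = range(len(dataset.triples)) if indices is None else indices
    triples = [dataset.triples[i] for i in idx]
    drug_arr = np.stack([xd[d] for d, _, _ in triples])
    prot_arr = np.stack([xp[p] for _, p, _ in triples])
    y = np.array([v for _, _, v in triples], dtype=float)
    return drug_arr, prot_arr, y


def train(
    dataset,
    config: ModelConfig,
    seed: int,
    threshold_drug: int = 100,
    threshold_protein: int = 100,
    train_indices: Sequence[int] | None = None,
    epochs: int | None = None,
    callback=None,
) -> TrainedRun:
    """End-to-end: tokenise a dataset, build the model, fit, return the run.

    ``train_indices`` restricts fitting to a subset of triples (fold
    training); vocabularies are always trained on the full entity tables
    since those are inputs, not labels.
    """
    vocab_d, vocab_p, xd, xp = encode_dataset(
        dataset, config, threshold_drug, threshold_protein
    )
    drug_arr, prot_arr, y = triples_to_arrays(dataset, xd, xp, train_indices)
    model = DTAModel(config, vocab_d.n_ids, vocab_p.n_ids, seed=seed)
    trace = model.fit(drug_arr, prot_arr, y, seed=seed, epochs=epochs, callback=callback)
    return TrainedRun(
        model=model,
        trace=trace,
        drug_vocab=vocab_d,
        protein_vocab=vocab_p,
        encoded_drugs=xd,
        encoded_proteins=xp,
    )


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------
def _vocab_hash(vocab) -> str:
    return hashlib.sha256(vocab.to_json_str().encode()).hexdigest()[:16]


def save_checkpoint(model: DTAModel, path: str | Path, drug_vocab=None,
                    protein_vocab=None) -> None:
    """Single-file checkpoint: parameters + config + vocabularies."""
    meta = {
        "config": model.config.to_dict(),
        "y_mean": model.y_mean,
        "y_std": model.y_std,
        "n_drug_tokens": model.n_drug_tokens,
        "n_protein_tokens": model.n_protein_tokens,
        "drug_vocab": drug_vocab.to_json_str() if drug_vocab is not None else None,
        "protein_vocab": protein_vocab.to_json_str() if protein_vocab is not None else None,
        "vocab_hashes": {
            "drug": _vocab_hash(drug_vocab) if drug_vocab is not None else None,
            "protein": _vocab_hash(protein_vocab) if protein_vocab is not None else None,
        },
    }
    arrays = {f"param::{k}": t.data for k, t in model._params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path):
    """Returns ``(model, drug_vocab, protein_vocab)``; vocabs may be None."""
    from .bpe import Vocabulary

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = DTAModel(
            ModelConfig.from_dict(meta["config"]),
            meta["n_drug_tokens"],
            meta["n_protein_tokens"],
        )
        model.y_mean = meta["y_mean"]
        model.y_std = meta["y_std"]
        for key, tensor in model._params.items():
            tensor.data[...] = data[f"param::{key}"]
    vd = Vocabulary.from_json_str(meta["drug_vocab"]) if meta["drug_vocab"] else None
    vp = Vocabulary.from_json_str(meta["protein_vocab"]) if meta["protein_vocab"] else None
    return model, vd, vp
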