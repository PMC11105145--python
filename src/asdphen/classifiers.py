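"""The three trainable sentence labelers.

* ``binary_gru`` — a bidirectional GRU trained separately per criterion
  (seven binary models); decision: sigmoid score strictly above the
  threshold.
* ``hybrid_lstm`` — a bidirectional LSTM with additive attention pooling
  whose input is augmented with a side channel encoding the rule-parser
  lexicon terms found in the sentence (expert knowledge injected into the
  neural model); also trained per criterion.
* ``multilabel_lstm`` — one bidirectional LSTM with attention emitting all
  seven criterion scores; each label whose score is strictly above the
  threshold (default 0.5) is assigned.

Embeddings are pluggable and fixed (not trained): the default provider maps
each token to a deterministic pseudo-random vector derived by hashing the
token string with a salt, so runs are reproducible with no embedding file;
a loader for 300-d GloVe-format text files is included for pretrained
vectors.  Named presets expose both full-scale reference hyperparameters
(two epochs / 128 GRUs / depth 9 / batch 1000; ten epochs / batch 16 /
150 recurrent units / 10 parser-input units / 20 attention units /
150 final units) and small presets sized for desk-scale corpora.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .rules import RuleSet, all_lexicon_terms, extract_lexicon_terms, tokenize
from .types import ALL_CRITERIA, Criterion, PredictionSet, Record

# ---------------------------------------------------------------------------
# embeddings


class HashEmbeddings:
    """Deterministic pseudo-random token vectors (no external file).

    Each token's vector is drawn from a Generator seeded by a salted
    blake2b hash of the token, so vectors are stable across processes and
    platforms.  Every token, including previously unseen ones, gets a
    well-defined vector.
    """

    def __init__(self, dimension: int = 300, seed: int = 0, scale: float = 0.3):
        self.dimension = dimension
        self.seed = seed
        self.scale = scale
        self._cache: Dict[str, np.ndarray] = {}

    @property
    def provenance(self) -> Dict[str, object]:
        return {"kind": "seeded-hash", "dimension": self.dimension, "seed": self.seed,
                "scale": self.scale}

    def vector(self, token: str) -> np.ndarray:
        v = self._cache.get(token)
        if v is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{token}".encode("utf-8"), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            v = rng.normal(0.0, self.scale, size=self.dimension).astype(np.float32)
            self._cache[token] = v
        return v


class GloveEmbeddings:
    """Pretrained vectors from a GloVe-format text file (token + floats).

    Out-of-vocabulary tokens map to the zero vector.
    """

    def __init__(self, path):
        self.path = str(path)
        self._table: Dict[str, np.ndarray] = {}
        dim = None
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) < 2:
                    continue
                vec = np.asarray(parts[1:], dtype=np.float32)
                if dim is None:
                    dim = vec.size
                elif vec.size != dim:
                    raise ValueError(f"inconsistent embedding width in {path}")
                self._table[parts[0]] = vec
        if dim is None:
            raise ValueError(f"no vectors found in {path}")
        self.dimension = int(dim)
        self._oov = np.zeros(self.dimension, dtype=np.float32)

    @property
    def provenance(self) -> Dict[str, object]:
        return {"kind": "glove-text", "path": self.path, "dimension": self.dimension}

    def vector(self, token: str) -> np.ndarray:
        return self._table.get(token, self._oov)


EmbeddingProvider = Union[HashEmbeddings, GloveEmbeddings]


def embeddings_from_provenance(prov: Dict[str, object]) -> EmbeddingProvider:
    if prov["kind"] == "seeded-hash":
        return HashEmbeddings(
            dimension=int(prov["dimension"]), seed=int(prov["seed"]),
            scale=float(prov.get("scale", 0.3))
        )
    if prov["kind"] == "glove-text":
        return GloveEmbeddings(prov["path"])
    raise ValueError(f"unknown embedding provenance {prov!r}")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one classifier architecture.

    ``layers`` counts total block depth (embedding, each directional
    recurrent block, pooling, dense, output); depth >= 8 stacks a second
    bidirectional recurrent layer.  ``threshold`` is the strict decision
    cut on sigmoid scores: a score exactly at the threshold does NOT assign
    the label.
    """

    architecture: str = "binary_gru"  # binary_gru | hybrid_lstm | multilabel_lstm
    epochs: int = 2
    batch_size: int = 64
    recurrent_units: int = 128
    layers: int = 9
    parser_input_units: int = 10
    attention_units: int = 20
    final_layer_units: int = 150
    threshold: float = 0.5
    learning_rate: float = 0.003
    max_tokens: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")
        if self.architecture not in {"binary_gru", "hybrid_lstm", "multilabel_lstm"}:
            raise ValueError(f"unknown architecture {self.architecture!r}")

    @property
    def recurrent_layers(self) -> int:
        return 2 if self.layers >= 8 else 1

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.blake2b(payload, digest_size=4).hexdigest()

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


#: Named presets: reference hyperparameters and scaled-down test presets.
PRESETS: Dict[str, ModelConfig] = {
    "binary_gru": ModelConfig(
        architecture="binary_gru", epochs=2, batch_size=1000,
        recurrent_units=128, layers=9, final_layer_units=64,
    ),
    "hybrid_lstm": ModelConfig(
        architecture="hybrid_lstm", epochs=10, batch_size=16,
        recurrent_units=150, layers=6, parser_input_units=10,
        attention_units=20, final_layer_units=150,
    ),
    "multilabel_lstm": ModelConfig(
        architecture="multilabel_lstm", epochs=10, batch_size=16,
        recurrent_units=150, layers=6, parser_input_units=10,
        attention_units=20, final_layer_units=150, threshold=0.5,
    ),
    "binary_gru_small": ModelConfig(
        architecture="binary_gru", epochs=6, batch_size=64,
        recurrent_units=16, layers=5, final_layer_units=16, learning_rate=0.01,
    ),
    "hybrid_lstm_small": ModelConfig(
        architecture="hybrid_lstm", epochs=6, batch_size=64,
        recurrent_units=16, layers=5, parser_input_units=8,
        attention_units=8, final_layer_units=16, learning_rate=0.01,
    ),
    # small batches keep the shared multilabel head from collapsing to the
    # all-negative solution under the ~95%-negative label marginals
    "multilabel_lstm_small": ModelConfig(
        architecture="multilabel_lstm", epochs=8, batch_size=16,
        recurrent_units=16, layers=5, attention_units=8,
        final_layer_units=16, learning_rate=0.01,
    ),
}


# ---------------------------------------------------------------------------
# batching


def _encode_batch(
    texts: Sequence[str], emb: EmbeddingProvider, max_tokens: int
) -> Tuple[List[nn.Tensor], np.ndarray]:
    toks = [[t for t, _, _ in tokenize(x)][:max_tokens] for x in texts]
    T = max(1, max((len(t) for t in toks), default=1))
    B, D = len(texts), emb.dimension
    mask = np.zeros((B, T), dtype=np.float32)
    steps = np.zeros((T, B, D), dtype=np.float32)
    for b, seq in enumerate(toks):
        for t, tok in enumerate(seq):
            steps[t, b] = emb.vector(tok)
            mask[b, t] = 1.0
    return [nn.constant(steps[t]) for t in range(T)], mask


# ---------------------------------------------------------------------------
# core network


class SentenceNet:
    """One recurrent sentence scorer; architecture chosen by config."""

    def __init__(self, cfg: ModelConfig, emb: EmbeddingProvider,
                 n_outputs: int, side_dim: int = 0):
        self.cfg = cfg
        self.emb = emb
        self.n_outputs = n_outputs
        self.side_dim = side_dim
        rng = np.random.default_rng(cfg.seed)
        kind = "gru" if cfg.architecture == "binary_gru" else "lstm"
        H = cfg.recurrent_units
        self.layers: List[nn.BiRecurrent] = [nn.BiRecurrent(rng, kind, emb.dimension, H)]
        for _ in range(cfg.recurrent_layers - 1):
            self.layers.append(nn.BiRecurrent(rng, kind, 2 * H, H))
        self.use_attention = cfg.architecture != "binary_gru"
        if self.use_attention:
            self.attn = nn.AttentionPool(rng, 2 * H, cfg.attention_units)
        feat = 2 * H
        if side_dim > 0:
            self.side_dense = nn.Dense(rng, side_dim, cfg.parser_input_units, "tanh")
            feat += cfg.parser_input_units
        else:
            self.side_dense = None
        self.final = nn.Dense(rng, feat, cfg.final_layer_units, "tanh")
        self.out = nn.Dense(rng, cfg.final_layer_units, n_outputs)
        self._train_rng = np.random.default_rng(cfg.seed + 1)

    @property
    def params(self) -> List[nn.Tensor]:
        ps: List[nn.Tensor] = []
        for layer in self.layers:
            ps += layer.params
        if self.use_attention:
            ps += self.attn.params
        if self.side_dense is not None:
            ps += self.side_dense.params
        ps += self.final.params + self.out.params
        return ps

    def _forward(self, texts: Sequence[str],
                 side: Optional[np.ndarray]) -> nn.Tensor:
        xs, mask = _encode_batch(texts, self.emb, self.cfg.max_tokens)
        states = xs
        final = None
        for layer in self.layers:
            states, final = layer(states, mask)
        pooled = self.attn(states, mask) if self.use_attention else final
        if self.side_dense is not None:
            assert side is not None
            pooled = nn.concat_cols([pooled, self.side_dense(nn.constant(side))])
        return self.out(self.final(pooled))

    def fit(self, texts: Sequence[str], targets: np.ndarray,
            side: Optional[np.ndarray] = None) -> List[float]:
        """Minibatch Adam training on binary cross-entropy; returns the
        per-epoch mean losses."""
        n = len(texts)
        opt = nn.Adam(self.params, lr=self.cfg.learning_rate)
        history = []
        for _ in range(self.cfg.epochs):
            order = self._train_rng.permutation(n)
            losses = []
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start : start + self.cfg.batch_size]
                batch_texts = [texts[i] for i in idx]
                batch_side = side[idx] if side is not None else None
                logits = self._forward(batch_texts, batch_side)
                loss = nn.bce_with_logits(logits, targets[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        return history

    def predict_scores(self, texts: Sequence[str],
                       side: Optional[np.ndarray] = None,
                       batch_size: int = 256) -> np.ndarray:
        out = np.zeros((len(texts), self.n_outputs), dtype=np.float32)
        for start in range(0, len(texts), batch_size):
            chunk = list(texts[start : start + batch_size])
            if not chunk:
                continue
            s = side[start : start + batch_size] if side is not None else None
            logits = self._forward(chunk, s)
            out[start : start + len(chunk)] = 1.0 / (1.0 + np.exp(-logits.data))
        return out


# ---------------------------------------------------------------------------
# trained-model wrappers


def _corpus_sentences(records: Sequence[Record]) -> Tuple[List[str], List[str], np.ndarray]:
    ids, texts = [], []
    y = []
    for rec in records:
        for s in rec.sentences:
            ids.append(s.sentence_id)
            texts.append(s.text)
            y.append([1.0 if c in s.gold_labels else 0.0 for c in ALL_CRITERIA])
    return ids, texts, np.asarray(y, dtype=np.float32)


def _side_features(texts: Sequence[str], rs: RuleSet, vocab: Sequence[str]) -> np.ndarray:
    index = {t: i for i, t in enumerate(vocab)}
    out = np.zeros((len(texts), max(1, len(vocab))), dtype=np.float32)
    if not vocab:
        return out[:, :0]
    for row, text in enumerate(texts):
        for term in extract_lexicon_terms(text, rs):
            j = index.get(term)
            if j is not None:
                out[row, j] = 1.0
    return out


@dataclass
class BinaryFamily:
    """Seven per-criterion binary models sharing one config."""

    cfg: ModelConfig
    models: Dict[Criterion, SentenceNet]
    degenerate: Dict[Criterion, bool] = field(default_factory=dict)  # no positives seen

    @property
    def predictor_id(self) -> str:
        return f"{self.cfg.architecture}-{self.cfg.config_hash()}"


@dataclass
class HybridFamily(BinaryFamily):
    ruleset: Optional[RuleSet] = None
    term_vocab: Tuple[str, ...] = ()


@dataclass
class MultilabelModel:
    cfg: ModelConfig
    net: SentenceNet = None  # type: ignore[assignment]

    @property
    def predictor_id(self) -> str:
        return f"{self.cfg.architecture}-{self.cfg.config_hash()}"


TrainedModel = Union[BinaryFamily, HybridFamily, MultilabelModel]


def train_binary_per_criterion(
    train: Sequence[Record], cfg: ModelConfig, emb: EmbeddingProvider
) -> BinaryFamily:
    """Train one binary model per criterion on all sentences.

    A criterion with zero positive sentences is still trained (on the
    all-negative task) but flagged ``degenerate``; such a model assigns the
    label to no sentence.
    """
    _, texts, y = _corpus_sentences(train)
    models: Dict[Criterion, SentenceNet] = {}
    degenerate: Dict[Criterion, bool] = {}
    for ci, crit in enumerate(ALL_CRITERIA):
        sub = replace(cfg, architecture="binary_gru", seed=cfg.seed * 7 + ci)
        net = SentenceNet(sub, emb, n_outputs=1)
        target = y[:, ci : ci + 1]
        degenerate[crit] = float(target.sum()) == 0.0
        net.fit(texts, target)
        models[crit] = net
    return BinaryFamily(cfg=cfg, models=models, degenerate=degenerate)


def train_hybrid(
    train: Sequence[Record], cfg: ModelConfig, emb: EmbeddingProvider, rs: RuleSet
) -> HybridFamily:
    """Per-criterion BiLSTM models with the parser-term side channel.

    With an empty ruleset the side channel is empty and the model reduces
    to the text-only BiLSTM.
    """
    _, texts, y = _corpus_sentences(train)
    vocab = tuple(all_lexicon_terms(rs))
    side = _side_features(texts, rs, vocab)
    side_dim = side.shape[1]
    models: Dict[Criterion, SentenceNet] = {}
    degenerate: Dict[Criterion, bool] = {}
    for ci, crit in enumerate(ALL_CRITERIA):
        sub = replace(cfg, architecture="hybrid_lstm", seed=cfg.seed * 7 + ci)
        net = SentenceNet(sub, emb, n_outputs=1, side_dim=side_dim)
        target = y[:, ci : ci + 1]
        degenerate[crit] = float(target.sum()) == 0.0
        net.fit(texts, target, side=side)
        models[crit] = net
    return HybridFamily(
        cfg=cfg, models=models, degenerate=degenerate, ruleset=rs, term_vocab=vocab
    )


def train_multilabel(
    train: Sequence[Record], cfg: ModelConfig, emb: EmbeddingProvider
) -> MultilabelModel:
    """One BiLSTM emitting all seven criterion scores per sentence."""
    _, texts, y = _corpus_sentences(train)
    sub = replace(cfg, architecture="multilabel_lstm")
    net = SentenceNet(sub, emb, n_outputs=len(ALL_CRITERIA))
    net.fit(texts, y)
    return MultilabelModel(cfg=cfg, net=net)


def decide_labels(scores: np.ndarray, threshold: float) -> List[set]:
    """Apply the strict-greater-than threshold to a (N, 7) score matrix."""
    out = []
    for row in scores:
        out.append({c for c, s in zip(ALL_CRITERIA, row) if s > threshold})
    return out


def predict(model: TrainedModel, records: Sequence[Record]) -> PredictionSet:
    """Label every sentence of ``records``; deterministic given the model.

    predictor_id identifies the architecture plus a hash of its config.
    Unseen tokens are handled by the embedding provider's OOV convention,
    never an error.
    """
    ids: List[str] = []
    texts: List[str] = []
    for rec in records:
        for s in rec.sentences:
            ids.append(s.sentence_id)
            texts.append(s.text)
    pred = PredictionSet(predictor_id=model.predictor_id)
    if not ids:
        return pred
    if isinstance(model, MultilabelModel):
        scores = model.net.predict_scores(texts)
        label_sets = decide_labels(scores, model.cfg.threshold)
    else:
        side = None
        if isinstance(model, HybridFamily) and model.ruleset is not None:
            side = _side_features(texts, model.ruleset, model.term_vocab)
        cols = []
        for crit in ALL_CRITERIA:
            net = model.models[crit]
            s = net.predict_scores(texts, side=side if net.side_dense is not None else None)
            cols.append(s[:, 0])
        scores = np.stack(cols, axis=1)
        label_sets = decide_labels(scores, model.cfg.threshold)
    for sid, labels in zip(ids, label_sets):
        if labels:
            pred.labels_by_sentence[sid] = labels
    return pred


# ---------------------------------------------------------------------------
# persistence: npz weights + JSON sidecar with config/seeds/provenance


def _net_state(net: SentenceNet) -> List[np.ndarray]:
    return [p.data for p in net.params]


def _load_net_state(net: SentenceNet, arrays: List[np.ndarray]) -> None:
    params = net.params
    if len(params) != len(arrays):
        raise ValueError("checkpoint parameter count mismatch")
    for p, a in zip(params, arrays):
        if p.data.shape != a.shape:
            raise ValueError("checkpoint parameter shape mismatch")
        p.data = a.astype(np.float32)


def save_model(model: TrainedModel, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta: Dict[str, object] = {
        "config": asdict(model.cfg),
        "embedding": None,
        "kind": type(model).__name__,
    }
    arrays: Dict[str, np.ndarray] = {}
    if isinstance(model, MultilabelModel):
        meta["embedding"] = model.net.emb.provenance
        for i, a in enumerate(_net_state(model.net)):
            arrays[f"net/{i}"] = a
    else:
        meta["degenerate"] = {c.value: bool(v) for c, v in model.degenerate.items()}
        first = model.models[ALL_CRITERIA[0]]
        meta["embedding"] = first.emb.provenance
        if isinstance(model, HybridFamily):
            meta["term_vocab"] = list(model.term_vocab)
        for crit in ALL_CRITERIA:
            for i, a in enumerate(_net_state(model.models[crit])):
                arrays[f"{crit.value}/{i}"] = a
    np.savez(out_dir / "weights.npz", **arrays)
    (out_dir / "model.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def load_model(out_dir, ruleset: Optional[RuleSet] = None) -> TrainedModel:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "model.json").read_text(encoding="utf-8"))
    cfg = ModelConfig(**meta["config"])
    emb = embeddings_from_provenance(meta["embedding"])
    data = np.load(out_dir / "weights.npz")

    def group(prefix: str) -> List[np.ndarray]:
        keys = sorted(
            (k for k in data.files if k.startswith(prefix + "/")),
            key=lambda k: int(k.split("/")[1]),
        )
        return [data[k] for k in keys]

    if meta["kind"] == "MultilabelModel":
        net = SentenceNet(replace(cfg, architecture="multilabel_lstm"), emb,
                          n_outputs=len(ALL_CRITERIA))
        _load_net_state(net, group("net"))
        return MultilabelModel(cfg=cfg, net=net)

    degenerate = {Criterion(k): v for k, v in meta.get("degenerate", {}).items()}
    models: Dict[Criterion, SentenceNet] = {}
    if meta["kind"] == "HybridFamily":
        vocab = tuple(meta.get("term_vocab", []))
        side_dim = len(vocab)
        for ci, crit in enumerate(ALL_CRITERIA):
            sub = replace(cfg, architecture="hybrid_lstm", seed=cfg.seed * 7 + ci)
            net = SentenceNet(sub, emb, n_outputs=1, side_dim=side_dim)
            _load_net_state(net, group(crit.value))
            models[crit] = net
        return HybridFamily(cfg=cfg, models=models, degenerate=degenerate,
                            ruleset=ruleset, term_vocab=vocab)
    for ci, crit in enumerate(ALL_CRITERIA):
        sub = replace(cfg, architecture="binary_gru", seed=cfg.seed * 7 + ci)
        net = SentenceNet(sub, emb, n_outputs=1)
        _load_net_state(net, group(crit.value))
        models[crit] = net
    return BinaryFamily(cfg=cfg, models=models, degenerate=degenerate)
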