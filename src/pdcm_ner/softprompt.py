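"""Prompt-tuning for BIO token classification with a frozen backbone.

The trainable state is a short sequence of continuous "virtual token"
vectors prepended to the token-embedding sequence, plus a linear
classification head mapping backbone hidden states to BIO labels. The
backbone itself is never updated — its parameter fingerprint is bit-identical
before and after training, and every training test asserts this.

The backbone is abstracted behind :class:`BackboneAdapter`: anything that can
embed tokens, produce per-position hidden states (with a vector-Jacobian
product for training), look up word embeddings for label-based prompt
initialization, and fingerprint its frozen parameters. :class:`ToyBackbone`
is a small deterministic realization used by the test-suite and the examples;
a real LLM backbone plugs into the same contract.

Defaults follow the experimental configuration the toolkit targets: prompt
length 30, 50 training epochs, learning rate 0.001, prompt vectors
initialized from the embeddings of the entity-type names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .bio import LabelSet, Token, bio_to_spans
from .evaluation import MatchMode, micro_f1_spans
from .schema import EntitySchema

__all__ = [
    "BackboneAdapter",
    "ToyBackbone",
    "SoftPromptState",
    "init_soft_prompt",
    "train_soft_prompt",
    "predict_labels",
]

STATE_FORMAT_VERSION = 1


@runtime_checkable
class BackboneAdapter(Protocol):
    """Frozen language-model backbone contract."""

    embedding_dim: int
    hidden_dim: int

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        """(n, embedding_dim) embeddings for token surface strings."""
        ...

    def lookup(self, word: str) -> np.ndarray:
        """(embedding_dim,) embedding of a single vocabulary word."""
        ...

    def hidden_states(self, embeddings: np.ndarray) -> np.ndarray:
        """(L, hidden_dim) hidden vectors for an (L, embedding_dim) input."""
        ...

    def hidden_states_vjp(self, embeddings: np.ndarray, grad_hidden: np.ndarray) -> np.ndarray:
        """Backpropagate grad_hidden through hidden_states to the embeddings."""
        ...

    def fingerprint(self) -> str:
        """Digest of all backbone parameters; must never change."""
        ...


class ToyBackbone:
    """Deterministic miniature backbone: hashed embeddings + one mixing layer.

    Token embeddings come from a seeded table indexed by a stable hash of the
    token string. Hidden states mix each position's embedding with the causal
    mean of all embeddings up to that position (so prepended prompt vectors
    influence every downstream position), through a tanh layer:

        h_i = tanh(W1 e_i + W2 mean(e_0..e_i) + b)

    The context projection W2 is deliberately mild (``context_scale``) so
    token identity dominates each position while the prompt still shifts
    every hidden state. All parameters are fixed at construction; the class
    exposes the analytic vector-Jacobian product needed to train prompt
    vectors through it.
    """

    def __init__(self, embedding_dim: int = 32, hidden_dim: int = 128,
                 vocab_size: int = 4096, seed: int = 12345,
                 context_scale: float = 0.1) -> None:
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        self._E = rng.standard_normal((vocab_size, embedding_dim))
        self._W1 = rng.standard_normal((embedding_dim, hidden_dim)) / np.sqrt(embedding_dim)
        self._W2 = (
            context_scale
            * rng.standard_normal((embedding_dim, hidden_dim))
            / np.sqrt(embedding_dim)
        )
        self._b = rng.standard_normal(hidden_dim) * 0.01

    def _token_id(self, word: str) -> int:
        digest = hashlib.blake2b(word.encode("utf-8"), digest_size=8).digest()
        return int.from_bytes(digest, "big") % self.vocab_size

    def lookup(self, word: str) -> np.ndarray:
        return self._E[self._token_id(word)].copy()

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros((0, self.embedding_dim))
        return self._E[[self._token_id(t) for t in tokens]].copy()

    def hidden_states(self, embeddings: np.ndarray) -> np.ndarray:
        context = np.cumsum(embeddings, axis=0) / np.arange(1, len(embeddings) + 1)[:, None]
        pre = embeddings @ self._W1 + context @ self._W2 + self._b
        return np.tanh(pre)

    def hidden_states_vjp(self, embeddings: np.ndarray, grad_hidden: np.ndarray) -> np.ndarray:
        h = self.hidden_states(embeddings)
        dpre = grad_hidden * (1.0 - h * h)
        grad_e = dpre @ self._W1.T
        dcontext = dpre @ self._W2.T
        # context_i = mean(e_0..e_i): e_j receives sum_{i>=j} dcontext_i/(i+1)
        weighted = dcontext / np.arange(1, len(embeddings) + 1)[:, None]
        grad_e += np.cumsum(weighted[::-1], axis=0)[::-1]
        return grad_e

    def fingerprint(self) -> str:
        digest = hashlib.sha256()
        for arr in (self._E, self._W1, self._W2, self._b):
            digest.update(np.ascontiguousarray(arr).tobytes())
        return digest.hexdigest()


@dataclass
class SoftPromptState:
    """Trainable soft-prompt parameters plus training history."""

    prompt_vectors: np.ndarray  # (prompt_length, embedding_dim)
    head_weight: np.ndarray     # (hidden_dim, n_labels)
    head_bias: np.ndarray       # (n_labels,)
    seed: int
    hyperparameters: dict = field(
        default_factory=lambda: {"epochs": 50, "learning_rate": 0.001, "prompt_length": 30}
    )
    history: list[dict] = field(default_factory=list)

    @property
    def prompt_length(self) -> int:
        return len(self.prompt_vectors)

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": STATE_FORMAT_VERSION,
            "prompt_vectors": self.prompt_vectors.tolist(),
            "head_weight": self.head_weight.tolist(),
            "head_bias": self.head_bias.tolist(),
            "seed": self.seed,
            "hyperparameters": self.hyperparameters,
            "history": self.history,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SoftPromptState":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format_version") != STATE_FORMAT_VERSION:
            raise ValueError(f"unsupported state format {payload.get('format_version')!r}")
        return cls(
            prompt_vectors=np.asarray(payload["prompt_vectors"], dtype=float),
            head_weight=np.asarray(payload["head_weight"], dtype=float),
            head_bias=np.asarray(payload["head_bias"], dtype=float),
            seed=int(payload["seed"]),
            hyperparameters=dict(payload["hyperparameters"]),
            history=list(payload["history"]),
        )


def _name_embedding(backbone: BackboneAdapter, name: str) -> np.ndarray:
    """Embed an entity-type name; multi-piece names are averaged."""
    pieces = [p for p in name.split("_") if p]
    vectors = np.stack([backbone.lookup(p) for p in pieces])
    return vectors.mean(axis=0)


def init_soft_prompt(
    schema: EntitySchema,
    backbone: BackboneAdapter,
    prompt_length: int = 30,
    seed: int = 0,
    epochs: int = 50,
    learning_rate: float = 0.001,
) -> SoftPromptState:
    """Initialize prompt vectors from the entity-type-name embeddings.

    Vector ``i`` is the embedding of type name ``i mod k`` (k = number of
    types), so a length-30 prompt over the 15-type schema uses each type's
    embedding exactly twice. The classification head is seeded small-normal.
    """
    if prompt_length < 1:
        raise ValueError("prompt_length must be >= 1")
    labels = LabelSet.from_schema(schema)
    names = schema.names
    prompt = np.stack(
        [_name_embedding(backbone, names[i % len(names)]) for i in range(prompt_length)]
    )
    rng = np.random.default_rng(seed)
    head_weight = rng.standard_normal((backbone.hidden_dim, len(labels))) * 0.01
    head_bias = np.zeros(len(labels))
    return SoftPromptState(
        prompt_vectors=prompt,
        head_weight=head_weight,
        head_bias=head_bias,
        seed=seed,
        hyperparameters={
            "epochs": epochs,
            "learning_rate": learning_rate,
            "prompt_length": prompt_length,
        },
    )


def _forward_logits(
    backbone: BackboneAdapter, state: SoftPromptState, tokens: Sequence[Token]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (logits over real-token positions, full input X, hidden H)."""
    embeddings = backbone.embed_tokens([t.text for t in tokens])
    x = np.concatenate([state.prompt_vectors, embeddings], axis=0)
    h = backbone.hidden_states(x)
    logits = h[state.prompt_length :] @ state.head_weight + state.head_bias
    return logits, x, h


def predict_labels(
    backbone: BackboneAdapter,
    state: SoftPromptState,
    tokens: Sequence[Token],
    labels: LabelSet,
) -> list[str]:
    """Argmax label per real-token position (prompt positions are never
    classified); ties resolve to the lowest label index, i.e. ``O``."""
    if not tokens:
        return []
    logits, _, _ = _forward_logits(backbone, state, tokens)
    return [labels.labels[i] for i in np.argmax(logits, axis=1)]


def _dev_micro_f1(
    backbone: BackboneAdapter,
    state: SoftPromptState,
    dev_sentences: Sequence[tuple[Sequence[Token], Sequence[str]]],
    labels: LabelSet,
) -> float:
    gold_spans, pred_spans = [], []
    for tokens, gold in dev_sentences:
        pred = predict_labels(backbone, state, tokens, labels)
        gold_spans.append(bio_to_spans(tokens, gold))
        pred_spans.append(bio_to_spans(tokens, pred))
    return micro_f1_spans(gold_spans, pred_spans, MatchMode.EXACT)


def train_soft_prompt(
    backbone: BackboneAdapter,
    state: SoftPromptState,
    train_sentences: Sequence[tuple[Sequence[Token], Sequence[str]]],
    dev_sentences: Sequence[tuple[Sequence[Token], Sequence[str]]],
    labels: LabelSet,
) -> SoftPromptState:
    """Train prompt vectors and head by token-level cross-entropy (Adam).

    Per sentence, prompt vectors are prepended to the token embeddings, the
    frozen backbone produces hidden states, the head classifies each real
    token position, and the loss gradient flows back to prompt vectors and
    head only. History records per-epoch mean loss and dev micro-F1; the
    state with the best dev F1 is returned (falling back to the last epoch
    when there is no dev set).
    """
    if not train_sentences:
        raise ValueError("training set is empty")
    for tokens, labs in list(train_sentences) + list(dev_sentences):
        for lab in labs:
            if lab not in labels:
                raise ValueError(f"label {lab!r} not in label set")

    epochs = int(state.hyperparameters.get("epochs", 50))
    lr = float(state.hyperparameters.get("learning_rate", 0.001))
    fingerprint_before = backbone.fingerprint()

    params = [state.prompt_vectors, state.head_weight, state.head_bias]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    rng = np.random.default_rng(state.seed)
    label_index = {lab: i for i, lab in enumerate(labels.labels)}
    best_f1 = -1.0
    best_params: list[np.ndarray] | None = None
    order = np.arange(len(train_sentences))

    for epoch in range(epochs):
        rng.shuffle(order)
        losses = []
        for idx in order:
            tokens, labs = train_sentences[idx]
            if not tokens:
                continue
            logits, x, h = _forward_logits(backbone, state, tokens)
            y = np.array([label_index[l] for l in labs])
            # softmax cross-entropy over real-token positions
            shifted = logits - logits.max(axis=1, keepdims=True)
            expl = np.exp(shifted)
            probs = expl / expl.sum(axis=1, keepdims=True)
            n_tok = len(tokens)
            losses.append(float(-np.log(probs[np.arange(n_tok), y] + 1e-12).mean()))

            dlogits = probs.copy()
            dlogits[np.arange(n_tok), y] -= 1.0
            dlogits /= n_tok
            grad_w = h[state.prompt_length :].T @ dlogits
            grad_b = dlogits.sum(axis=0)
            grad_h = np.zeros_like(h)
            grad_h[state.prompt_length :] = dlogits @ state.head_weight.T
            grad_x = backbone.hidden_states_vjp(x, grad_h)
            grad_prompt = grad_x[: state.prompt_length]

            step += 1
            for p, g, m, v in zip(params, [grad_prompt, grad_w, grad_b], adam_m, adam_v):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                m_hat = m / (1 - beta1**step)
                v_hat = v / (1 - beta2**step)
                p -= lr * m_hat / (np.sqrt(v_hat) + eps)

        record = {"epoch": epoch, "loss": float(np.mean(losses)) if losses else 0.0}
        if dev_sentences:
            record["dev_f1"] = _dev_micro_f1(backbone, state, dev_sentences, labels)
            if record["dev_f1"] > best_f1:
                best_f1 = record["dev_f1"]
                best_params = [p.copy() for p in params]
        state.history.append(record)

    if best_params is not None:
        state.prompt_vectors, state.head_weight, state.head_bias = best_params

    if backbone.fingerprint() != fingerprint_before:
        raise RuntimeError("backbone parameters changed during training; contract violated")
    return state
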