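"""Temporal word embeddings from EEG-word contexts (CBOW, hierarchical
softmax).

Each word id is mapped to a d-dimensional vector (a row of the embedding
matrix A).  Training maximises the average log probability of each word
given its 2k surrounding words,

    L = (1/T) * sum_t log p(a_t | a_{t-k}, ..., a_{t+k}),

where the conditional is scored not by a flat softmax but by a binary
Huffman tree over the vocabulary: a word's probability is the product of
branch sigmoids along its root-to-leaf path, and the most frequent words
get the shortest paths.  Per update only the context rows of A and the
internal nodes on the target's path are touched, so a step costs
O(log vocab) instead of O(vocab).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .translation import EEGSentence


class VocabularyError(KeyError):
    """Raised when a word id has no leaf in the Huffman tree."""


# ---------------------------------------------------------------------------
# Huffman tree

@dataclass
class HuffmanTree:
    """Prefix-code binary tree over the vocabulary.

    codes[w] is the bit path (0 = lower-frequency branch first popped) and
    paths[w] the internal-node indices from the root to w's leaf.  With V
    leaves there are V-1 internal nodes, indexed 0..V-2.
    """

    codes: dict[int, list[int]]
    paths: dict[int, list[int]]
    n_internal: int

    @property
    def vocab(self) -> list[int]:
        return sorted(self.codes)

    def code_length(self, word: int) -> int:
        return len(self.codes[word])


def build_huffman(freqs: dict[int, float]) -> HuffmanTree:
    """Standard Huffman construction, deterministic via (freq, id) ordering.

    Ties between equal frequencies break toward the smaller word id
    (internal nodes order after all leaves), so the same frequency table
    always yields the same tree.
    """
    import heapq

    items = [(f, w) for w, f in freqs.items() if f > 0]
    if not items:
        raise ValueError("empty vocabulary: no word has positive frequency")
    if len(items) == 1:
        return HuffmanTree(codes={items[0][1]: []}, paths={items[0][1]: []}, n_internal=0)

    # heap entries: (freq, tiebreak, node); leaves carry their word id as
    # tiebreak, internal nodes order after leaves by creation time
    max_id = max(w for _, w in items)
    heap = [(float(f), w, ("leaf", w)) for f, w in items]
    heapq.heapify(heap)
    counter = max_id + 1
    while len(heap) > 1:
        f1, _, n1 = heapq.heappop(heap)
        f2, _, n2 = heapq.heappop(heap)
        heapq.heappush(heap, (f1 + f2, counter, ("node", n1, n2)))
        counter += 1
    root = heap[0][2]

    codes: dict[int, list[int]] = {}
    paths: dict[int, list[int]] = {}
    next_internal = [0]

    def walk(node, bits, internals):
        if node[0] == "leaf":
            codes[node[1]] = bits
            paths[node[1]] = internals
            return
        idx = next_internal[0]
        next_internal[0] += 1
        walk(node[1], bits + [0], internals + [idx])
        walk(node[2], bits + [1], internals + [idx])

    walk(root, [], [])
    return HuffmanTree(codes=codes, paths=paths, n_internal=next_internal[0])


# ---------------------------------------------------------------------------
# Model

@dataclass
class CBOWConfig:
    d: int = 26
    k: int = 2
    epochs: int = 10
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    min_count: int = 1
    integration: str = "average"  # or "concatenate"
    seed: int = 0

    def __post_init__(self):
        if self.d < 1 or self.k < 1:
            raise ValueError("d and k must be >= 1")
        if self.integration not in ("average", "concatenate"):
            raise ValueError(f"unknown integration {self.integration!r}")


@dataclass
class CBOWModel:
    embeddings: np.ndarray          # (vocab_size, d) — matrix A, one row per word
    node_vectors: np.ndarray        # (n_internal, dh) hierarchical-softmax params
    tree: HuffmanTree
    freqs: dict[int, int]
    config: CBOWConfig

    @property
    def vocab_size(self) -> int:
        return self.embeddings.shape[0]

    def word_vector(self, word: int) -> np.ndarray:
        if not 0 <= word < self.vocab_size:
            raise VocabularyError(f"word id {word} outside [0, {self.vocab_size})")
        return self.embeddings[word]

    def integrate(self, context: list[int]) -> np.ndarray:
        rows = self.embeddings[list(context)]
        if self.config.integration == "average":
            return rows.mean(axis=0)
        return rows.reshape(-1)

    # -- persistence: JSON header line, then A and node vectors as flat
    #    little-endian float64 blocks (tree rebuilt from the stored freqs).

    def save(self, path) -> None:
        header = {
            "kind": "cbow",
            "config": asdict(self.config),
            "vocab_size": self.vocab_size,
            "freqs": {str(k): v for k, v in self.freqs.items()},
            "shapes": [list(self.embeddings.shape), list(self.node_vectors.shape)],
        }
        with open(path, "wb") as fh:
            fh.write((json.dumps(header, sort_keys=True) + "\n").encode())
            fh.write(np.ascontiguousarray(self.embeddings, dtype="<f8").tobytes())
            fh.write(np.ascontiguousarray(self.node_vectors, dtype="<f8").tobytes())

    @classmethod
    def load(cls, path) -> "CBOWModel":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            if header.get("kind") != "cbow":
                raise ValueError(f"{path} is not a serialized embedding model")
            cfg = CBOWConfig(**header["config"])
            freqs = {int(k): v for k, v in header["freqs"].items()}
            (sa, sn) = header["shapes"]
            A = np.frombuffer(fh.read(int(np.prod(sa)) * 8), dtype="<f8").reshape(sa).copy()
            nv = np.frombuffer(fh.read(int(np.prod(sn)) * 8), dtype="<f8").reshape(sn).copy()
        return cls(embeddings=A, node_vectors=nv, tree=build_huffman(freqs),
                   freqs=freqs, config=cfg)


def export_embeddings(model: CBOWModel, path) -> None:
    """Plain text: a "vocab d" header line, then "word_id v1 ... vd" rows."""
    with open(path, "w") as fh:
        fh.write(f"{model.vocab_size} {model.config.d}\n")
        for w in range(model.vocab_size):
            vals = " ".join(f"{v:.8g}" for v in model.embeddings[w])
            fh.write(f"{w} {vals}\n")


# ---------------------------------------------------------------------------
# Scoring

def _log_sigmoid(x: float) -> float:
    return -np.logaddexp(0.0, -x)


def context_of(sentence: EEGSentence, t: int, k: int) -> list[int]:
    """The 2k ids around position t; only full-context positions are valid."""
    ids = sentence.word_ids if isinstance(sentence, EEGSentence) else list(sentence)
    if not k <= t <= len(ids) - 1 - k:
        raise IndexError(
            f"position {t} lacks a full +/-{k} context in a length-{len(ids)} sentence"
        )
    return ids[t - k : t] + ids[t + 1 : t + k + 1]


def hs_log_prob(model: CBOWModel, context: list[int], target: int) -> float:
    """log p(target | context) through the Huffman-tree softmax.

    Along the target's root-to-leaf path each internal node contributes
    log sigma(+/- <v_node, h>), the sign set by the branch direction; the
    per-branch probabilities are complementary, so the leaf probabilities
    sum to one over the vocabulary.
    """
    if target not in model.tree.codes:
        raise VocabularyError(f"word id {target} not in the trained vocabulary")
    h = model.integrate(context)
    logp = 0.0
    for node, bit in zip(model.tree.paths[target], model.tree.codes[target]):
        sign = 1.0 if bit else -1.0
        logp += _log_sigmoid(sign * float(model.node_vectors[node] @ h))
    return float(logp)


def hs_gradients(model: CBOWModel, context: list[int], target: int):
    """Exact gradients of log p(target|context) for one position.

    Returns (logp, grad_h, node_grads) where grad_h is d log p / d h and
    node_grads maps internal-node index -> gradient of its vector.  With
    average integration each context row of A receives grad_h / len(context).
    """
    if target not in model.tree.codes:
        raise VocabularyError(f"word id {target} not in the trained vocabulary")
    h = model.integrate(context)
    grad_h = np.zeros_like(h)
    node_grads: dict[int, np.ndarray] = {}
    logp = 0.0
    for node, bit in zip(model.tree.paths[target], model.tree.codes[target]):
        v = model.node_vectors[node]
        sign = 1.0 if bit else -1.0
        s = sign * float(v @ h)
        logp += _log_sigmoid(s)
        coef = sign * (1.0 - 1.0 / (1.0 + np.exp(-s)))  # d log sigma(s) / ds
        grad_h += coef * v
        node_grads[node] = node_grads.get(node, 0.0) + coef * h
    return float(logp), grad_h, node_grads


def cbow_objective(model: CBOWModel, sentences: list[EEGSentence], k: int | None = None) -> float:
    """Average log probability over all full-context positions (<= 0)."""
    k = model.config.k if k is None else k
    total, count = 0.0, 0
    for sent in sentences:
        ids = sent.word_ids
        for t in range(k, len(ids) - k):
            if ids[t] not in model.tree.codes:
                continue
            total += hs_log_prob(model, context_of(sent, t, k), ids[t])
            count += 1
    if count == 0:
        warnings.warn("no full-context positions; objective defined as 0")
        return 0.0
    return total / count


# ---------------------------------------------------------------------------
# Training

def count_frequencies(sentences: list[EEGSentence]) -> dict[int, int]:
    freqs: dict[int, int] = {}
    for sent in sentences:
        for w in sent.word_ids:
            freqs[w] = freqs.get(w, 0) + 1
    return freqs


def train_cbow(
    sentences: list[EEGSentence],
    config: CBOWConfig,
    vocab_size: int | None = None,
) -> CBOWModel:
    """Stochastic gradient ascent on the context objective.

    `vocab_size` fixes the number of embedding rows (default: max observed
    id + 1) so every word id resolves to a vector downstream even if it
    was never sampled.  Words rarer than min_count keep their seeded init
    row and are skipped as prediction targets.  Deterministic per seed.
    """
    freqs = count_frequencies(sentences)
    if not freqs:
        raise ValueError("empty corpus")
    if sum(freqs.values()) < 2 * config.k + 1:
        raise ValueError(
            f"corpus of {sum(freqs.values())} tokens cannot fill a 2k+1="
            f"{2 * config.k + 1} window"
        )
    if vocab_size is None:
        vocab_size = max(freqs) + 1
    if max(freqs) >= vocab_size:
        raise VocabularyError(f"word id {max(freqs)} >= vocab_size {vocab_size}")

    kept = {w: f for w, f in freqs.items() if f >= config.min_count}
    if not kept:
        raise ValueError("min_count removed the entire vocabulary")
    tree = build_huffman(kept)

    rng = np.random.default_rng(config.seed)
    dh = config.d if config.integration == "average" else 2 * config.k * config.d
    model = CBOWModel(
        embeddings=(rng.random((vocab_size, config.d)) - 0.5) / config.d,
        node_vectors=np.zeros((tree.n_internal, dh)),
        tree=tree,
        freqs=freqs,
        config=config,
    )

    positions = [
        (si, t)
        for si, sent in enumerate(sentences)
        for t in range(config.k, len(sent.word_ids) - config.k)
        if sent.word_ids[t] in tree.codes
    ]
    if not positions:
        warnings.warn("no trainable positions; returning initialized model")
        return model

    total_steps = config.epochs * len(positions)
    step = 0
    for _ in range(config.epochs):
        for si, t in positions:
            lr = max(
                config.min_learning_rate,
                config.learning_rate * (1.0 - step / total_steps),
            )
            sent = sentences[si]
            ctx = context_of(sent, t, config.k)
            _, grad_h, node_grads = hs_gradients(model, ctx, sent.word_ids[t])
            for node, g in node_grads.items():
                model.node_vectors[node] += lr * g
            if config.integration == "average":
                upd = lr * grad_h / len(ctx)
                for w in ctx:
                    model.embeddings[w] += upd
            else:
                d = config.d
                for j, w in enumerate(ctx):
                    model.embeddings[w] += lr * grad_h[j * d : (j + 1) * d]
            step += 1
    return model
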