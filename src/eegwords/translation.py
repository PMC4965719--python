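"""Translate fragment sequences into discrete "EEG word" sentences.

Each of the M top-layer hidden units of the trained autoencoder decodes to
one basic waveform — an EEG word; the dictionary is the set of all M.  A
fragment's top-layer activation h is normalized into the multinomial
P(word i) = h_i / sum_j h_j and the fragment is sampled (or argmax-read)
to a single word id, so a continuous record becomes a sentence of ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sae import SAEModel, fragment_features
from .segmentation import FragmentPool


@dataclass
class EEGDictionary:
    """The M decoded basis waveforms, one per top-layer hidden unit."""

    words: np.ndarray  # (M, input_dim), values in (0, 1)

    def __len__(self) -> int:
        return self.words.shape[0]


@dataclass
class EEGSentence:
    """Ordered word ids for one record's fragments, with their start times."""

    word_ids: list[int]
    start_times: list[float] = field(default_factory=list)
    record_id: str = ""

    def __len__(self) -> int:
        return len(self.word_ids)

    def __iter__(self):
        return iter(self.word_ids)


def build_dictionary(model: SAEModel) -> EEGDictionary:
    """Decode each hidden unit in isolation: word i = decode(one-hot_i)."""
    m = model.config.n_words
    return EEGDictionary(words=model.decode(np.eye(m)))


def word_distribution(h) -> np.ndarray:
    """Normalize nonnegative activations into the word multinomial."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("activations must be nonnegative")
    total = h.sum()
    if total <= 0:
        raise ValueError("all-zero activation vector cannot be normalized")
    return h / total


def sample_word(dist, rng: np.random.Generator | None = None, mode: str = "sample") -> int:
    """Draw one word id from the multinomial, or take the argmax.

    argmax ties break toward the lowest id (np.argmax convention), making
    the argmax path a pure function of the distribution.
    """
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
        raise ValueError("not a probability distribution")
    if mode == "argmax":
        return int(np.argmax(dist))
    if mode == "sample":
        if rng is None:
            raise ValueError("sample mode requires an rng")
        return int(rng.choice(len(dist), p=dist / dist.sum()))
    raise ValueError(f"unknown mode {mode!r}")


def translate(
    pool: FragmentPool,
    model: SAEModel,
    rng: np.random.Generator | None = None,
    mode: str = "sample",
) -> list[EEGSentence]:
    """Translate a fragment pool into one sentence per record.

    Per fragment: encode each channel, average the top-layer codes over
    channels, normalize into the word multinomial, and draw a word id.
    Sentence order follows fragment time order within each record.
    """
    if len(pool) == 0:
        return []
    feats = fragment_features(model, pool)
    sentences: dict[str, EEGSentence] = {}
    for i, frag in enumerate(pool):
        if frag.record_id not in sentences:
            sentences[frag.record_id] = EEGSentence([], [], frag.record_id)
        try:
            wid = sample_word(word_distribution(feats[i]), rng=rng, mode=mode)
        except ValueError as exc:
            raise ValueError(f"fragment {i} (record {frag.record_id!r}, "
                             f"t={frag.start_s}s): {exc}") from exc
        sent = sentences[frag.record_id]
        sent.word_ids.append(wid)
        sent.start_times.append(frag.start_s)
    return list(sentences.values())


def write_corpus(sentences: list[EEGSentence], path) -> None:
    """One record per line, whitespace-separated integer tokens."""
    lines = [" ".join(str(w) for w in s.word_ids) for s in sentences]
    Path(path).write_text("\n".join(lines) + "\n")


def read_corpus(path) -> list[EEGSentence]:
    sentences = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if line.strip():
            sentences.append(EEGSentence([int(t) for t in line.split()], record_id=str(i)))
    return sentences


def concentration(dist, mass: float = 0.9) -> int:
    """Number of words holding the top `mass` of probability — small on a
    sparsity-trained model, where most activations sit near zero."""
    p = np.sort(np.asarray(dist))[::-1]
    return int(np.searchsorted(np.cumsum(p), mass) + 1)
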