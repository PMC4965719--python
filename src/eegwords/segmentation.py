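"""Sliding-window segmentation of EEG records into fixed-length fragments.

A record of duration D seconds cut with a window of L seconds sliding by
`step` seconds yields floor((D - L)/step) + 1 fragments; windows never
cross the record boundary.  Fragments are min-max normalized per channel
into [0, 1] before they feed the sigmoid autoencoder, and labeled
seizure / non-seizure from the annotated intervals by fractional overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .records import EEGRecord, SeizureAnnotation

LABEL_SEIZURE = "seizure"
LABEL_NON_SEIZURE = "non_seizure"
LABEL_UNLABELED = "unlabeled"


class DataError(ValueError):
    """Raised on non-finite samples or otherwise unusable signal data."""


@dataclass
class EEGFragment:
    """One windowed epoch: a channels x round(L*fs) slice of a record."""

    values: np.ndarray
    start_s: float
    label: str = LABEL_UNLABELED
    record_id: str = ""
    window_s: float = 0.0
    normalized: bool = False

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def end_s(self) -> float:
        return self.start_s + self.window_s


@dataclass
class FragmentPool:
    """Ordered collection of fragments produced by one segmentation pass."""

    fragments: list[EEGFragment] = field(default_factory=list)
    window_s: float = 3.0
    step_s: float = 1.0

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __getitem__(self, i):
        return self.fragments[i]

    def labels(self) -> list[str]:
        return [f.label for f in self.fragments]

    def record_ids(self) -> list[str]:
        seen: list[str] = []
        for f in self.fragments:
            if f.record_id not in seen:
                seen.append(f.record_id)
        return seen


def fragment_count(duration_s: float, window_s: float, step_s: float) -> int:
    """Number of full windows that fit: floor((D - L)/step) + 1."""
    if duration_s < window_s:
        return 0
    # guard the floor against float fuzz at exact multiples
    return int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1


def segment_record(
    record: EEGRecord,
    window_s: float = 3.0,
    step_s: float = 1.0,
    channels: Iterable[int] | None = None,
) -> FragmentPool:
    """Cut `record` into overlapping raw (unnormalized) fragments.

    `channels` optionally selects a subset of channel indices.  A window
    longer than the record produces an empty pool with a warning rather
    than an error, so batch processing over mixed-length records degrades
    gracefully.
    """
    if step_s <= 0:
        raise ValueError(f"step_s must be positive, got {step_s}")
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    data = record.data if channels is None else record.data[list(channels)]
    n = fragment_count(record.duration_s, window_s, step_s)
    if n == 0:
        warnings.warn(
            f"window {window_s}s longer than record "
            f"{record.subject_id!r} ({record.duration_s:.2f}s); empty pool"
        )
    win = int(round(window_s * record.fs))
    frags = []
    for i in range(n):
        start_s = i * step_s
        s0 = int(round(start_s * record.fs))
        frags.append(
            EEGFragment(
                values=data[:, s0 : s0 + win].copy(),
                start_s=start_s,
                record_id=record.subject_id,
                window_s=window_s,
            )
        )
    return FragmentPool(fragments=frags, window_s=window_s, step_s=step_s)


def normalize_fragment(fragment: EEGFragment) -> EEGFragment:
    """Min-max scale each channel into [0, 1]; constant channels map to 0.5.

    Per-channel, per-fragment scaling removes inter-subject amplitude
    offsets and puts targets in the range the sigmoid decoder and
    cross-entropy loss require.  Idempotent on normalized fragments.
    """
    x = np.asarray(fragment.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError(f"fragment at {fragment.start_s}s contains NaN/inf samples")
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.empty_like(x)
    flat = (span == 0).ravel()
    out[flat] = 0.5
    nz = ~flat
    out[nz] = (x[nz] - lo[nz]) / span[nz]
    return replace(fragment, values=out, normalized=True)


def _overlap_fraction(start_s: float, end_s: float, annotations) -> float:
    length = end_s - start_s
    if length <= 0:
        return 0.0
    covered = 0.0
    for ann in annotations:
        covered += max(0.0, min(end_s, ann.end_s) - max(start_s, ann.start_s))
    return covered / length


def label_fragment(
    fragment: EEGFragment,
    annotations: list[SeizureAnnotation],
    overlap_threshold: float = 0.5,
) -> str:
    """Seizure iff the fraction of [start, start+L) inside annotated
    seizure time reaches `overlap_threshold` (default 0.5)."""
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    frac = _overlap_fraction(fragment.start_s, fragment.end_s, annotations)
    return LABEL_SEIZURE if frac >= overlap_threshold else LABEL_NON_SEIZURE


def label_pool(
    pool: FragmentPool,
    annotations_by_record: dict[str, list[SeizureAnnotation]],
    overlap_threshold: float = 0.5,
) -> FragmentPool:
    """Label every fragment in place from its record's annotations."""
    for frag in pool:
        anns = annotations_by_record.get(frag.record_id, [])
        frag.label = label_fragment(frag, anns, overlap_threshold)
    return pool


def normalize_pool(pool: FragmentPool) -> FragmentPool:
    """Normalized copy of every fragment, preserving pool structure."""
    return FragmentPool(
        fragments=[normalize_fragment(f) for f in pool],
        window_s=pool.window_s,
        step_s=pool.step_s,
    )
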