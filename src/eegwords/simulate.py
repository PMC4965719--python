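"""Seeded synthetic scalp-EEG generator with annotated seizure events.

Background activity per channel is band-limited noise plus alpha-band
sinusoids; seizure intervals replace it with a high-amplitude 3 Hz
spike-and-wave complex (fundamental plus decaying harmonics) scaled so the
ictal RMS exceeds the background RMS by a configurable gain.  A cohort
generator jitters the spectral parameters multiplicatively per subject,
mimicking the cross-patient variability that makes non-patient-specific
detection hard.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .records import EEGRecord, SeizureAnnotation


class SimulationError(ValueError):
    """Raised when the requested seizures cannot be packed into the record."""


@dataclass
class SimConfig:
    fs: float = 256.0
    n_channels: int = 23
    duration_s: float = 3600.0
    n_seizures: int = 1
    seizure_len_range_s: tuple[float, float] = (30.0, 100.0)
    # background: list of (frequency Hz, amplitude uV) sinusoid peaks
    background_peaks: list[tuple[float, float]] = field(
        default_factory=lambda: [(10.0, 20.0)]
    )
    noise_sd: float = 8.0            # uV, band-limited background noise
    seizure_freq: float = 3.0        # Hz, spike-and-wave fundamental
    seizure_gain: float = 6.0        # ictal RMS / background RMS
    seizure_noise_frac: float = 1.0  # in-seizure noise, fraction of background RMS
    subject_jitter_sd: float = 0.25  # multiplicative parameter jitter
    seed: int = 0
    subject_id: str = "sim01"


def _spike_wave(t: np.ndarray, freq: float, phase: float) -> np.ndarray:
    """Unit-RMS spike-and-wave: fundamental plus 1/m-weighted harmonics."""
    w = np.zeros_like(t)
    for m in range(1, 5):
        w += np.sin(2.0 * np.pi * freq * m * t + phase * m) / m
    rms = np.sqrt(np.mean(w**2))
    return w / rms if rms > 0 else w


def _place_seizures(cfg: SimConfig, rng: np.random.Generator) -> list[SeizureAnnotation]:
    if cfg.n_seizures == 0:
        return []
    lo, hi = cfg.seizure_len_range_s
    lengths = [float(np.round(rng.uniform(lo, hi))) for _ in range(cfg.n_seizures)]
    margin = 5.0  # seconds of background guaranteed around each event
    needed = sum(lengths) + margin * (cfg.n_seizures + 1)
    if needed > cfg.duration_s:
        raise SimulationError(
            f"{cfg.n_seizures} seizures of total {sum(lengths):.0f}s do not fit "
            f"in a {cfg.duration_s:.0f}s record"
        )
    free = cfg.duration_s - needed
    gaps = rng.dirichlet(np.ones(cfg.n_seizures + 1)) * free
    anns, cursor = [], 0.0
    for i, length in enumerate(lengths):
        cursor += gaps[i] + margin
        start = float(np.round(cursor))
        anns.append(SeizureAnnotation(start, start + length))
        cursor = start + length
    return anns


def simulate_record(config: SimConfig) -> EEGRecord:
    """Generate one annotated multichannel record from the config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    anns = _place_seizures(cfg, rng)

    data = np.empty((cfg.n_channels, n))
    nyq = cfg.fs / 2.0
    b, a = butter(4, min(40.0, 0.9 * nyq) / nyq, btype="low")
    for ch in range(cfg.n_channels):
        x = filtfilt(b, a, rng.standard_normal(n)) * cfg.noise_sd * 2.0
        for freq, amp in cfg.background_peaks:
            x += amp * np.sin(2.0 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        sigma = float(np.sqrt(np.mean(x**2)))
        for ann in anns:
            s0, s1 = int(round(ann.start_s * cfg.fs)), int(round(ann.end_s * cfg.fs))
            seg_t = t[s0:s1]
            wave = _spike_wave(seg_t, cfg.seizure_freq, rng.uniform(0, 2 * np.pi))
            x[s0:s1] = (
                cfg.seizure_gain * sigma * wave
                + cfg.seizure_noise_frac * sigma * rng.standard_normal(s1 - s0)
            )
        data[ch] = x
    return EEGRecord(
        data=data,
        fs=cfg.fs,
        channel_labels=[f"CH{c+1:02d}" for c in range(cfg.n_channels)],
        annotations=anns,
        subject_id=cfg.subject_id,
    )


def cohort_configs(n_subjects: int, base: SimConfig) -> list[SimConfig]:
    """Per-subject configs with multiplicatively jittered spectral params.

    Each parameter p becomes p * (1 + jitter_sd * z) with z standard
    normal, clipped to stay positive; subject seeds derive from the base
    seed so the whole cohort is reproducible.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    configs = []
    ss = np.random.SeedSequence(base.seed)
    children = ss.spawn(n_subjects)
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)

        def jit(v, r=rng):
            return float(max(v * (1.0 + base.subject_jitter_sd * r.standard_normal()),
                             0.05 * v))

        configs.append(
            replace(
                base,
                seizure_freq=jit(base.seizure_freq),
                seizure_gain=jit(base.seizure_gain),
                background_peaks=[(jit(f), jit(amp)) for f, amp in base.background_peaks],
                noise_sd=jit(base.noise_sd),
                seed=int(child.generate_state(1)[0] % (2**31)),
                subject_id=f"subj{s+1:02d}",
            )
        )
    return configs


def simulate_cohort(n_subjects: int, base_config: SimConfig) -> list[EEGRecord]:
    """Generate a cohort of records, one per jittered subject config."""
    return [simulate_record(cfg) for cfg in cohort_configs(n_subjects, base_config)]
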