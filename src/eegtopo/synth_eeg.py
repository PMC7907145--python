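"""Synthetic two-class EEG cohorts with controllable class differences.

Each channel is a sum of one band-limited oscillation per theta/alpha/beta
band (random in-band frequency and phase) over a 1/f "pink" background.
Class 1 ("patient") recordings additionally receive broadband white noise
scaled by ``complexity_effect`` and a multiplicative theta amplitude factor
``theta_power_effect``, both weighted by a frontal-dominant spatial profile,
so that downstream complexity (fuzzy entropy) and band-power features carry
a recoverable, frontally localized group difference.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from eegtopo.montage_layout import DEFAULT_60_LABELS

__all__ = [
    "SynthConfig",
    "Recording",
    "default_frontal_weights",
    "generate_recording",
    "generate_cohort",
]

# (f_lo, f_hi, amplitude) of the per-band oscillations.  Amplitudes are
# deliberately modest relative to the broadband admixture so that a unit
# complexity_effect produces a clearly recoverable in-band complexity shift.
_OSCILLATIONS = {
    "theta": (4.0, 7.0, 0.4),
    "alpha": (8.0, 13.0, 0.4),
    "beta": (14.0, 30.0, 0.1),
}


def default_frontal_weights(labels: Sequence[str]) -> Dict[str, float]:
    """Frontal-dominant effect profile: F*/Fp*/AF* -> 1.0, central/temporal -> 0.4,
    everything else (parietal/occipital/ocular) -> 0.1."""
    weights = {}
    for lab in labels:
        u = lab.upper()
        if u.startswith(("FP", "AF", "F")):
            weights[lab] = 1.0
        elif u.startswith(("C", "T")):
            weights[lab] = 0.4
        else:
            weights[lab] = 0.1
    return weights


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic cohort; the cohort is a pure function of this."""

    n_subjects_per_class: int
    trials_per_subject: int = 55
    trial_duration: float = 1.4
    sampling_rate: float = 500.0
    channel_labels: Tuple[str, ...] = DEFAULT_60_LABELS
    complexity_effect: float = 0.0
    theta_power_effect: float = 1.0
    frontal_weight: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class <= 0:
            raise ValueError("n_subjects_per_class must be > 0")
        if self.trials_per_subject <= 0:
            raise ValueError("trials_per_subject must be > 0")
        if self.trial_duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("trial_duration and sampling_rate must be > 0")
        n_samp = self.trial_duration * self.sampling_rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("trial_duration * sampling_rate must be an integer")
        if len(self.channel_labels) == 0:
            raise ValueError("need at least one channel")
        if self.complexity_effect < 0:
            raise ValueError("complexity_effect must be >= 0")
        if self.theta_power_effect <= 0:
            raise ValueError("theta_power_effect must be > 0")
        if self.frontal_weight is not None:
            missing = [c for c in self.channel_labels if c not in self.frontal_weight]
            if missing:
                raise ValueError(f"frontal_weight missing channels: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    def resolved_weights(self) -> Dict[str, float]:
        if self.frontal_weight is not None:
            return dict(self.frontal_weight)
        return default_frontal_weights(self.channel_labels)


@dataclass
class Recording:
    """One subject's EEG: a channels x samples matrix with metadata."""

    subject_id: str
    label: int
    channel_labels: List[str]
    sampling_rate: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _subject_rng(seed: int, subject_id: str, label: int) -> np.random.Generator:
    # crc32 keeps the per-subject stream independent of PYTHONHASHSEED
    key = zlib.crc32(f"{subject_id}|{label}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f noise via spectral shaping of white noise, unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def generate_recording(cfg: SynthConfig, subject_id: str, label: int) -> Recording:
    """Deterministically synthesize one subject's continuous recording.

    The recording spans ``trials_per_subject * trial_duration`` seconds so the
    default segmentation yields exactly the configured number of trials.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    rng = _subject_rng(cfg.seed, subject_id, label)
    n = cfg.samples_per_trial * cfg.trials_per_subject
    t = np.arange(n) / cfg.sampling_rate
    weights = cfg.resolved_weights()

    data = np.empty((cfg.n_channels, n))
    for ci, ch in enumerate(cfg.channel_labels):
        w = weights[ch]
        x = _pink_noise(rng, n)
        for band, (f_lo, f_hi, amp) in _OSCILLATIONS.items():
            freq = rng.uniform(f_lo, f_hi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            if band == "theta" and label == 1:
                amp = amp * cfg.theta_power_effect**w
            x = x + amp * np.sin(2.0 * np.pi * freq * t + phase)
        if label == 1:
            x = x + cfg.complexity_effect * w * rng.standard_normal(n)
        else:
            # consume the same number of draws so class 0/1 streams stay aligned
            rng.standard_normal(n)
        data[ci] = x
    return Recording(
        subject_id=subject_id,
        label=label,
        channel_labels=list(cfg.channel_labels),
        sampling_rate=cfg.sampling_rate,
        data=data,
    )


def generate_cohort(cfg: SynthConfig) -> List[Recording]:
    """Balanced cohort of ``2 * n_subjects_per_class`` recordings (controls first)."""
    recs = []
    for label, prefix in ((0, "C"), (1, "P")):
        for i in range(cfg.n_subjects_per_class):
            recs.append(generate_recording(cfg, f"{prefix}{i:03d}", label))
    return recs
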