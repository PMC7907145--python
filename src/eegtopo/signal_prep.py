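"""Channel pruning, trial segmentation, sliding windows, band decomposition.

Band filters are zero-phase 4th-order Butterworth bandpasses applied
forward-backward (``sosfiltfilt``), so windows keep their temporal alignment
across bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as sps

from eegtopo.synth_eeg import Recording

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BROADBAND",
    "Trial",
    "Window",
    "remove_channels",
    "segment_trials",
    "sliding_windows",
    "bandpass",
]

_FILTER_ORDER = 4


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges ({self.f_lo}, {self.f_hi})")

    def validate_for(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.f_hi} Hz >= Nyquist ({fs / 2} Hz)"
            )


DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
)

#: broadband prefilter applied to raw recordings
BROADBAND = BandDefinition("broadband", 0.5, 50.0)


@dataclass
class Trial:
    recording_id: str
    trial_index: int
    data: np.ndarray  # channels x samples
    sampling_rate: float
    label: Optional[int] = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Window:
    trial_ref: str
    window_index: int
    data: np.ndarray  # channels x samples
    sampling_rate: float


def remove_channels(rec: Recording, drop_labels: Sequence[str]) -> Recording:
    """Drop the named channels, preserving the order of the rest.

    Labels absent from the recording produce a ``UserWarning`` rather than an
    error, so montages without e.g. ocular channels pass through untouched.
    """
    drop = set(drop_labels)
    missing = sorted(drop - set(rec.channel_labels))
    if missing:
        warnings.warn(f"channels not present, ignored: {missing}", UserWarning, stacklevel=2)
    keep = [i for i, lab in enumerate(rec.channel_labels) if lab not in drop]
    if not keep:
        raise ValueError("removing these channels would leave an empty recording")
    return Recording(
        subject_id=rec.subject_id,
        label=rec.label,
        channel_labels=[rec.channel_labels[i] for i in keep],
        sampling_rate=rec.sampling_rate,
        data=rec.data[keep],
    )


def segment_trials(
    rec: Recording, trial_length: float = 1.4, max_trials: Optional[int] = None
) -> List[Trial]:
    """Cut consecutive non-overlapping trials from t = 0, truncated to ``max_trials``."""
    n_trial = int(round(trial_length * rec.sampling_rate))
    if n_trial <= 0:
        raise ValueError("trial_length must be positive")
    if rec.n_samples < n_trial:
        raise ValueError(
            f"recording of {rec.duration:.3f}s shorter than one {trial_length}s trial"
        )
    count = rec.n_samples // n_trial
    if max_trials is not None:
        count = min(count, max_trials)
    return [
        Trial(
            recording_id=rec.subject_id,
            trial_index=k,
            data=rec.data[:, k * n_trial : (k + 1) * n_trial].copy(),
            sampling_rate=rec.sampling_rate,
            label=rec.label,
        )
        for k in range(count)
    ]


def sliding_windows(trial: Trial, window: float = 0.4, step: float = 0.2) -> List[Window]:
    """Overlapping windows starting at t = 0; count = floor((T - w)/s) + 1."""
    if step <= 0:
        raise ValueError("step must be positive")
    n_win = int(round(window * trial.sampling_rate))
    n_step = int(round(step * trial.sampling_rate))
    if n_win <= 0 or n_step <= 0:
        raise ValueError("window and step must span at least one sample")
    if n_win > trial.n_samples:
        raise ValueError(
            f"window of {window}s longer than trial of {trial.duration:.3f}s"
        )
    count = (trial.n_samples - n_win) // n_step + 1
    ref = f"{trial.recording_id}/t{trial.trial_index}"
    return [
        Window(
            trial_ref=ref,
            window_index=k,
            data=trial.data[:, k * n_step : k * n_step + n_win],
            sampling_rate=trial.sampling_rate,
        )
        for k in range(count)
    ]


@lru_cache(maxsize=64)
def _design(f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    return sps.butter(_FILTER_ORDER, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis; same length out."""
    band.validate_for(fs)
    x = np.asarray(x, dtype=np.float64)
    sos = _design(band.f_lo, band.f_hi, fs)
    return sps.sosfiltfilt(sos, x, axis=-1)
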