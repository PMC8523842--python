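"""Core data containers: epoched EEG, stimulus specifications, the montage.

The default montage covers sensorimotor and occipital cortex with fifteen
electrodes; the first eleven (fronto-central/central/centro-parietal) carry
the motor-imagery signal, the last four (parieto-occipital/occipital) carry
the SSVEP response.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Default 15-electrode montage, in fixed order. Indices 0-10 form the motor
#: block, indices 11-14 the occipital block.
MONTAGE: tuple[str, ...] = (
    "FC3", "FC4", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "CP3", "CP4",
    "POz", "O1", "Oz", "O2",
)

#: 0-based channel indices of the two blocks of the default montage.
MOTOR_BLOCK: tuple[int, ...] = tuple(range(0, 11))
OCCIPITAL_BLOCK: tuple[int, ...] = tuple(range(11, 15))


@dataclass
class EpochSet:
    """A set of labelled EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial time series (arbitrary amplitude units).
    labels : ndarray, shape (n_trials,)
        Integer class label per trial.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
        Electrode names in channel order.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = field(default=MONTAGE)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} trials"
            )
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} data channels"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def select_channels(self, indices: Sequence[int]) -> "EpochSet":
        """Return a new EpochSet restricted to the given channel indices."""
        idx = np.asarray(indices, dtype=int)
        return EpochSet(
            data=self.data[:, idx, :],
            labels=self.labels,
            fs=self.fs,
            channel_names=tuple(self.channel_names[i] for i in idx),
        )

    def select_mask(self, mask: np.ndarray) -> "EpochSet":
        """Restrict to the channels where the binary mask is 1."""
        mask = np.asarray(mask)
        if mask.shape != (self.n_channels,):
            raise ValueError(
                f"mask length {mask.shape} does not match {self.n_channels} channels"
            )
        return self.select_channels(np.flatnonzero(mask))


@dataclass(frozen=True)
class StimulusSpec:
    """SSVEP stimulation setup: flicker frequencies and harmonics per reference.

    Each stimulus frequency f contributes sine/cosine reference pairs at
    f, 2f, ..., n_harmonics*f (a truncated Fourier series).
    """

    frequencies: tuple[float, ...]
    n_harmonics: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
        if len(set(self.frequencies)) != len(self.frequencies):
            raise ValueError(f"stimulus frequencies must be distinct: {self.frequencies}")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("stimulus frequencies must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")

    def check_nyquist(self, fs: float) -> None:
        top = max(self.frequencies) * self.n_harmonics
        if top >= fs / 2:
            raise ValueError(
                f"highest harmonic {top} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


def mask_from_names(names: Sequence[str], montage: Sequence[str] = MONTAGE) -> np.ndarray:
    """Build a binary channel mask selecting the named electrodes."""
    montage = list(montage)
    mask = np.zeros(len(montage), dtype=np.uint8)
    unknown = [n for n in names if n not in montage]
    if unknown:
        raise ValueError(f"unknown channel names: {unknown}")
    for n in names:
        mask[montage.index(n)] = 1
    return mask


def names_from_mask(mask: np.ndarray, montage: Sequence[str] = MONTAGE) -> list[str]:
    """Electrode names selected by a binary mask, in montage order."""
    return [montage[i] for i in np.flatnonzero(mask)]
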