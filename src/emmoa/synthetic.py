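"""Synthetic hybrid-EEG generator with known informative channels.

Motor imagery is modelled as event-related desynchronization (ERD): a mu
rhythm (~10 Hz) rides on the motor electrodes of both hemispheres, and the
hemisphere contralateral to the imagined hand attenuates it. Left-hand
imagery (label 0) suppresses the right-hemisphere channel (C4 by default),
right-hand imagery (label 1) the left (C3). The SSVEP response is a
sinusoid at the attended flicker frequency plus harmonics, confined to the
occipital electrodes. Both ride on 1/f background noise on every channel,
so the motor-imagery band-pass has a realistic spectral effect.

None of this models volume conduction, eye/muscle artifacts, or
non-stationarity; it plants a ground truth that channel selection should
recover.
"""
from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import MONTAGE, EpochSet, StimulusSpec


@dataclass
class SynthConfig:
    """Generator settings; the defaults define the standard study conditions
    used throughout the test-bench.

    Amplitudes are in arbitrary units relative to the 1/f noise amplitude,
    so mu_amplitude / noise_amplitude and ssvep_amplitude / noise_amplitude
    act as SNR dials. erd_depth in [0, 1] is the fractional mu attenuation
    on the desynchronizing hemisphere (0 = no class effect).
    """

    montage: tuple[str, ...] = MONTAGE
    fs: float = 256.0
    trial_seconds: float = 2.0
    # motor-imagery side
    mi_trials_per_class: int = 20
    mu_freq: float = 10.0
    mu_amplitude: float = 2.0
    erd_depth: float = 0.8
    mi_channels: tuple[str, ...] = ("C3", "C4")  # (left hemi, right hemi)
    # SSVEP side
    ssvep_trials_per_class: int = 10
    stim_freqs: tuple[float, ...] = (10.0, 12.0, 15.0)
    n_harmonics: int = 2
    harmonic_amplitudes: tuple[float, ...] = (1.0, 0.5)
    ssvep_amplitude: float = 1.5
    ssvep_channels: tuple[str, ...] = ("O1", "Oz", "O2")
    # background noise
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0

    def __post_init__(self) -> None:
        for group in (self.mi_channels, self.ssvep_channels):
            unknown = [c for c in group if c not in self.montage]
            if unknown:
                raise ValueError(f"invalid channel names: {unknown}")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if len(self.harmonic_amplitudes) != self.n_harmonics:
            raise ValueError("need one amplitude per harmonic")
        if max(self.stim_freqs) * self.n_harmonics >= self.fs / 2:
            raise ValueError("stimulus harmonics reach the Nyquist frequency")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_seconds))

    @property
    def stimulus_spec(self) -> StimulusSpec:
        return StimulusSpec(frequencies=self.stim_freqs,
                            n_harmonics=self.n_harmonics)


def one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                     exponent: float = 1.0, amplitude: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum along the last axis,
    scaled to unit standard deviation then by `amplitude`."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0:
        return amplitude * white
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    colored = np.fft.irfft(spectrum * scale, n=n, axis=-1)
    sd = colored.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return amplitude * colored / sd


def generate_mi_epochs(config: SynthConfig, seed: int | np.random.Generator = 0
                       ) -> EpochSet:
    """Two-class motor-imagery epochs with planted contralateral ERD.

    Label 0 = left-hand imagery (mu attenuated on the right-hemisphere
    channel), label 1 = right-hand (attenuated on the left). Balanced
    classes; deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_trials = 2 * config.mi_trials_per_class
    n_ch = len(config.montage)
    t = np.arange(config.n_samples) / config.fs
    left_idx = config.montage.index(config.mi_channels[0])
    right_idx = config.montage.index(config.mi_channels[1])

    labels = np.repeat([0, 1], config.mi_trials_per_class)
    rng.shuffle(labels)
    data = one_over_f_noise(rng, (n_trials, n_ch, config.n_samples),
                            config.noise_exponent, config.noise_amplitude)
    attenuated = config.mu_amplitude * (1.0 - config.erd_depth)
    for i, label in enumerate(labels):
        # contralateral suppression: left-hand imagery quiets the right hemisphere
        amp_left = config.mu_amplitude if label == 0 else attenuated
        amp_right = attenuated if label == 0 else config.mu_amplitude
        for idx, amp in ((left_idx, amp_left), (right_idx, amp_right)):
            phase = rng.uniform(0, 2 * np.pi)
            data[i, idx] += amp * np.sin(2 * np.pi * config.mu_freq * t + phase)
    return EpochSet(data=data, labels=labels, fs=config.fs,
                    channel_names=config.montage)


def generate_ssvep_epochs(config: SynthConfig, seed: int | np.random.Generator = 0
                          ) -> tuple[EpochSet, StimulusSpec]:
    """SSVEP epochs: per trial of class c, sinusoids at stimulus frequency
    f_c and its harmonics on the occipital channels, random phase per trial,
    over 1/f noise everywhere. Labels index the stimulus list; balanced."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_classes = len(config.stim_freqs)
    n_trials = n_classes * config.ssvep_trials_per_class
    n_ch = len(config.montage)
    t = np.arange(config.n_samples) / config.fs
    occ_idx = [config.montage.index(c) for c in config.ssvep_channels]

    labels = np.repeat(np.arange(n_classes), config.ssvep_trials_per_class)
    rng.shuffle(labels)
    data = one_over_f_noise(rng, (n_trials, n_ch, config.n_samples),
                            config.noise_exponent, config.noise_amplitude)
    for i, label in enumerate(labels):
        f = config.stim_freqs[label]
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.zeros(config.n_samples)
        for h, amp in enumerate(config.harmonic_amplitudes, start=1):
            wave += amp * np.sin(2 * np.pi * h * f * t + h * phase)
        data[i, occ_idx] += config.ssvep_amplitude * wave
    return (EpochSet(data=data, labels=labels, fs=config.fs,
                     channel_names=config.montage),
            config.stimulus_spec)


def make_fixture_suite(out_dir: str | Path, config: SynthConfig | None = None,
                       seed: int = 0) -> dict:
    """Write a canonical pair of epoch fixtures plus a ground-truth manifest.

    Regeneration with the same (config, seed) is checksum-stable. Returns
    the manifest dict.
    """
    from .io import write_epochs  # local import to avoid a cycle

    config = config or SynthConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mi = generate_mi_epochs(config, seed)
    ssvep, stim = generate_ssvep_epochs(config, seed + 1)
    mi_path = write_epochs(mi, out_dir / "mi_epochs")
    ssvep_path = write_epochs(ssvep, out_dir / "ssvep_epochs",
                              extra={"stim_freqs": list(stim.frequencies),
                                     "n_harmonics": stim.n_harmonics})
    manifest = {
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "planted_mi_channels": list(config.mi_channels),
        "planted_ssvep_channels": list(config.ssvep_channels),
        "files": {"mi": mi_path.name, "ssvep": ssvep_path.name},
        "checksums": {
            "mi": hashlib.sha256(mi.data.tobytes()).hexdigest(),
            "ssvep": hashlib.sha256(ssvep.data.tobytes()).hexdigest(),
        },
    }
    (out_dir / "fixture_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
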