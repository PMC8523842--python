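"""Signal-side primitives: band-pass filtering, CSP spatial filters,
canonical-correlation SSVEP scoring.

CSP solves the generalized eigenproblem of the two class-average normalized
covariance matrices; with B = S1 + S2 as the metric, the eigenvalues lie in
[0, 1] and degenerate to 0.5 everywhere when the classes share a covariance.
CCA scores a multichannel trial against a truncated Fourier reference set
(sines and cosines at the stimulus frequency and its harmonics); the score
is the largest canonical correlation, computed via orthonormal bases and an
SVD of their cross-product.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal

from .data import EpochSet, StimulusSpec

MI_BAND = (5.0, 30.0)


class DegenerateTrialError(ValueError):
    """Raised when a trial carries no variance and features are undefined."""


def bandpass_mi(epochs: EpochSet, band: tuple[float, float] = MI_BAND,
                order: int = 4) -> EpochSet:
    """Zero-phase band-pass (forward-backward Butterworth) per trial/channel.

    Zero-phase filtering avoids introducing class-dependent phase
    distortion ahead of the covariance-based CSP step.
    """
    low, high = band
    if high >= epochs.fs / 2:
        raise ValueError(
            f"band edge {high} Hz requires fs > {2 * high} Hz; got fs={epochs.fs}"
        )
    sos = scipy.signal.butter(order, [low, high], btype="bandpass",
                              fs=epochs.fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(data=filtered, labels=epochs.labels, fs=epochs.fs,
                    channel_names=epochs.channel_names)


def _normalized_covariance(trial: np.ndarray) -> np.ndarray:
    """Channel covariance of one trial, normalized to unit trace."""
    x = trial - trial.mean(axis=1, keepdims=True)
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        raise DegenerateTrialError("trial has zero variance")
    return c / tr


@dataclass
class SpatialFilterBank:
    """CSP projection vectors: the first m and last m generalized
    eigenvectors, columns of `filters` (channels x 2m)."""

    filters: np.ndarray
    eigenvalues: np.ndarray
    pair_count: int

    @property
    def n_filters(self) -> int:
        return self.filters.shape[1]


def default_pair_count(n_channels: int) -> int:
    """CSP filter pairs used by the objective backend: min(2, C // 2)."""
    return min(2, n_channels // 2)


def csp_fit(epochs: EpochSet, m: int | None = None) -> SpatialFilterBank:
    """Fit CSP filters discriminating the two classes of `epochs`.

    Solves S1 w = lambda (S1 + S2) w, where S1 and S2 are the class-average
    trace-normalized covariances. Keeps the m largest- and m smallest-
    eigenvalue eigenvectors; eigh's B-normalization (w^T B w = 1) whitens
    the projected composite covariance. A rank-deficient composite
    covariance is ridge-regularized with eps = 1e-8 * trace/dim and a
    warning.
    """
    classes = epochs.classes()
    if len(classes) != 2:
        raise ValueError(f"CSP needs exactly 2 classes, got {list(classes)}")
    if epochs.n_channels < 2:
        raise ValueError("CSP needs at least 2 channels")
    if m is None:
        m = default_pair_count(epochs.n_channels)
    if 2 * m > epochs.n_channels:
        raise ValueError(f"2*m = {2 * m} exceeds {epochs.n_channels} channels")

    covs = []
    for cls in classes:
        trials = epochs.data[epochs.labels == cls]
        covs.append(np.mean([_normalized_covariance(t) for t in trials], axis=0))
    s1, s2 = covs
    composite = s1 + s2
    eigvals_b = np.linalg.eigvalsh(composite)
    if eigvals_b[0] < 1e-12 * max(eigvals_b[-1], 1e-300):
        eps = 1e-8 * np.trace(composite) / composite.shape[0]
        composite = composite + eps * np.eye(composite.shape[0])
        warnings.warn("rank-deficient composite covariance; ridge-regularized",
                      RuntimeWarning, stacklevel=2)
    w, v = scipy.linalg.eigh(s1, composite)
    # ascending eigenvalues: first m favor class 2, last m favor class 1
    pick = list(range(m)) + list(range(len(w) - m, len(w)))
    return SpatialFilterBank(filters=v[:, pick], eigenvalues=w[pick], pair_count=m)


def csp_features(trial: np.ndarray, bank: SpatialFilterBank) -> np.ndarray:
    """Normalized log-variance features of one trial under a filter bank.

    Per filter: log(projected variance / total projected variance), which
    is invariant to global amplitude scaling of the trial.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.shape[0] != bank.filters.shape[0]:
        raise ValueError(
            f"trial has {trial.shape[0]} channels; bank expects {bank.filters.shape[0]}"
        )
    projected = bank.filters.T @ (trial - trial.mean(axis=1, keepdims=True))
    var = projected.var(axis=1)
    total = var.sum()
    if total <= 0:
        raise DegenerateTrialError("zero-variance trial; log-variance undefined")
    return np.log(var / total)


def log_variance_feature(trial: np.ndarray) -> np.ndarray:
    """Single-channel fallback feature when CSP is not defined: the log
    variance of the lone channel."""
    trial = np.asarray(trial, dtype=float)
    var = trial.var(axis=-1)
    if np.any(var <= 0):
        raise DegenerateTrialError("zero-variance trial; log-variance undefined")
    return np.log(var).reshape(-1)


def _orthonormal_basis(x: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal column basis of the centered matrix, dropping
    numerically null directions."""
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise DegenerateTrialError("signal has no variance; CCA undefined")
    keep = s > rtol * s[0]
    return u[:, keep]


def harmonic_references(freq: float, n_samples: int, fs: float,
                        n_harmonics: int) -> np.ndarray:
    """Sine/cosine reference matrix (n_samples x 2*n_harmonics) at a
    stimulus frequency and its harmonics."""
    t = np.arange(n_samples) / fs
    cols = []
    for h in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * h * freq * t))
        cols.append(np.cos(2 * np.pi * h * freq * t))
    return np.column_stack(cols)


def cca_score(trial: np.ndarray, stim: StimulusSpec, fs: float) -> np.ndarray:
    """Largest canonical correlation between a trial and each stimulus
    reference set.

    trial is (channels, samples). Returns one value in [0, 1] per stimulus
    frequency. Scale-invariant in the trial by construction.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim == 1:
        trial = trial[np.newaxis, :]
    n_samples = trial.shape[1]
    if n_samples < 2:
        raise ValueError("CCA needs more than one sample")
    stim.check_nyquist(fs)
    if n_samples < fs / min(stim.frequencies):
        raise ValueError("trial shorter than one period of the lowest frequency")
    qx = _orthonormal_basis(trial.T)
    scores = np.empty(len(stim.frequencies))
    for i, f in enumerate(stim.frequencies):
        ref = harmonic_references(f, n_samples, fs, stim.n_harmonics)
        qy = _orthonormal_basis(ref)
        s = np.linalg.svd(qx.T @ qy, compute_uv=False)
        scores[i] = min(1.0, float(s[0]))
    return scores


def cca_classify(trial: np.ndarray, stim: StimulusSpec, fs: float,
                 tol: float = 1e-12) -> int:
    """Index of the stimulus frequency with the largest canonical
    correlation; scores within `tol` of the maximum tie-break to the lowest
    index."""
    if len(stim.frequencies) < 2:
        raise ValueError("classification needs at least 2 stimulus frequencies")
    scores = cca_score(trial, stim, fs)
    return int(np.flatnonzero(scores >= scores.max() - tol)[0])
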