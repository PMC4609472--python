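"""Temporal filtering, inverse-distance Laplacian re-referencing, window z-scoring.

All filters are causal (single pass), matching the online use case; the
offline training path runs through the identical filters so feature
distributions agree between phases.  Processing order across the pipeline is
notch -> band-pass -> Laplacian -> windowing -> per-window normalisation.

The Laplacian subtracts from each electrode an inverse-distance weighted
average of every other electrode,

    V_i_lap = V_i - sum_{j != i} g_ij V_j,   g_ij = (1/d_ij) / sum_k (1/d_ik),

which sharpens local sensorimotor activity and removes any spatially common
component exactly (rows of g sum to one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage_io import DistanceTable, EEGRecording

__all__ = [
    "FilterSpec",
    "LaplacianWeights",
    "notch",
    "bandpass",
    "laplacian_weights",
    "apply_laplacian",
    "window_normalize",
]


@dataclass(frozen=True)
class FilterSpec:
    """Temporal filtering constants (defaults: 50 Hz notch, 5-40 Hz order-4)."""

    notch_freq: float = 50.0
    band: tuple[float, float] = (5.0, 40.0)
    order: int = 4
    notch_q: float = 35.0

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not 0 < low < high < fs / 2:
            raise ValueError(f"invalid band {self.band} for fs={fs}")
        if not 0 < self.notch_freq < fs / 2:
            raise ValueError(f"notch {self.notch_freq} Hz at/above Nyquist")


@dataclass(frozen=True)
class LaplacianWeights:
    """Matrix g with zero diagonal; row i holds g_ij for all j != i."""

    labels: tuple[str, ...]
    g: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.g.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")
        if np.any(np.diag(self.g) != 0):
            raise ValueError("self-weight must be zero")
        off = self.g[~np.eye(n, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("weights must be positive")
        if np.max(np.abs(self.g.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("weight rows must sum to 1")


def notch(rec: EEGRecording, f0: float = 50.0, q: float = 35.0) -> EEGRecording:
    """Causal IIR notch removing the power-line component at ``f0`` Hz."""
    if not 0 < f0 < rec.fs / 2:
        raise ValueError(f"notch frequency {f0} Hz outside (0, Nyquist)")
    b, a = signal.iirnotch(f0, q, fs=rec.fs)
    return rec.copy_with(signal.lfilter(b, a, rec.data, axis=1))


def bandpass(rec: EEGRecording, spec: FilterSpec = FilterSpec()) -> EEGRecording:
    """Causal Butterworth band-pass (removes DC and out-of-band activity)."""
    spec.validate(rec.fs)
    sos = signal.butter(spec.order, spec.band, btype="bandpass",
                        fs=rec.fs, output="sos")
    return rec.copy_with(signal.sosfilt(sos, rec.data, axis=1))


def laplacian_weights(d: DistanceTable) -> LaplacianWeights:
    """Inverse-distance weights g_ij = (1/d_ij) / sum_k (1/d_ik)."""
    dist = np.asarray(d.d, float)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] <= 0):
        raise ValueError("zero or negative inter-electrode distance")
    inv = np.zeros_like(dist)
    inv[off] = 1.0 / dist[off]
    g = inv / inv.sum(axis=1, keepdims=True)
    return LaplacianWeights(labels=tuple(d.labels), g=g)


def apply_laplacian(rec: EEGRecording, w: LaplacianWeights) -> EEGRecording:
    """Spatial filter: each channel minus the weighted sum of all others."""
    if tuple(rec.labels) != tuple(w.labels):
        raise ValueError(
            f"channel order mismatch: recording {rec.labels} vs weights "
            f"{list(w.labels)}")
    return rec.copy_with(rec.data - w.g @ rec.data)


def window_normalize(samples: np.ndarray, labels=None) -> np.ndarray:
    """Z-score each channel independently within one analysis window."""
    samples = np.asarray(samples, float)
    mean = samples.mean(axis=1, keepdims=True)
    std = samples.std(axis=1, keepdims=True)
    bad = np.nonzero(std.ravel() < 1e-12)[0]
    if bad.size:
        names = ([labels[i] for i in bad] if labels is not None
                 else list(bad))
        raise ValueError(f"zero-variance channel(s) in window: {names}")
    return (samples - mean) / std
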