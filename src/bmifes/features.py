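"""Spectral features for the two classification pathways.

* Motor-imagery pathway: the one-sided periodogram PSD of each 1-s window,
  sampled every 1 Hz from 8 to 36 Hz — 29 features per electrode, 464 for the
  16-channel montage.  A 1-s window at 256 Hz gives exactly 1 Hz bins, so the
  features are plain DFT bins (rectangular window, no detrending or log
  transform).
* Movement-intention pathway: per electrode, the sums of the one-sided PSD
  over the sensorimotor bands mu (8-12 Hz), low beta (13-24 Hz) and high beta
  (25-30 Hz), band edges inclusive.  The seven non-empty band subsets form
  the model-selection catalogue (combination 7 = all three bands).

Feature vectors are laid out channel-major: all components of channel 0,
then channel 1, and so on, in montage order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal

from .paradigm import Trial, TrialSet

__all__ = [
    "BANDS",
    "BandCombo",
    "periodogram_features",
    "bandpower_features",
    "enumerate_combos",
    "feature_matrix",
]

#: Sensorimotor band edges in Hz, inclusive on both ends.
BANDS: dict[str, tuple[int, int]] = {
    "mu": (8, 12),
    "low_beta": (13, 24),
    "high_beta": (25, 30),
}

_BAND_ORDER = ("mu", "low_beta", "high_beta")


@dataclass(frozen=True)
class BandCombo:
    """One of the 7 non-empty subsets of {mu, low_beta, high_beta}."""

    id: int
    bands: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band combination must be non-empty")
        unknown = set(self.bands) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands {unknown}")


def enumerate_combos() -> list[BandCombo]:
    """The 7 band combinations: singles first, then pairs, then all three."""
    subsets: list[tuple[str, ...]] = []
    for k in (1, 2, 3):
        subsets.extend(combinations(_BAND_ORDER, k))
    return [BandCombo(i + 1, bands) for i, bands in enumerate(subsets)]


def _psd(samples: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    return signal.periodogram(samples, fs=fs, window="boxcar",
                              detrend=False, scaling="density", axis=-1)


def _bin_indices(freqs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(freqs, targets)
    idx = np.clip(idx, 0, len(freqs) - 1)
    if np.max(np.abs(freqs[idx] - targets)) > 1e-6:
        raise ValueError(
            "window length does not place PSD bins on the requested "
            "integer frequencies")
    return idx


def periodogram_features(trial: Trial | np.ndarray, fs: float = 256.0,
                         fmin: float = 8.0, fmax: float = 36.0,
                         step: float = 1.0) -> np.ndarray:
    """Per-channel periodogram PSD at ``fmin..fmax`` every ``step`` Hz."""
    samples = trial.samples if isinstance(trial, Trial) else np.asarray(trial)
    n = samples.shape[-1]
    if fs / n > step + 1e-12:
        raise ValueError(
            f"{n} samples at {fs} Hz give {fs / n:.2f} Hz resolution, "
            f"coarser than the requested {step} Hz")
    freqs, psd = _psd(samples, fs)
    targets = np.arange(fmin, fmax + step / 2, step)
    return psd[..., _bin_indices(freqs, targets)].ravel()


def bandpower_features(trial: Trial | np.ndarray, combo: BandCombo,
                       fs: float = 256.0) -> np.ndarray:
    """Per-channel sums of the one-sided PSD over each band of ``combo``."""
    samples = trial.samples if isinstance(trial, Trial) else np.asarray(trial)
    freqs, psd = _psd(samples, fs)
    cols = []
    for band in combo.bands:
        lo, hi = BANDS[band]
        sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"no PSD bins inside band {band}")
        cols.append(psd[..., sel].sum(axis=-1))
    return np.stack(cols, axis=-1).ravel()  # channel-major, bands in combo order


def feature_matrix(ts: TrialSet, kind: str = "periodogram",
                   combo: BandCombo | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-trial features into (X, labels, runs) arrays.

    ``kind`` is ``"periodogram"`` (motor-imagery pathway) or ``"bandpower"``
    (movement-intention pathway; requires ``combo``).
    """
    if kind == "periodogram":
        rows = [periodogram_features(t, ts.fs) for t in ts]
    elif kind == "bandpower":
        if combo is None:
            raise ValueError("bandpower features require a BandCombo")
        rows = [bandpower_features(t, combo, ts.fs) for t in ts]
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    X = np.asarray(rows)
    y = np.array([t.label for t in ts])
    runs = np.array([t.run for t in ts])
    return X, y, runs
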