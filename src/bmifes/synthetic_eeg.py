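"""Synthetic 16-channel sensorimotor EEG with parameterised ERD/ERS.

Each channel is the sum of an independent 1/f (pink) background and three
band-limited stochastic oscillators — mu (8-12 Hz), low beta (13-24 Hz) and
high beta (25-30 Hz) — built by band-pass filtering white noise.  The
oscillators are amplitude-modulated by the paradigm: from ``erd_latency``
seconds before each task period until the period ends, the rhythm envelope
drops by the factor ``1 - erd_depth`` (event-related desynchronisation); for
``ers_duration`` seconds afterwards it is multiplied by ``ers_gain``
(rebound synchronisation).  Because the carriers are filtered noise rather
than deterministic sinusoids, single trials are realistically variable and
ERD is only evident on average — as in real recordings.

Rhythm topography is a fixed two-lobe Gaussian spatial profile centred on
the hand areas at C3 and C4, so the central channels C3/Cz/C4 carry the
strongest rhythms.  There is no volume-conduction forward model,
no artifacts and no cue-evoked potentials.  Everything is reproducible from
a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .features import BANDS
from .montage_io import EEGRecording, EventList, standard_montage
from .paradigm import ParadigmSchedule

__all__ = ["ERDParams", "generate_session", "generate_cohort",
           "rhythm_topography"]

_TASK_LABELS = ("mi_task", "move_task")


@dataclass
class ERDParams:
    """Generator parameters: rhythm amplitudes (uV RMS), ERD/ERS dynamics."""

    band_amp: dict[str, float] = field(
        default_factory=lambda: {"mu": 4.0, "low_beta": 2.0, "high_beta": 1.0})
    erd_depth: float = 0.5
    ers_gain: float = 1.5
    ers_duration: float = 1.5
    erd_latency: float = 0.5
    background: float = 5.0
    topo_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.ers_gain < 1.0:
            raise ValueError("ers_gain must be >= 1")
        if any(a < 0 for a in self.band_amp.values()) or self.background < 0:
            raise ValueError("amplitudes must be nonnegative")


def rhythm_topography(ch_names: list[str], sigma: float = 0.6) -> np.ndarray:
    """Two-lobe Gaussian spatial weights centred on C3 and C4 (chord distance).

    Mimics the bilateral sensorimotor mu/beta sources over the hand areas;
    the maximum weight is normalised to 1 and C3/Cz/C4 carry the strongest
    rhythms.
    """
    m = standard_montage()
    lobes = [m.positions["C3"], m.positions["C4"]]
    w = np.array([
        sum(np.exp(-np.sum((m.positions[ch] - c) ** 2) / (2 * sigma**2))
            for c in lobes)
        for ch in ch_names])
    return w / w.max()


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f-power noise via frequency-domain shaping."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * amp, n=n)
    return x / x.std()


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited noise (4th-order Butterworth on white noise)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _envelope(sched: ParadigmSchedule, p: ERDParams, fs: float,
              n: int) -> np.ndarray:
    """Per-sample rhythm envelope: 1 at rest, 1-depth during tasks, ERS after."""
    env = np.ones(n)
    for ev in sched.with_label(*_TASK_LABELS):
        i0 = max(0, int(round((ev.onset - p.erd_latency) * fs)))
        i1 = min(n, int(round(ev.end * fs)))
        env[i0:i1] = 1.0 - p.erd_depth
        i2 = min(n, int(round((ev.end + p.ers_duration) * fs)))
        env[i1:i2] = p.ers_gain
    return env


def generate_session(sched: ParadigmSchedule, p: ERDParams | None = None,
                     fs: float = 256.0, pad: float = 2.0
                     ) -> tuple[EEGRecording, EventList]:
    """Synthesise one EEG session following ``sched``.

    Returns the recording (channels x samples, uV) and the schedule's events;
    ``pad`` seconds of plain background are appended after the last event.
    Identical seeds give bit-identical recordings.
    """
    p = ERDParams() if p is None else p
    ch_names = list(standard_montage().names)
    n = int(round((sched.duration + pad) * fs))
    rng = np.random.default_rng(p.seed)
    topo = rhythm_topography(ch_names, p.topo_sigma)
    env = _envelope(sched, p, fs, n)
    data = np.empty((len(ch_names), n))
    for c in range(len(ch_names)):
        x = p.background * _pink_noise(rng, n)
        for band, amp in p.band_amp.items():
            if amp <= 0:
                continue
            osc = _band_noise(rng, n, fs, BANDS[band])
            x = x + amp * topo[c] * env * osc
        data[c] = x
    rec = EEGRecording(data, fs=fs, labels=ch_names)
    return rec, sched.to_event_list()


def generate_cohort(sched: ParadigmSchedule, n_subjects: int,
                    depth_spread: tuple[float, float] = (0.3, 0.7),
                    seed: int = 0, fs: float = 256.0
                    ) -> list[tuple[EEGRecording, EventList, ERDParams]]:
    """Generate ``n_subjects`` sessions with per-subject ERD strength.

    Subject difficulty is emulated by drawing ``erd_depth`` uniformly from
    ``depth_spread`` (weak depths mimic the harder patient cases) and
    jittering rhythm amplitudes by +/-20 %.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        depth = float(rng.uniform(*depth_spread))
        amps = {b: a * float(rng.uniform(0.8, 1.2))
                for b, a in ERDParams().band_amp.items()}
        p = ERDParams(band_amp=amps, erd_depth=depth,
                      seed=int(rng.integers(2**31 - 1)))
        rec, events = generate_session(sched, p, fs=fs)
        out.append((rec, events, p))
    return out
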