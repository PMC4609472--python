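import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bmifes as b

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Reduced, fixed SVM settings for simulation-heavy tests (no inner search).
FAST_GRID = {"svc__C": [10.0], "svc__gamma": ["scale"]}


def make_mi_features(depth: float, seed: int, runs: int = 4, reps: int = 2,
                     ratio: int = 1):
    """Small motor-imagery session -> (X, y, run) periodogram features."""
    sched = b.build_mi_schedule(runs=runs, reps_per_task=reps)
    params = b.ERDParams(erd_depth=depth,
                         ers_gain=1.0 if depth == 0 else 1.5, seed=seed)
    rec, _ = b.generate_session(sched, params)
    proc = b.preprocess_recording(rec)
    ts = b.segment_trials(proc, sched)
    sub = b.subsample_rest(ts, ratio, seed=seed + 1)
    return b.feature_matrix(sub, "periodogram")


@pytest.fixture(scope="session")
def montage():
    return b.standard_montage()


@pytest.fixture(scope="session")
def lap_weights(montage):
    return b.laplacian_weights(b.distances(montage))


@pytest.fixture(scope="session")
def noise_recording():
    """800-s 16-channel white-noise recording for segmentation tests."""
    rng = np.random.default_rng(0)
    labels = list(b.standard_montage().names)
    data = rng.standard_normal((16, 830 * 256))
    return b.EEGRecording(data, fs=256.0, labels=labels)


@pytest.fixture(scope="session")
def strong_mi_trialset():
    """Preprocessed, segmented strong-ERD motor-imagery session (small)."""
    sched = b.build_mi_schedule(runs=4, reps_per_task=2)
    rec, _ = b.generate_session(sched, b.ERDParams(erd_depth=0.6, seed=11))
    proc = b.preprocess_recording(rec)
    return sched, b.segment_trials(proc, sched)
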