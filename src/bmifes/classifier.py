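"""SVM-RBF classification, run-fold cross-validation and the online decision rule.

The rest class deliberately outnumbers the task class (1:1, 2:1 or 3:1
rest:task, chosen per subject) to bias the model toward rest and keep false
activations rare; imbalance is handled only by subsampling, never by class
weighting.  Model assessment uses each run as one cross-validation fold, so
the reported accuracy reflects between-run generalisation.

Online, a control command is emitted only after ``n`` consecutive task
predictions (default 3); any non-task prediction resets the counter, as does
an emitted command.  Commands alternate extension/flexion with the arm state
(arm starts flexed, so the first actuated command is an extension).  Commands
during rest periods are logged but never actuate stimulation; they only count
toward the false-positive rate.

Period-level metrics: TPR is the percentage of task periods with a correct
command, FPR the percentage of rest periods containing at least one
(suppressed) command, and ACC the percentage of all periods resolved
correctly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import BandCombo, bandpower_features, periodogram_features
from .montage_io import EEGRecording
from .paradigm import ParadigmSchedule, TrialSet, window_count
from .preprocess import window_normalize

__all__ = [
    "ClassifierModel",
    "CVReport",
    "Command",
    "DecisionTrace",
    "Metrics",
    "DEFAULT_GRID",
    "subsample_rest",
    "train_model",
    "crossval_by_run",
    "select_ratio",
    "select_combo",
    "online_decide",
    "intention_decide",
    "simulate_online",
    "score",
]

logger = logging.getLogger(__name__)

#: Hyperparameter grid for the seeded inner 3-fold search (C, gamma are not
#: dictated by the protocol; this small log grid is the package default).
DEFAULT_GRID: dict[str, list] = {
    "svc__C": [1.0, 10.0, 100.0],
    "svc__gamma": ["scale", 0.01],
}


@dataclass
class ClassifierModel:
    """A fitted scaler + SVM-RBF pipeline plus its feature-layout contract."""

    pipeline: Pipeline
    feature_spec: dict
    classes: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        expected = self.feature_spec.get("n_features")
        if expected is not None and X.shape[1] != expected:
            raise ValueError(
                f"feature layout mismatch: model expects {expected} "
                f"features, got {X.shape[1]}")
        return self.pipeline.predict(X)

    def featurize(self, samples: np.ndarray, fs: float) -> np.ndarray:
        """Compute this model's feature vector for one window."""
        spec = self.feature_spec
        if spec["kind"] == "periodogram":
            return periodogram_features(samples, fs,
                                        fmin=spec.get("fmin", 8.0),
                                        fmax=spec.get("fmax", 36.0))
        combo = BandCombo(spec["combo_id"], tuple(spec["bands"]))
        return bandpower_features(samples, combo, fs)

    def save(self, path) -> None:
        import joblib

        joblib.dump({"pipeline": self.pipeline,
                     "feature_spec": self.feature_spec,
                     "classes": self.classes,
                     "metadata": self.metadata}, path)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        import joblib

        d = joblib.load(path)
        return cls(d["pipeline"], d["feature_spec"], tuple(d["classes"]),
                   d["metadata"])


@dataclass
class CVReport:
    """Per-fold and summary accuracies (percent) of a run-fold CV.

    ``total_acc`` is the unweighted mean of the task and rest class
    accuracies (balanced accuracy), so it stays at 50 % for a degenerate
    always-rest model even when the rest class is deliberately oversampled.
    """

    fold_runs: list[int]
    task_acc: np.ndarray
    rest_acc: np.ndarray
    total_acc: np.ndarray
    skipped: list[int] = field(default_factory=list)

    def _ms(self, a: np.ndarray) -> tuple[float, float]:
        return float(np.mean(a)), float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    @property
    def mean_task(self) -> float:
        return float(np.mean(self.task_acc))

    @property
    def mean_rest(self) -> float:
        return float(np.mean(self.rest_acc))

    @property
    def mean_total(self) -> float:
        return float(np.mean(self.total_acc))

    def summary(self) -> dict[str, float]:
        return {
            "task_acc_mean": self.mean_task,
            "task_acc_sd": float(np.std(self.task_acc, ddof=1)) if len(self.task_acc) > 1 else 0.0,
            "rest_acc_mean": self.mean_rest,
            "rest_acc_sd": float(np.std(self.rest_acc, ddof=1)) if len(self.rest_acc) > 1 else 0.0,
            "total_acc_mean": self.mean_total,
            "total_acc_sd": float(np.std(self.total_acc, ddof=1)) if len(self.total_acc) > 1 else 0.0,
        }


@dataclass(frozen=True)
class Command:
    time: float
    kind: str           # "extension" | "flexion"
    period_id: int
    suppressed: bool    # True when emitted during a rest period (not actuated)


@dataclass
class DecisionTrace:
    """Per-window predictions, counter trace and emitted commands."""

    window_preds: list[tuple[int, str, str, float]]  # (period, truth, pred, t)
    commands: list[Command]
    period_labels: dict[int, str]
    movement_windows: list[tuple[float, float]] = field(default_factory=list)
    n_consecutive: int = 3


@dataclass
class Metrics:
    tpr: float
    fpr: float
    acc: float
    n_task: int
    n_task_detected: int
    n_rest: int
    n_rest_violated: int


# --------------------------------------------------------------------------
# training & cross-validation
# --------------------------------------------------------------------------

def subsample_rest(ts: TrialSet, ratio: int, seed: int) -> TrialSet:
    """Keep all task trials and ``ratio`` x as many rest trials (uniform,
    without replacement, reproducible by ``seed``)."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    task_idx = [i for i, t in enumerate(ts) if t.label == "task"]
    rest_idx = [i for i, t in enumerate(ts) if t.label == "rest"]
    need = ratio * len(task_idx)
    if need > len(rest_idx):
        raise ValueError(
            f"need {need} rest trials for ratio {ratio}:1, have {len(rest_idx)}")
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(rest_idx), size=need, replace=False)
    chosen = sorted(task_idx + [rest_idx[i] for i in keep])
    return ts.subset(chosen)


def _make_pipeline() -> Pipeline:
    return Pipeline([("scaler", StandardScaler()),
                     ("svc", SVC(kernel="rbf"))])


def train_model(X: np.ndarray, y: Sequence[str], seed: int = 0,
                grid: dict | None = None, inner_folds: int = 3,
                feature_spec: dict | None = None) -> ClassifierModel:
    """Fit an SVM-RBF with a seeded inner grid search over (C, gamma)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    grid = DEFAULT_GRID if grid is None else grid
    n_candidates = int(np.prod([len(v) for v in grid.values()]))
    if n_candidates == 1:
        pipe = _make_pipeline()
        pipe.set_params(**{k: v[0] for k, v in grid.items()})
        pipe.fit(X, y)
        best = {k: v[0] for k, v in grid.items()}
    else:
        cv = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                             random_state=seed)
        search = GridSearchCV(_make_pipeline(), grid, cv=cv, n_jobs=1)
        search.fit(X, y)
        pipe = search.best_estimator_
        best = search.best_params_
    spec = dict(feature_spec or {})
    spec.setdefault("n_features", X.shape[1])
    return ClassifierModel(pipe, spec, tuple(classes),
                           metadata={"seed": seed, "best_params": best})


def crossval_by_run(X: np.ndarray, y: np.ndarray, runs: np.ndarray,
                    seed: int = 0, grid: dict | None = None,
                    inner_folds: int = 3) -> CVReport:
    """Run-as-fold cross-validation with per-class and total accuracies."""
    X, y, runs = np.asarray(X), np.asarray(y), np.asarray(runs)
    fold_ids = sorted(set(runs.tolist()))
    if len(fold_ids) < 2:
        raise ValueError("need at least 2 runs for run-fold CV")
    task_acc, rest_acc, total_acc, used, skipped = [], [], [], [], []
    for r in fold_ids:
        test = runs == r
        train = ~test
        if (len(set(y[train])) < 2) or (len(set(y[test])) < 2):
            warnings.warn(f"fold (run {r}) missing a class; skipped")
            skipped.append(r)
            continue
        model = train_model(X[train], y[train], seed=seed, grid=grid,
                            inner_folds=inner_folds)
        pred = model.predict(X[test])
        yt = y[test]
        ta = 100.0 * np.mean(pred[yt == "task"] == "task")
        ra = 100.0 * np.mean(pred[yt == "rest"] == "rest")
        task_acc.append(ta)
        rest_acc.append(ra)
        total_acc.append((ta + ra) / 2.0)  # balanced, as in the CV tables
        used.append(r)
    if not used:
        raise ValueError("every fold was skipped")
    return CVReport(used, np.array(task_acc), np.array(rest_acc),
                    np.array(total_acc), skipped)


def select_ratio(reports: dict[int, CVReport], margin: float = 5.0) -> int:
    """Pick the rest:task ratio maximising rest-class accuracy among ratios
    whose total accuracy is within ``margin`` points of the best total.
    Ties break toward the larger ratio."""
    best_total = max(r.mean_total for r in reports.values())
    candidates = [k for k, r in reports.items()
                  if r.mean_total >= best_total - margin]
    return max(candidates, key=lambda k: (reports[k].mean_rest, k))


def select_combo(reports: dict[int, CVReport],
                 combos: dict[int, BandCombo] | None = None) -> int:
    """Pick the band combination with the best total accuracy.  Ties break
    toward more bands, then toward the lower combination id."""
    if combos is None:
        from .features import enumerate_combos

        combos = {c.id: c for c in enumerate_combos()}

    def key(k: int):
        return (reports[k].mean_total, len(combos[k].bands), -k)

    return max(reports, key=key)


# --------------------------------------------------------------------------
# online decision rule
# --------------------------------------------------------------------------

class _ConsecutiveDetector:
    """Counter for the n-consecutive-detections rule plus arm-state bookkeeping."""

    def __init__(self, n_consecutive: int = 3, arm: str = "flexed") -> None:
        if n_consecutive < 1:
            raise ValueError("n_consecutive must be >= 1")
        self.n = n_consecutive
        self.counter = 0
        self.arm = arm

    def reset(self) -> None:
        self.counter = 0

    def step(self, pred: str, truth: str, period_id: int,
             t: float) -> Command | None:
        if pred != "task":  # any non-task output counts as rest
            self.counter = 0
            return None
        self.counter += 1
        if self.counter < self.n:
            return None
        self.counter = 0
        kind = "extension" if self.arm == "flexed" else "flexion"
        suppressed = truth != "task"
        if not suppressed:  # FES actually fires -> arm moves -> state flips
            self.arm = "extended" if self.arm == "flexed" else "flexed"
        return Command(t, kind, period_id, suppressed)


def online_decide(stream: Iterable[tuple[int, str, str, float]] |
                  Iterable[tuple[int, str, str]],
                  n_consecutive: int = 3) -> DecisionTrace:
    """Apply the consecutive-detection rule to a per-window prediction stream.

    ``stream`` yields ``(period_id, true_label, predicted_label[, time])``
    tuples in temporal order; the counter resets at period boundaries, on any
    rest prediction and after each emitted command.
    """
    det = _ConsecutiveDetector(n_consecutive)
    windows: list[tuple[int, str, str, float]] = []
    commands: list[Command] = []
    period_labels: dict[int, str] = {}
    prev_period: int | None = None
    for i, item in enumerate(stream):
        pid, truth, pred = item[0], item[1], item[2]
        t = float(item[3]) if len(item) > 3 else float(i)
        if pid != prev_period:
            det.reset()
            prev_period = pid
        period_labels.setdefault(pid, truth)
        windows.append((pid, truth, pred, t))
        cmd = det.step(pred, truth, pid, t)
        if cmd is not None:
            commands.append(cmd)
    return DecisionTrace(windows, commands, period_labels,
                         n_consecutive=n_consecutive)


def intention_decide(window_preds: Sequence[str]) -> str:
    """Single end-of-period decision for the intention pathway: majority vote
    over the period's window predictions (ties resolve to rest)."""
    votes = sum(1 for p in window_preds if p == "task")
    return "task" if votes * 2 > len(window_preds) else "rest"


def simulate_online(rec: EEGRecording, sched: ParadigmSchedule,
                    model: ClassifierModel, n_consecutive: int = 3,
                    win: float = 1.0, overlap: float = 0.5,
                    fes_window: float = 5.0) -> DecisionTrace:
    """Replay a (preprocessed) session through the causal online loop.

    ``rec`` must already be notch/band-pass/Laplacian filtered; windows are
    z-scored here, exactly as in training.  Task periods are truncated at the
    first command and a ``fes_window``-second movement window is appended;
    rest periods always run to completion, with false commands logged but
    suppressed.
    """
    det = _ConsecutiveDetector(n_consecutive)
    n_win = int(round(win * rec.fs))
    step = win - overlap
    windows: list[tuple[int, str, str, float]] = []
    commands: list[Command] = []
    period_labels: dict[int, str] = {}
    movement: list[tuple[float, float]] = []
    for pid, (ev, cls) in enumerate(sched.class_periods()):
        period_labels[pid] = cls
        det.reset()
        for i in range(window_count(ev.duration, win, overlap)):
            t0 = ev.onset + i * step
            s0 = int(round((t0 - rec.start_time) * rec.fs))
            sl = window_normalize(rec.data[:, s0 : s0 + n_win], rec.labels)
            pred = str(model.predict(model.featurize(sl, rec.fs)[None, :])[0])
            t_end = t0 + win
            windows.append((pid, cls, pred, t_end))
            cmd = det.step(pred, cls, pid, t_end)
            if cmd is not None:
                commands.append(cmd)
                if not cmd.suppressed:
                    movement.append((cmd.time, cmd.time + fes_window))
                    break  # task period ends at the first correct detection
    return DecisionTrace(windows, commands, period_labels, movement,
                         n_consecutive)


def score(trace: DecisionTrace) -> Metrics:
    """Period-level TPR / FPR / ACC from a decision trace."""
    task_ids = [p for p, l in trace.period_labels.items() if l == "task"]
    rest_ids = [p for p, l in trace.period_labels.items() if l == "rest"]
    if not task_ids or not rest_ids:
        raise ValueError("trace must cover at least one task and one rest period")
    hit = {c.period_id for c in trace.commands}
    n_task_det = sum(1 for p in task_ids if p in hit)
    n_rest_bad = sum(1 for p in rest_ids if p in hit)
    n = len(task_ids) + len(rest_ids)
    correct = n_task_det + (len(rest_ids) - n_rest_bad)
    return Metrics(
        tpr=100.0 * n_task_det / len(task_ids),
        fpr=100.0 * n_rest_bad / len(rest_ids),
        acc=100.0 * correct / n,
        n_task=len(task_ids), n_task_detected=n_task_det,
        n_rest=len(rest_ids), n_rest_violated=n_rest_bad,
    )
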