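"""Sliding-window tensorization, train/test split and normalization.

Feature frames from label-contiguous runs are cut into overlapping
windows of 40 time-steps (8 s at 5 Hz) advanced by a stride of 13
samples (~33% of the window).  Each window inherits the single
behaviour of its source run and becomes one observation unit — the
classifier's atomic training/testing example, a (40, 15) tensor.

The unit pool is randomly split 80/20 into training and testing sets;
every feature column is then z-scored using the mean and standard
deviation of the *training* partition only, so no test-set statistics
leak into the model.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .io import CLASSES

log = logging.getLogger(__name__)

#: Window length in samples (8 s at 5 Hz).
WINDOW = 40
#: Sliding stride in samples (~33% of the window).
STRIDE = 13
#: Fraction of units assigned to the training partition.
TRAIN_FRACTION = 0.8


@dataclass
class WindowSet:
    """A pool of observation units in dense array form.

    Attributes
    ----------
    X : ndarray, shape (n, window, 15)
        Feature windows, in the fixed column order.
    y : ndarray of int, shape (n,)
        Label indices into ``classes``.
    provenance : list of (cow_id, run_index, start_offset)
        Where each unit came from, aligned with ``X``.
    classes : tuple of str
        Label vocabulary, fixed order.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: list = field(default_factory=list)
    classes: tuple = CLASSES

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class SplitDataset:
    """Disjoint train/test partitions plus train-only normalization.

    ``mean``/``sd`` hold one value per feature column, computed over
    every time-step of every *training* window; both partitions are
    stored already normalized.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    seed: int
    classes: tuple = CLASSES

    @property
    def n_train(self) -> int:
        return len(self.X_train)

    @property
    def n_test(self) -> int:
        return len(self.X_test)


def window_count(n: int, win: int = WINDOW, stride: int = STRIDE) -> int:
    """Number of windows a run of ``n`` feature rows yields."""
    if n < win:
        return 0
    return (n - win) // stride + 1


def make_windows(frame: pd.DataFrame, behaviour: str,
                 win: int = WINDOW, stride: int = STRIDE,
                 cow_id: str = "", run_index: int = 0) -> WindowSet:
    """Cut one single-behaviour feature frame into observation units.

    Windows start at offsets 0, stride, 2*stride, ... while they fit;
    a frame shorter than ``win`` contributes nothing.
    """
    if win <= 0 or stride <= 0:
        raise ValueError("win and stride must be positive")
    if behaviour not in CLASSES:
        raise ValueError(f"unknown behaviour {behaviour!r}")
    arr = frame[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
    n = window_count(len(arr), win, stride)
    X = np.empty((n, win, arr.shape[1]), dtype=np.float64)
    prov = []
    for i in range(n):
        off = i * stride
        X[i] = arr[off:off + win]
        prov.append((cow_id, run_index, off))
    y = np.full(n, CLASSES.index(behaviour), dtype=np.int64)
    return WindowSet(X=X, y=y, provenance=prov)


def concat_windows(sets: list[WindowSet]) -> WindowSet:
    """Pool observation units from several runs/cows."""
    sets = [s for s in sets if len(s)]
    if not sets:
        return WindowSet(X=np.empty((0, WINDOW, len(FEATURE_COLUMNS))),
                         y=np.empty(0, dtype=np.int64))
    return WindowSet(
        X=np.concatenate([s.X for s in sets]),
        y=np.concatenate([s.y for s in sets]),
        provenance=[p for s in sets for p in s.provenance])


def split_dataset(units: WindowSet, train_fraction: float = TRAIN_FRACTION,
                  seed: int = 0, group_by_cow: bool = False) -> SplitDataset:
    """Randomly split units and z-score with train statistics.

    The default splits uniformly over windows (the study design).
    Because overlapping windows share raw samples, window-level
    splitting leaks some information between partitions; pass
    ``group_by_cow=True`` for a stricter split that keeps each cow's
    windows entirely in one partition (a deliberate deviation from the
    study design, for leakage-free estimates).
    """
    n = len(units)
    if n < 2:
        raise ValueError("need at least 2 observation units to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if group_by_cow:
        cows = np.array([p[0] for p in units.provenance])
        unique = rng.permutation(np.unique(cows))
        n_target = int(math.floor(train_fraction * n))
        train_mask = np.zeros(n, dtype=bool)
        taken = 0
        for cow in unique:
            if taken >= n_target:
                break
            m = cows == cow
            train_mask |= m
            taken += int(m.sum())
        idx_train = np.flatnonzero(train_mask)
        idx_test = np.flatnonzero(~train_mask)
    else:
        perm = rng.permutation(n)
        n_train = int(math.floor(train_fraction * n))
        idx_train, idx_test = perm[:n_train], perm[n_train:]

    X_train, y_train = units.X[idx_train], units.y[idx_train]
    X_test, y_test = units.X[idx_test], units.y[idx_test]

    present = set(np.unique(y_train))
    absent = [c for i, c in enumerate(units.classes) if i not in present]
    if absent:
        log.warning("classes absent from the training split: %s "
                    "(the model can never predict them)", absent)

    mean = X_train.reshape(-1, X_train.shape[-1]).mean(axis=0)
    sd = X_train.reshape(-1, X_train.shape[-1]).std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [FEATURE_COLUMNS[i] for i in np.flatnonzero(sd <= 0)]
        log.warning("constant feature columns %s; their sd is clamped "
                    "to 1 for normalization", bad)
        sd = np.where(sd <= 0, 1.0, sd)
    return SplitDataset(
        X_train=(X_train - mean) / sd, y_train=y_train,
        X_test=(X_test - mean) / sd, y_test=y_test,
        mean=mean, sd=sd, seed=seed, classes=units.classes)


def normalize(X: np.ndarray, data: SplitDataset) -> np.ndarray:
    """Apply a split's training statistics to new raw windows."""
    return (np.asarray(X, dtype=np.float64) - data.mean) / data.sd


def updates_per_epoch(n_train: int, batch: int = 32) -> int:
    """Number of weight updates per epoch: ceil(n_train / batch).

    With the study's numbers, 169,362 training units at batch size 32
    give 5293 updates per epoch.
    """
    if n_train < 1 or batch < 1:
        raise ValueError("n_train and batch must be >= 1")
    return -(-n_train // batch)


def one_hot(y: np.ndarray, n_classes: int = len(CLASSES)) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float32)[y]


def save_tensor_store(path, data: SplitDataset) -> None:
    """Persist a split as a portable ``.npz`` plus a JSON sidecar."""
    path = Path(path)
    np.savez(path,
             X_train=data.X_train, y_train=data.y_train,
             X_test=data.X_test, y_test=data.y_test,
             mean=data.mean, sd=data.sd)
    sidecar = {"classes": list(data.classes), "seed": int(data.seed),
               "columns": list(FEATURE_COLUMNS)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_tensor_store(path) -> SplitDataset:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        arrays = {k: z[k] for k in z.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return SplitDataset(**arrays, seed=sidecar["seed"],
                        classes=tuple(sidecar["classes"]))
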