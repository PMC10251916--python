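"""Per-sample feature engineering for tri-axial acceleration runs.

Each 5 Hz sample is expanded to 15 variables: the three raw axis values
plus, per axis, the trailing rolling average and sample standard
deviation over 15 observations, the percentage change from the previous
sample, and a binary indicator that is 0 when that change is negative
and 1 otherwise.  Rolling metrics are causal (trailing window), so the
first ``window - 1`` samples of every run are warm-up and are not
emitted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Default rolling-window length in samples (3 s at 5 Hz).
ROLLING_WINDOW = 15

#: Denominator threshold below which percentage change is defined as 0.
PCT_EPS = 1e-12

AXES = ("x", "y", "z")

#: Fixed column order of every feature frame produced by this module.
FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(AXES)
    + tuple(f"avg_{a}" for a in AXES)
    + tuple(f"sd_{a}" for a in AXES)
    + tuple(f"pct_{a}" for a in AXES)
    + tuple(f"bin_{a}" for a in AXES)
)


def pct_change(prev, curr, eps: float = PCT_EPS):
    """Percentage change ``100 * (curr - prev) / prev``.

    Total by design: when ``|prev| <= eps`` the change is defined as 0
    (so its binary indicator is 1), avoiding infinities on a still
    sensor axis.  Accepts scalars or arrays.
    """
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    safe = np.abs(prev) > eps
    out = np.zeros(np.broadcast(prev, curr).shape, dtype=float)
    np.divide(100.0 * (curr - prev), prev, out=out, where=safe)
    if out.ndim == 0:
        return float(out)
    return out


def rolling_features(xyz: np.ndarray, window: int = ROLLING_WINDOW,
                     ddof: int = 1) -> pd.DataFrame:
    """Compute the 15-column feature frame for one contiguous run.

    Parameters
    ----------
    xyz : ndarray, shape (n, 3)
        Raw acceleration samples of a single gap-free, single-behaviour
        run (axes X, Y, Z).
    window : int
        Trailing rolling-window length in samples.
    ddof : int
        Delta degrees of freedom for the rolling standard deviation
        (1 = sample sd, the default; recorded in the frame metadata).

    Returns
    -------
    DataFrame with columns :data:`FEATURE_COLUMNS`; row ``i`` of the
    output corresponds to source sample ``window - 1 + i``.  Runs
    shorter than ``window`` yield an empty frame (with a warning).
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError(f"expected (n, 3) array, got {xyz.shape}")
    n = len(xyz)
    raw = pd.DataFrame(xyz, columns=list(AXES))
    # the first sample additionally has no predecessor for pct change,
    # so the warm-up always covers at least one row
    warmup = max(window - 1, 1)
    if n <= warmup or n < window:
        log.warning("run of length %d shorter than rolling window %d; "
                    "no feature rows emitted", n, window)
        frame = pd.DataFrame(
            {c: pd.Series(dtype=float) for c in FEATURE_COLUMNS})
        frame.attrs.update(window=window, ddof=ddof, pct_eps=PCT_EPS)
        return frame

    roll = raw.rolling(window)
    avg = roll.mean()
    sd = roll.std(ddof=ddof)
    pct = pd.DataFrame(
        np.vstack([np.zeros((1, 3)),
                   pct_change(xyz[:-1], xyz[1:])]),
        columns=list(AXES))
    binary = (pct >= 0).astype(float)

    frame = pd.concat(
        {"": raw, "avg": avg, "sd": sd, "pct": pct, "bin": binary},
        axis=1)
    frame.columns = [f"{p}_{a}".lstrip("_") for p, a in frame.columns]
    frame = frame.iloc[warmup:].reset_index(drop=True)
    frame = frame[list(FEATURE_COLUMNS)]
    frame.attrs.update(window=window, ddof=ddof, pct_eps=PCT_EPS)
    return frame


def metadata(frame: pd.DataFrame) -> dict:
    """Serializable sidecar describing how a frame was computed."""
    return {
        "columns": list(frame.columns),
        "window": frame.attrs.get("window"),
        "sd_ddof": frame.attrs.get("ddof"),
        "pct_zero_denominator": "returns 0 (binary 1)",
        "pct_eps": frame.attrs.get("pct_eps"),
        "alignment": "trailing (causal); first window-1 rows dropped",
    }
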