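"""Radar-cross-section feature engineering, windowing, scaling, splitting.

Two features are derived per interrogation:

* **Feature 1** — reflected signal strength with interrogator-controlled terms
  removed. Isolating the wearer-state terms of the RCS link budget gives

      zeta = G_tag^-2 r^4 R^-1 = P_Tx G_reader^2 P_Rx^-1 (lambda / 4 pi)^4,

  so ``-10 log10(zeta)`` tracks received power with the channel-hop
  wavelength dependence removed (up to an additive constant fixed by the
  interrogator configuration, which standardization absorbs). A residual
  per-hop term ``delta(f) = -10 log10(f^4 / (f - 0.5 MHz)^4)`` from the
  50-channel sawtooth is subtracted on top.
* **Feature 2** — the current value minus the minimum observed over a trailing
  window (default 28 samples, ~1 s), which is large while chest motion
  modulates the backscatter and near zero during apnea.

Samples are then reduced to per-second non-overlapping windows (feature means,
majority ground-truth label), standardized to zero mean / unit variance with
statistics fitted on the training split only, and split 3:1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from neorespire.errors import ParseError, ValidationError
from neorespire.synthetic import (
    SPEED_OF_LIGHT_M_S,
    GroundTruthTimeline,
    InterrogationStream,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RCSContext:
    """Interrogator-side constants of the link budget (all strictly positive)."""

    p_tx_w: float = 1.0
    g_reader: float = 3.98
    r_m: float = 0.3048
    g_tag: float = 1.26
    return_loss: float = 0.5

    def __post_init__(self):
        for name in ("p_tx_w", "g_reader", "r_m", "g_tag", "return_loss"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def compute_zeta(p_rx_w: float | np.ndarray, channel_mhz: float | np.ndarray,
                 ctx: RCSContext = RCSContext()) -> np.ndarray:
    """Wearer-state feature zeta = P_Tx G_reader^2 P_Rx^-1 (lambda/4pi)^4.

    Both powers are linear watts; mixing units between P_Tx and P_Rx breaks
    the ratio, so the operation takes them on a single scale.
    """
    p_rx_w = np.asarray(p_rx_w, dtype=float)
    if np.any(p_rx_w <= 0):
        raise ValidationError("received power must be positive (linear watts)")
    lam = SPEED_OF_LIGHT_M_S / (np.asarray(channel_mhz, dtype=float) * 1e6)
    return ctx.p_tx_w * ctx.g_reader**2 / p_rx_w * (lam / (4.0 * np.pi)) ** 4


def deoscillate(rssi_dbm: float | np.ndarray, channel_mhz: float | np.ndarray) -> np.ndarray:
    """Remove the channel-hop residual: returns rssi - delta(f) with
    delta(f) = -10 log10(f^4 / (f - 0.5 MHz)^4), f in MHz."""
    f = np.asarray(channel_mhz, dtype=float)
    if np.any(f <= 0.5):
        raise ValidationError("channel frequency must exceed 0.5 MHz")
    delta = -40.0 * np.log10(f / (f - 0.5))
    return np.asarray(rssi_dbm, dtype=float) - delta


def rssi_from_min(series, window_n: int = 28) -> np.ndarray:
    """Per-sample difference from the trailing-window minimum (>= 0).

    The window is causal and includes the current sample; for the first
    window_n-1 samples the available prefix is used.
    """
    if window_n < 1:
        raise ValidationError("window_n must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if s.empty:
        return np.array([], dtype=float)
    trailing_min = s.rolling(window_n, min_periods=1).min()
    return (s - trailing_min).to_numpy()


def featurize_records(
    stream: InterrogationStream,
    timeline: GroundTruthTimeline | None = None,
    ctx: RCSContext = RCSContext(),
    window_n: int = 28,
    feature1: str = "zeta_log",
) -> pd.DataFrame:
    """Compute the per-poll feature pair (and labels when a timeline is given).

    ``feature1='zeta_log'`` (default) uses -10 log10(zeta), which removes the
    wavelength ripple exactly; ``'deosc_dbm'`` keeps raw dBm minus delta(f).
    Feature 2 is computed on the de-oscillated series so the hop sawtooth does
    not contaminate the trailing minimum.
    """
    if feature1 not in ("zeta_log", "deosc_dbm"):
        raise ValidationError(f"unknown feature1 variant {feature1!r}")
    t = stream.timestamp_s
    if feature1 == "zeta_log":
        p_rx_w = 1e-3 * 10.0 ** (stream.rssi_dbm / 10.0)
        zeta = compute_zeta(p_rx_w, stream.channel_mhz, ctx)
        f1 = deoscillate(-10.0 * np.log10(zeta), stream.channel_mhz)
    else:
        f1 = deoscillate(stream.rssi_dbm, stream.channel_mhz)
    f2 = rssi_from_min(f1, window_n=window_n)
    out = pd.DataFrame({"timestamp_s": t, "prx_deosc": f1, "rssi_from_min": f2})
    if timeline is not None:
        out["state"] = timeline.state_at(t).astype(int)
    return out


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-feature standardization statistics (population sigma)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std <= 0):
            raise ValidationError("cannot standardize a zero-variance feature")


@dataclass
class WindowedDataset:
    """1-s non-overlapping windows reduced to (mean f1, mean f2) + label."""

    X: np.ndarray
    y: np.ndarray
    window_length_s: float = 1.0
    provenance: str = "all"
    window_start_s: np.ndarray | None = None
    scaler: ScalerParams | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValidationError("X must be (n, d) aligned with y")

    def __len__(self) -> int:
        return len(self.y)


def build_windows(
    samples: pd.DataFrame,
    timeline: GroundTruthTimeline | None = None,
    window_length_s: float = 1.0,
    aggregator: Callable[[np.ndarray], np.ndarray] | None = None,
) -> WindowedDataset:
    """Tile the record span with half-open [t, t+1) windows.

    Each window becomes the per-feature mean of its samples (the aggregator is
    pluggable) with the majority ground-truth state as label; exact ties
    resolve to 0, the safety-critical non-breathing class. Empty windows are
    dropped with a logged warning.
    """
    t = samples["timestamp_s"].to_numpy(dtype=float)
    if len(t) and np.any(np.diff(t) < 0):
        raise ValidationError("samples must be time-sorted")
    if "state" in samples.columns:
        states = samples["state"].to_numpy(dtype=float)
    elif timeline is not None:
        states = timeline.state_at(t).astype(float)
    else:
        raise ValidationError("need per-sample states or a timeline for labels")
    if len(t) == 0:
        return WindowedDataset(np.empty((0, 2)), np.empty(0, dtype=int),
                               window_length_s, window_start_s=np.empty(0))

    agg = aggregator if aggregator is not None else (lambda a: a.mean(axis=0))
    idx = np.floor(t / window_length_s).astype(int)
    feats = samples[["prx_deosc", "rssi_from_min"]].to_numpy(dtype=float)

    span_end = timeline.duration if timeline is not None else t[-1] + window_length_s
    n_windows_expected = int(math.ceil(span_end / window_length_s))

    X, y, starts = [], [], []
    order = np.argsort(idx, kind="stable")
    bounds = np.searchsorted(idx[order], np.arange(idx.max() + 1), side="left")
    bounds = np.append(bounds, len(idx))
    occupied = set()
    for w in range(idx.max() + 1):
        lo, hi = bounds[w], bounds[w + 1]
        if lo == hi:
            continue
        rows = order[lo:hi]
        X.append(agg(feats[rows]))
        y.append(1 if states[rows].mean() > 0.5 else 0)
        starts.append(w * window_length_s)
        occupied.add(w)
    n_empty = n_windows_expected - len(occupied)
    if n_empty > 0:
        logger.warning("dropped %d empty window(s) out of %d", n_empty, n_windows_expected)
    return WindowedDataset(np.array(X), np.array(y), window_length_s,
                           window_start_s=np.array(starts))


# ---------------------------------------------------------------------------
# Scaling and splitting
# ---------------------------------------------------------------------------

def fit_scaler(X: np.ndarray) -> ScalerParams:
    """Per-feature mean and population standard deviation (divide by n)."""
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValidationError("cannot fit a scaler on empty data")
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population sigma
    if np.any(std <= 0):
        raise ValidationError("cannot standardize a zero-variance feature")
    return ScalerParams(mean=mean, std=std)


def apply_scaler(X: np.ndarray, scaler: ScalerParams) -> np.ndarray:
    return (np.asarray(X, dtype=float) - scaler.mean) / scaler.std


def inverse_scaler(Z: np.ndarray, scaler: ScalerParams) -> np.ndarray:
    return np.asarray(Z, dtype=float) * scaler.std + scaler.mean


def clean_and_split(
    dataset: WindowedDataset,
    test_fraction: float = 0.25,
    seed: int = 0,
    chronological: bool = False,
) -> tuple[WindowedDataset, WindowedDataset]:
    """Drop NaN rows, split 3:1, standardize with train-fitted statistics.

    The test partition takes ceil(test_fraction * N) rows; the split is a
    seeded random permutation by default, or the trailing block when
    ``chronological``. Partitions are disjoint and exhaustive.
    """
    if not (0 < test_fraction < 1):
        raise ValidationError("test_fraction must be in (0, 1)")
    keep = ~np.isnan(dataset.X).any(axis=1)
    if not keep.any():
        raise ValidationError("dataset is empty after NaN filtering")
    X, y = dataset.X[keep], dataset.y[keep]
    starts = dataset.window_start_s[keep] if dataset.window_start_s is not None else None
    n = len(y)
    n_test = int(math.ceil(test_fraction * n))
    if n_test >= n:
        raise ValidationError("split leaves no training data")
    if chronological:
        test_idx = np.arange(n - n_test, n)
        train_idx = np.arange(n - n_test)
    else:
        perm = np.random.default_rng(seed).permutation(n)
        test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    scaler = fit_scaler(X[train_idx])

    def _part(idx, name):
        return WindowedDataset(
            apply_scaler(X[idx], scaler), y[idx], dataset.window_length_s,
            provenance=name,
            window_start_s=None if starts is None else starts[idx],
            scaler=scaler,
        )

    return _part(train_idx, "train"), _part(test_idx, "test")


# ---------------------------------------------------------------------------
# CSV plumbing (features.csv + labels.csv, mirroring the two-file exchange)
# ---------------------------------------------------------------------------

def write_feature_csvs(frame: pd.DataFrame, features_path, labels_path) -> None:
    frame[["timestamp_s", "prx_deosc", "rssi_from_min"]].to_csv(features_path, index=False)
    if "state" not in frame.columns:
        raise ValidationError("frame has no 'state' column to write labels from")
    frame[["timestamp_s", "state"]].to_csv(labels_path, index=False)


def read_feature_csvs(features_path, labels_path) -> pd.DataFrame:
    feats = pd.read_csv(features_path)
    labels = pd.read_csv(labels_path)
    for path, df, cols in (
        (features_path, feats, ["timestamp_s", "prx_deosc", "rssi_from_min"]),
        (labels_path, labels, ["timestamp_s", "state"]),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
    if len(feats) != len(labels):
        raise ParseError("features and labels files disagree on row count")
    out = feats.copy()
    out["state"] = labels["state"].to_numpy()
    return out
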