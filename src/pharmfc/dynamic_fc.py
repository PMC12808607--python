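"""Sliding-window dynamic functional connectivity.

A rectangular window of ``window_length_s`` (default 300 s) is shifted
by ``step_samples`` (default one TR); Pearson correlations are computed
within each window and Fisher z-transformed. The adopted window-count
convention is ``n_windows = (n_t - W) // step`` (for step 1: ``n_t - W``,
i.e. 4500 windows from an 80-min run at TR = 1 s), matching the study
design this package reproduces.

Per-ROI global FC — the sum of a region's z-connectivity with all other
regions per window — summarizes whole-brain coupling strength over time.
Stacks can be streamed window-by-window (``iter_window_matrices``,
``global_fc_timecourses``) so a full stack never needs to fit in memory
for large parcellations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .containers import ConditionSegmentation, RoiTimeSeriesSet, group_mean_sem
from .static_fc import R_CLAMP

_PAIR_CHUNK = 256  # pair-columns per rolling-sum chunk (bounds memory)


@dataclass
class DfcStack:
    """Windowed stack of symmetric z-space FC matrices."""

    values: np.ndarray            # (n_windows, n_roi, n_roi), z-space
    window_length_s: float
    step_samples: int
    tr_s: float
    window_start_times_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.window_start_times_s is None:
            self.window_start_times_s = (
                np.arange(self.n_windows) * self.step_samples * self.tr_s)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_roi(self) -> int:
        return self.values.shape[1]


@dataclass
class GlobalFcSeries:
    """Per-ROI global FC (sum of off-diagonal z entries) per window."""

    values: np.ndarray            # (n_roi, n_windows)
    roi_labels: list[str]
    window_start_times_s: np.ndarray
    window_length_s: float


def _window_count(n_t: int, window_samples: int, step_samples: int) -> int:
    if window_samples > n_t:
        raise ValueError("window longer than the series")
    n = (n_t - window_samples) // step_samples
    if n < 1:
        raise ValueError(
            "series too short: zero windows under the n_t - W convention")
    return n


def _rolling_z(signal: np.ndarray, window_samples: int,
               step_samples: int) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (window index, z matrix) using cumulative-sum rolling moments.

    Exactly equivalent (to float round-off) to Pearson + atanh on each
    sample slice; ROIs are globally centred first for conditioning.
    """
    x = np.asarray(signal, dtype=float)
    n_roi, n_t = x.shape
    w = window_samples
    n_win = _window_count(n_t, w, step_samples)
    xc = x - x.mean(axis=1, keepdims=True)
    starts = np.arange(n_win) * step_samples
    # rolling first moments and squares
    cs = np.concatenate([np.zeros((n_roi, 1)), np.cumsum(xc, axis=1)], axis=1)
    cs2 = np.concatenate([np.zeros((n_roi, 1)), np.cumsum(xc * xc, axis=1)], axis=1)
    s1 = cs[:, starts + w] - cs[:, starts]          # (n_roi, n_win)
    s2 = cs2[:, starts + w] - cs2[:, starts]
    var = s2 - s1 * s1 / w
    iu, ju = np.triu_indices(n_roi, k=1)
    n_pairs = iu.size
    cov = np.empty((n_pairs, n_win))
    for lo in range(0, n_pairs, _PAIR_CHUNK):
        hi = min(lo + _PAIR_CHUNK, n_pairs)
        prod = xc[iu[lo:hi]] * xc[ju[lo:hi]]
        cp = np.concatenate([np.zeros((hi - lo, 1)), np.cumsum(prod, axis=1)], axis=1)
        sxy = cp[:, starts + w] - cp[:, starts]
        cov[lo:hi] = sxy - s1[iu[lo:hi]] * s1[ju[lo:hi]] / w
    denom = np.sqrt(var[iu] * var[ju])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    for widx in range(n_win):
        mat = np.full((n_roi, n_roi), np.nan)
        mat[iu, ju] = z[:, widx]
        mat[ju, iu] = z[:, widx]
        yield widx, mat


def sliding_window_dfc(signal: np.ndarray, window_length_s: float = 300.0,
                       step_samples: int = 1, tr_s: float = 1.0) -> DfcStack:
    """Full windowed z-space FC stack for one animal's ROI x time matrix."""
    w = int(round(window_length_s / tr_s))
    n_roi, n_t = np.asarray(signal).shape
    n_win = _window_count(n_t, w, step_samples)
    out = np.empty((n_win, n_roi, n_roi))
    for widx, mat in _rolling_z(signal, w, step_samples):
        out[widx] = mat
    return DfcStack(out, window_length_s, step_samples, tr_s)


def iter_window_matrices(signal: np.ndarray, window_length_s: float = 300.0,
                         step_samples: int = 1,
                         tr_s: float = 1.0) -> Iterator[np.ndarray]:
    """Stream the windowed z matrices without materializing the stack."""
    w = int(round(window_length_s / tr_s))
    for _, mat in _rolling_z(signal, w, step_samples):
        yield mat


def global_fc(stack: DfcStack, roi_labels: list[str] | None = None) -> GlobalFcSeries:
    """Per window, per ROI: sum of off-diagonal z row entries.

    NaN entries (e.g. constant-ROI edges) are excluded from the sum with
    their count retained in no way other than the NaN-aware reduction.
    """
    vals = stack.values
    n_roi = stack.n_roi
    gl = np.nansum(np.where(np.isnan(vals), 0.0, vals), axis=2)
    # diagonal is NaN in z-space already; nansum drops it
    out = gl.T  # (n_roi, n_windows)
    labels = roi_labels if roi_labels is not None else [f"ROI{i:02d}" for i in range(n_roi)]
    return GlobalFcSeries(out, list(labels), stack.window_start_times_s,
                          stack.window_length_s)


def global_fc_timecourses(tsset: RoiTimeSeriesSet, window_length_s: float = 300.0,
                          step_samples: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Streaming per-animal global-FC series plus group mean and SEM.

    Returns ``(per_animal (n_animals, n_roi, n_windows), mean, sem)``
    without ever holding a full dFC stack.
    """
    w = int(round(window_length_s / tsset.tr_s))
    n_win = _window_count(tsset.n_t, w, step_samples)
    per = np.empty((tsset.n_animals, tsset.n_roi, n_win))
    for k in range(tsset.n_animals):
        for widx, mat in _rolling_z(tsset.data[k], w, step_samples):
            per[k, :, widx] = np.nansum(np.where(np.isnan(mat), 0.0, mat), axis=1)
    mean, sem = group_mean_sem(per)
    return per, mean, sem


def edge_timecourse(tsset: RoiTimeSeriesSet, segmentation: ConditionSegmentation,
                    edge: tuple[str | int, str | int], mode: str = "interval",
                    window_length_s: float = 300.0, step_samples: int = 1):
    """Time-resolved FC for one ROI pair.

    ``interval`` mode: Fisher z per condition interval (8 points per
    animal under the default 20/30/30-min design). ``windowed`` mode: the
    sliding-window z trace. Returns ``(per_animal, mean, sem, grid)``
    where grid is interval mid-times or window start times in seconds.
    """
    i = tsset.roi_index(edge[0])
    j = tsset.roi_index(edge[1])
    if mode == "interval":
        n_iv = segmentation.n_intervals
        per = np.empty((tsset.n_animals, n_iv))
        for k in range(tsset.n_animals):
            for m, iv in enumerate(segmentation):
                seg = tsset.data[k][:, iv.slice]
                r = np.corrcoef(seg[i], seg[j])[0, 1]
                per[k, m] = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
        grid = np.array([(iv.start + iv.stop) / 2.0 * tsset.tr_s
                         for iv in segmentation])
    elif mode == "windowed":
        w = int(round(window_length_s / tsset.tr_s))
        n_win = _window_count(tsset.n_t, w, step_samples)
        per = np.empty((tsset.n_animals, n_win))
        for k in range(tsset.n_animals):
            for widx, mat in _rolling_z(tsset.data[k], w, step_samples):
                per[k, widx] = mat[i, j]
        grid = np.arange(n_win) * step_samples * tsset.tr_s
    else:
        raise ValueError("mode must be 'interval' or 'windowed'")
    mean, sem = group_mean_sem(per)
    return per, mean, sem, grid
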