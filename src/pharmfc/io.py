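"""Reading ROI time series and the temporal preprocessing stage.

Input is either delimited tables (one per animal, rows = time, columns =
ROI) or already-registered 4D volumes with an integer label atlas, from
which mean ROI time series are extracted. Temporal preprocessing follows
the standard pharmacological resting-state chain: polynomial detrend,
least-squares nuisance regression (pseudo-WM/CSF, motion, ...), then a
zero-phase Butterworth band-pass in 0.008-0.1 Hz. Runs are segmented
into consecutive equal-length condition intervals (default 10 min).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .containers import ConditionSegmentation, Interval, RoiTimeSeriesSet

log = logging.getLogger(__name__)

DEFAULT_BAND_HZ: tuple[float, float] = (0.008, 0.1)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def extract_roi_timeseries(volume_4d, label_atlas) -> np.ndarray:
    """Mean time series per atlas label from a 4D volume.

    Row ``r`` of the result is the spatial mean over voxels carrying the
    r-th label (ascending label value, label 0 treated as background) at
    each time point. Accepts nibabel images or plain arrays.
    """
    vol = np.asanyarray(volume_4d.dataobj if hasattr(volume_4d, "dataobj") else volume_4d)
    atlas = np.asanyarray(label_atlas.dataobj if hasattr(label_atlas, "dataobj") else label_atlas)
    if vol.ndim != 4:
        raise ValueError("volume must be 4D (x, y, z, t)")
    if atlas.ndim == 4 and atlas.shape[3] == 1:
        atlas = atlas[..., 0]
    if atlas.shape != vol.shape[:3]:
        raise ValueError("atlas and volume must share the spatial grid")
    if not np.issubdtype(atlas.dtype, np.integer):
        rounded = np.round(atlas)
        if not np.allclose(atlas, rounded):
            raise ValueError("atlas must be integer-valued")
        atlas = rounded.astype(int)
    labels = np.unique(atlas)
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ValueError("atlas contains no non-zero labels")
    n_t = vol.shape[3]
    out = np.empty((labels.size, n_t))
    flat = vol.reshape(-1, n_t)
    afl = atlas.reshape(-1)
    for r, lab in enumerate(labels):
        mask = afl == lab
        if not mask.any():
            raise ValueError(f"label {lab} has no voxels")
        out[r] = flat[mask].mean(axis=0)
    return out


def _read_sidecar(path: Path) -> dict:
    sidecar = path / "cohort.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing cohort sidecar: {sidecar}")
    return json.loads(sidecar.read_text())


def load_cohort_tables(path: str | Path) -> RoiTimeSeriesSet:
    """Read a table-format cohort directory written by ``export_cohort``."""
    path = Path(path)
    meta = _read_sidecar(path)
    mats, ids, genos = [], [], []
    for rec in meta["animals"]:
        tab = np.loadtxt(path / rec["file"], delimiter="\t", skiprows=1)
        mats.append(tab.T)  # rows = time on disk -> ROI x time in memory
        ids.append(rec["id"])
        genos.append(rec["genotype"])
    return RoiTimeSeriesSet(
        data=np.stack(mats), animal_ids=ids, genotypes=genos,
        roi_labels=list(meta["roi_labels"]), tr_s=float(meta["tr_s"]),
        vehicle_onset_s=float(meta["vehicle_onset_s"]),
        drug_onset_s=float(meta["drug_onset_s"]))


def load_cohort_volumes(path: str | Path) -> RoiTimeSeriesSet:
    """Read a volume-format cohort directory (4D NIfTI + label atlas)."""
    import nibabel as nib

    path = Path(path)
    meta = _read_sidecar(path)
    atlas = nib.load(path / "atlas.nii")
    mats, ids, genos = [], [], []
    for rec in meta["animals"]:
        vol = nib.load(path / rec["file"])
        mats.append(extract_roi_timeseries(vol, atlas))
        ids.append(rec["id"])
        genos.append(rec["genotype"])
    return RoiTimeSeriesSet(
        data=np.stack(mats), animal_ids=ids, genotypes=genos,
        roi_labels=list(meta["roi_labels"]), tr_s=float(meta["tr_s"]),
        vehicle_onset_s=float(meta["vehicle_onset_s"]),
        drug_onset_s=float(meta["drug_onset_s"]))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _drop_collinear(design: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Keep a maximal linearly independent column subset (pivoted QR)."""
    if design.shape[1] == 0:
        return design
    _, r, piv = sla.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    if rank < design.shape[1]:
        log.warning("dropping %d collinear nuisance column(s)",
                    design.shape[1] - rank)
    keep = np.sort(piv[:rank])
    return design[:, keep]


def preprocess(
    tsset: RoiTimeSeriesSet,
    nuisance: np.ndarray | str | None = "auto",
    band: tuple[float, float] | None = DEFAULT_BAND_HZ,
    detrend_order: int = 1,
    filter_order: int = 4,
) -> RoiTimeSeriesSet:
    """Detrend, regress nuisance signals, and band-pass each ROI series.

    Order of operations is fixed as detrend -> nuisance regression ->
    band-pass: detrending and regression share one least-squares
    projection (polynomial trend columns plus nuisance columns), so the
    filter never re-introduces removed drift. The band-pass is a
    zero-phase forward-backward Butterworth (``filter_order`` prototype),
    preserving windowed-correlation timing.

    ``nuisance="auto"`` uses the regressors carried by the set (if any);
    pass an array ``(n_reg, n_t)`` shared across animals, ``(n_animals,
    n_reg, n_t)`` per animal, or ``None`` to skip regression.
    """
    fs = 1.0 / tsset.tr_s
    if band is not None:
        lo, hi = band
        if not 0.0 < lo < hi < fs / 2.0:
            raise ValueError("band must lie strictly inside (0, Nyquist)")
        sos = sps.butter(filter_order, [lo, hi], btype="bandpass", fs=fs,
                         output="sos")
    n_t = tsset.n_t
    tt = np.linspace(-1.0, 1.0, n_t)
    trend_cols = np.column_stack([tt ** p for p in range(detrend_order + 1)]) \
        if detrend_order >= 0 else np.empty((n_t, 0))

    if isinstance(nuisance, str):
        if nuisance != "auto":
            raise ValueError("nuisance must be an array, None, or 'auto'")
        nuis_all = tsset.nuisance
    else:
        nuis_all = nuisance

    out = np.empty_like(tsset.data)
    for k in range(tsset.n_animals):
        y = tsset.data[k].T  # time x roi
        cols = [trend_cols]
        if nuis_all is not None:
            nk = np.asarray(nuis_all)
            nk = nk[k] if nk.ndim == 3 else nk
            if not np.all(np.isfinite(nk)):
                raise ValueError("nuisance regressors must be finite")
            cols.append(nk.T)
        design = _drop_collinear(np.column_stack(cols))
        if design.shape[1]:
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            y = y - design @ beta
        if band is not None:
            y = sps.sosfiltfilt(sos, y, axis=0)
            y = y - y.mean(axis=0)  # filter edge transients leave a tiny DC
        out[k] = y.T
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values after preprocessing")
    res = tsset.with_data(out)
    res.nuisance = None
    return res


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_conditions(tsset: RoiTimeSeriesSet,
                       interval_length_s: float = 600.0) -> ConditionSegmentation:
    """Split the run into consecutive condition intervals.

    Baseline covers ``[0, vehicle_onset)``, vehicle ``[vehicle_onset,
    drug_onset)``, drug ``[drug_onset, duration)``; each span is cut into
    consecutive intervals of exactly ``interval_length_s``. A span not
    divisible by the interval length is an error (no partial intervals).
    Sample ranges are half-open and 0-based; the sample acquired at an
    injection time belongs to the post-injection interval.
    """
    w = interval_length_s / tsset.tr_s
    if abs(w - round(w)) > 1e-9 or round(w) < 1:
        raise ValueError("interval length must be a positive multiple of TR")
    w = int(round(w))
    bounds_s = [0.0, tsset.vehicle_onset_s, tsset.drug_onset_s, tsset.duration_s]
    bounds = []
    for b in bounds_s:
        sb = b / tsset.tr_s
        if abs(sb - round(sb)) > 1e-9:
            raise ValueError("condition boundaries must align with the TR grid")
        bounds.append(int(round(sb)))
    intervals: list[Interval] = []
    for cond, lo, hi in zip(("baseline", "vehicle", "drug"),
                            bounds[:-1], bounds[1:]):
        span = hi - lo
        if span % w != 0:
            raise ValueError(
                f"{cond} span of {span * tsset.tr_s:.0f} s is not divisible "
                f"by {interval_length_s:.0f} s intervals")
        for j in range(span // w):
            intervals.append(Interval(cond, j, lo + j * w, lo + (j + 1) * w))
    return ConditionSegmentation(intervals=intervals,
                                 interval_length_s=interval_length_s,
                                 tr_s=tsset.tr_s)
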