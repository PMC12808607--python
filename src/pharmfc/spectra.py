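"""Group ICA of concatenated runs and slow-band spectral statistics.

Runs are temporally concatenated across animals, centred/whitened to
``n_comp`` dimensions and unmixed by negentropy maximization (FastICA,
fixed seed). Each component is a spatial map over ROI features plus a
per-animal time course. Component time courses are segmented by
condition; their amplitude (within-condition SD) and Welch power
spectral density feed the canonical slow-band comparisons:
slow-5 (0.01–0.027 Hz), slow-4 (0.027–0.073 Hz), slow-3 (0.073–0.1 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .containers import CONDITIONS, ConditionSegmentation, RoiTimeSeriesSet, group_mean_sem
from .edge_stats import paired_t
from .synthetic import SLOW_BANDS

log = logging.getLogger(__name__)


@dataclass
class ComponentSet:
    """Spatial maps + per-animal time courses from a group decomposition."""

    spatial_maps: np.ndarray       # (n_comp, n_features), unit L2 rows
    time_courses: np.ndarray       # (n_animals, n_comp, n_t)
    explained: np.ndarray          # variance-based ranking weight per comp
    feature_labels: list[str]
    component_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.component_labels:
            self.component_labels = [f"IC{k + 1:02d}" for k in range(self.n_comp)]

    @property
    def n_comp(self) -> int:
        return self.spatial_maps.shape[0]


def group_ica(tsset: RoiTimeSeriesSet, n_comp: int = 20,
              seed: int = 0, max_iter: int = 1000) -> ComponentSet:
    """Group ICA on temporally concatenated animal runs.

    Components are ranked by explained variance (squared mixing-column
    norm); the sign convention makes the largest-|value| map feature
    positive. Deterministic given ``seed``. ``n_comp`` greater than the
    feature rank is reduced with a warning.
    """
    X = np.concatenate([tsset.data[k].T for k in range(tsset.n_animals)], axis=0)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_comp > rank:
        log.warning("n_comp=%d exceeds data rank %d; reducing", n_comp, rank)
        n_comp = rank
    ica = FastICA(n_components=n_comp, whiten="unit-variance",
                  fun="logcosh", max_iter=max_iter, tol=1e-5,
                  random_state=int(seed))
    S = ica.fit_transform(X)                  # (total_t, n_comp), unit variance
    maps = ica.mixing_.T.astype(float)        # (n_comp, n_features)
    explained = (maps ** 2).sum(axis=1)
    order = np.argsort(explained)[::-1]
    maps, explained, S = maps[order], explained[order], S[:, order]
    # sign convention + unit-norm maps (scale moves into the time course)
    norms = np.linalg.norm(maps, axis=1)
    norms[norms == 0] = 1.0
    signs = np.sign(maps[np.arange(maps.shape[0]), np.argmax(np.abs(maps), axis=1)])
    signs[signs == 0] = 1.0
    maps = maps * (signs / norms)[:, None]
    S = S * (signs * norms)[None, :]
    # S holds n_animals stacked blocks of n_t rows each
    tcs = np.stack(np.split(S, tsset.n_animals, axis=0), axis=0)  # (n_animals, n_t, n_comp)
    tcs = np.transpose(tcs, (0, 2, 1))
    return ComponentSet(spatial_maps=maps, time_courses=tcs,
                        explained=explained, feature_labels=list(tsset.roi_labels))


def flag_components(cs: ComponentSet, nuisance: np.ndarray | None = None,
                    nuisance_corr_threshold: float = 0.6,
                    dominance_threshold: float = 0.5) -> list[int]:
    """Automatic component exclusion (replaces visual inspection).

    A component is excluded when its concatenated time course correlates
    above ``nuisance_corr_threshold`` with any nuisance regressor, or
    when a single feature carries more than ``dominance_threshold`` of
    its spatial-map energy. Returns the excluded component indices.
    """
    excluded: set[int] = set()
    energy = cs.spatial_maps ** 2
    frac = energy.max(axis=1) / energy.sum(axis=1)
    excluded.update(np.flatnonzero(frac > dominance_threshold).tolist())
    if nuisance is not None:
        nuis = np.asarray(nuisance)  # (n_animals, n_reg, n_t)
        for k in range(cs.n_comp):
            tc = cs.time_courses[:, k, :].reshape(-1)
            for r in range(nuis.shape[1]):
                reg = nuis[:, r, :].reshape(-1)
                c = np.corrcoef(tc, reg)[0, 1]
                if abs(c) > nuisance_corr_threshold:
                    excluded.add(k)
    if excluded:
        log.info("excluding %d/%d components: %s", len(excluded), cs.n_comp,
                 sorted(excluded))
    return sorted(excluded)


def condition_amplitude(time_course: np.ndarray,
                        segmentation: ConditionSegmentation,
                        mode: str = "sd") -> dict[str, float]:
    """Time-course amplitude per condition (SD by default, RMS optional)."""
    tc = np.asarray(time_course, dtype=float)
    if tc.ndim != 1:
        raise ValueError("time course must be 1-D on the run grid")
    out = {}
    for cond in CONDITIONS:
        seg = tc[segmentation.condition_slice(cond)]
        if seg.size == 0:
            raise ValueError(f"condition {cond!r} empty")
        out[cond] = float(np.sqrt(np.mean(seg ** 2)) if mode == "rms"
                          else np.std(seg))
    return out


@dataclass
class PsdEstimate:
    """One-sided Welch power spectral density with slow-band powers."""

    frequencies: np.ndarray       # Hz, ascending
    power: np.ndarray             # signal^2 / Hz
    segment_length_s: float
    overlap: float
    taper: str = "hann"
    band_powers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be ascending")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if not self.band_powers:
            self.band_powers = {name: band_power(self, b)
                                for name, b in SLOW_BANDS.items()}


def welch_psd(time_course: np.ndarray, tr_s: float = 1.0,
              segment_length_s: float = 256.0, overlap: float = 0.5,
              taper: str = "hann") -> PsdEstimate:
    """Welch PSD: averaged tapered overlapping modified periodograms.

    Defaults (256-s segments, 50% overlap, Hann taper) resolve 0.01 Hz
    while averaging many segments over a condition-concatenated series.
    A series shorter than one segment falls back to a single segment
    with a warning.
    """
    x = np.asarray(time_course, dtype=float)
    fs = 1.0 / tr_s
    nperseg = int(round(segment_length_s / tr_s))
    if x.size < nperseg:
        log.warning("series (%d) shorter than segment (%d); using one segment",
                    x.size, nperseg)
        nperseg = x.size
    f, p = sps.welch(x, fs=fs, window=taper, nperseg=nperseg,
                     noverlap=int(nperseg * overlap), detrend="constant",
                     scaling="density")
    return PsdEstimate(frequencies=f, power=p,
                       segment_length_s=nperseg * tr_s, overlap=overlap,
                       taper=taper, band_powers={})


def band_power(psd: PsdEstimate, band: tuple[float, float] | str) -> float:
    """Trapezoidal integral of the PSD over a frequency band.

    Band edges are interpolated onto the frequency grid so adjacent
    bands tile the spectrum additively.
    """
    if isinstance(band, str):
        band = SLOW_BANDS[band]
    lo, hi = band
    f, p = psd.frequencies, psd.power
    if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
        raise ValueError("band outside the estimated frequency range")
    inner = (f > lo) & (f < hi)
    grid = np.concatenate([[lo], f[inner], [hi]])
    vals = np.concatenate([[np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]])
    return float(np.trapezoid(vals, grid))


def band_power_contrast(tsset: RoiTimeSeriesSet,
                        segmentation: ConditionSegmentation,
                        time_courses: np.ndarray,
                        band: tuple[float, float] | str = "slow-5",
                        conditions: tuple[str, str] = ("vehicle", "drug"),
                        segment_length_s: float = 256.0,
                        overlap: float = 0.5) -> pd.DataFrame:
    """Per-genotype paired test of band power between two conditions.

    ``time_courses`` is ``(n_animals, n_t)`` — one series per animal
    (e.g. an ICA component time course or a network-mean signal). Band
    power is computed per animal per condition on the condition-
    concatenated samples, then compared with a paired t-test within each
    genotype. Returns a tidy DataFrame with one row per genotype.
    """
    tcs = np.asarray(time_courses, dtype=float)
    if tcs.shape != (tsset.n_animals, tsset.n_t):
        raise ValueError("time_courses must be (n_animals, n_t)")
    powers = {c: np.empty(tsset.n_animals) for c in conditions}
    for cond in conditions:
        sl = segmentation.condition_slice(cond)
        for k in range(tsset.n_animals):
            psd = welch_psd(tcs[k, sl], tsset.tr_s, segment_length_s, overlap)
            powers[cond][k] = band_power(psd, band)
    rows = []
    for genotype in sorted(set(tsset.genotypes)):
        mask = np.array([g == genotype for g in tsset.genotypes])
        a, b = powers[conditions[0]][mask], powers[conditions[1]][mask]
        res = paired_t(b - a)
        (m0, s0), (m1, s1) = group_mean_sem(a), group_mean_sem(b)
        rows.append({
            "genotype": genotype, "band": band if isinstance(band, str) else str(band),
            f"{conditions[0]}_mean": m0, f"{conditions[0]}_sem": s0,
            f"{conditions[1]}_mean": m1, f"{conditions[1]}_sem": s1,
            "t_stat": res.t, "df": res.df, "p": res.p,
        })
    return pd.DataFrame(rows)
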