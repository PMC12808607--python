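"""Interval-wise static functional connectivity.

Pairwise Pearson correlation matrices per condition interval, the Fisher
z transform (variance-stabilizing, applied before any parametric
statistics), interval-difference maps, the genotype baseline contrast,
and the per-animal FC-variability summary (variance of the pooled
off-diagonal z values within a condition).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CONDITIONS, ConditionSegmentation, RoiTimeSeriesSet, group_mean_sem

log = logging.getLogger(__name__)

R_CLAMP = 1.0 - 1e-7


@dataclass
class FcMatrix:
    """Symmetric ROI x ROI connectivity matrix in r- or z-space."""

    values: np.ndarray
    space: str = "r"  # 'r' (unit diagonal) or 'z' (diagonal excluded/NaN)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if self.space not in ("r", "z"):
            raise ValueError("space must be 'r' or 'z'")
        self.values = v

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


def _pearson_matrix(signal: np.ndarray) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1)
    bad = sd == 0
    if bad.any():
        log.warning("%d constant ROI(s): correlations set to NaN", bad.sum())
    sd_safe = np.where(bad, 1.0, sd)
    xn = xc / sd_safe[:, None]
    r = xn @ xn.T / x.shape[1]
    r = np.clip(r, -1.0, 1.0)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    return r


def fc_matrix(signal: np.ndarray, provenance: dict | None = None) -> FcMatrix:
    """Pairwise Pearson correlation of ROI rows over one interval.

    Constant ROIs yield NaN rows/columns with a logged warning.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValueError("signal must be (n_roi, n_t)")
    if signal.shape[1] < 4:
        raise ValueError("interval must contain at least 4 samples")
    return FcMatrix(_pearson_matrix(signal), "r", provenance or {})


def fisher_z(fc: FcMatrix) -> FcMatrix:
    """Elementwise atanh of off-diagonal correlations.

    Values with |r| >= 1 - 1e-7 are clamped before the transform (logged);
    the diagonal becomes NaN (self-correlation carries no information in
    z-space).
    """
    if fc.space != "r":
        raise ValueError("fisher_z expects an r-space matrix")
    r = fc.values.copy()
    off = r.copy()
    np.fill_diagonal(off, 0.0)
    n_clamped = int(np.nansum(np.abs(off) > R_CLAMP))
    if n_clamped > 0:
        log.warning("clamping %d |r| values at %.0e before atanh", n_clamped, 1 - R_CLAMP)
    z = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    np.fill_diagonal(z, np.nan)
    return FcMatrix(z, "z", dict(fc.provenance))


def inverse_fisher_z(fc: FcMatrix) -> FcMatrix:
    """tanh back to r-space; diagonal restored to 1."""
    if fc.space != "z":
        raise ValueError("inverse_fisher_z expects a z-space matrix")
    r = np.tanh(fc.values)
    np.fill_diagonal(r, 1.0)
    return FcMatrix(r, "r", dict(fc.provenance))


def interval_fc(tsset: RoiTimeSeriesSet, segmentation: ConditionSegmentation,
                space: str = "z") -> np.ndarray:
    """Stack of per-animal, per-interval FC matrices.

    Returns shape ``(n_animals, n_intervals, n_roi, n_roi)`` in the
    requested space ('z' by default: statistics happen in z-space).
    """
    n_iv = segmentation.n_intervals
    out = np.empty((tsset.n_animals, n_iv, tsset.n_roi, tsset.n_roi))
    for k in range(tsset.n_animals):
        for m, iv in enumerate(segmentation):
            fc = fc_matrix(tsset.data[k][:, iv.slice],
                           provenance={"animal": tsset.animal_ids[k],
                                       "condition": iv.condition,
                                       "interval": iv.index})
            out[k, m] = fisher_z(fc).values if space == "z" else fc.values
    return out


def interval_difference(curr: FcMatrix, prev: FcMatrix) -> FcMatrix:
    """Elementwise current-minus-preceding interval difference map."""
    if curr.space != prev.space:
        raise ValueError("interval_difference requires matching spaces")
    if curr.n_roi != prev.n_roi:
        raise ValueError("ROI sets differ")
    return FcMatrix(curr.values - prev.values, curr.space,
                    {"contrast": "interval_difference"})


def group_mean_fc(mats: list[FcMatrix] | np.ndarray, space: str = "z") -> FcMatrix:
    """NaN-aware group mean of same-space matrices (averaged in z-space)."""
    if isinstance(mats, np.ndarray):
        arr = mats
    else:
        spaces = {m.space for m in mats}
        if spaces != {space}:
            raise ValueError(f"expected all matrices in {space!r}-space")
        arr = np.stack([m.values for m in mats])
    if arr.shape[0] == 0:
        raise ValueError("empty group")
    n_nan = int(np.isnan(arr).any(axis=0).sum())
    if n_nan:
        log.info("group mean excludes NaN entries pairwise on %d edges", n_nan)
    with warnings.catch_warnings():
        # the z-space diagonal is NaN by design; an all-NaN mean is expected
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
    return FcMatrix(mean, space, {"contrast": "group_mean"})


def genotype_baseline_contrast(wt: list[FcMatrix], ko: list[FcMatrix]) -> FcMatrix:
    """Per-edge mean(KO) - mean(WT) over baseline-interval z matrices."""
    if not wt or not ko:
        raise ValueError("both genotype groups must be non-empty")
    mko = group_mean_fc(ko, "z")
    mwt = group_mean_fc(wt, "z")
    return FcMatrix(mko.values - mwt.values, "z",
                    {"contrast": "KO_minus_WT_baseline"})


# ---------------------------------------------------------------------------
# FC variability (per-animal spread of edge strengths within a condition)
# ---------------------------------------------------------------------------

def fc_variability(z_by_interval: np.ndarray,
                   segmentation: ConditionSegmentation,
                   condition: str) -> np.ndarray:
    """Per-animal FC variability for one condition.

    Defined as the population variance of the off-diagonal upper-triangle
    z values pooled over that condition's interval matrices — one scalar
    per animal. ``z_by_interval`` is the ``interval_fc`` stack (z-space).
    """
    ivs = segmentation.condition(condition)
    if not ivs:
        raise ValueError(f"condition {condition!r} has no intervals")
    idx = [m for m, iv in enumerate(segmentation) if iv.condition == condition]
    n_roi = z_by_interval.shape[-1]
    iu = np.triu_indices(n_roi, k=1)
    out = np.empty(z_by_interval.shape[0])
    for k in range(z_by_interval.shape[0]):
        pooled = np.concatenate([z_by_interval[k, m][iu] for m in idx])
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size == 0:
            raise ValueError("all edges NaN in condition matrices")
        out[k] = np.var(pooled)  # population variance (ddof=0)
    return out


def fc_variability_table(tsset: RoiTimeSeriesSet, z_by_interval: np.ndarray,
                         segmentation: ConditionSegmentation) -> pd.DataFrame:
    """Tidy per-animal x condition variability table with group summaries."""
    rows = []
    for cond in CONDITIONS:
        vals = fc_variability(z_by_interval, segmentation, cond)
        for k in range(tsset.n_animals):
            rows.append({"animal": tsset.animal_ids[k],
                         "genotype": tsset.genotypes[k],
                         "condition": cond,
                         "variability": vals[k]})
    return pd.DataFrame(rows)


def compare_variability(table: pd.DataFrame, condition: str,
                        group_a: str = "KO", group_b: str = "WT"):
    """Two-sample t-test (df = n1 + n2 - 2) of FC variability between
    genotypes for one condition; returns (t, df, p, mean_sem_by_group)."""
    sub = table[table["condition"] == condition]
    a = sub.loc[sub["genotype"] == group_a, "variability"].to_numpy()
    b = sub.loc[sub["genotype"] == group_b, "variability"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 animals per group")
    t, p = stats.ttest_ind(a, b)
    summary = {
        group_a: group_mean_sem(a),
        group_b: group_mean_sem(b),
    }
    return float(t), a.size + b.size - 2, float(p), summary
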