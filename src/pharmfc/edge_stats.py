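"""Edge-wise paired statistics for the drug challenge.

The drug contrast compares, per edge and animal, the Fisher-z FC of the
first post-drug interval against the mean of the two terminal intervals
(last vehicle interval and last drug interval) — a design that isolates
transient drug effects from slow time-dependent drift. Per-edge paired
t-tests are corrected with Benjamini–Hochberg FDR, and edges that are
also significant (same direction) in the mirrored post-vehicle contrast
are flagged as injection artifacts and removed from the significant set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConditionSegmentation


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


@dataclass
class EdgeContrastTable:
    """Per-edge paired-contrast results.

    One row per unordered ROI pair with the mean z difference, t statistic,
    raw and FDR-adjusted p, direction, artifact flag and significance call
    (``significant`` requires ``p_fdr < alpha`` and no artifact flag).
    """

    df: pd.DataFrame
    alpha: float
    contrast: str = ""

    COLUMNS = ("roi_i", "roi_j", "mean_diff_z", "t_stat", "df", "p_raw",
               "p_fdr", "direction", "artifact_flag", "significant")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.df[self.df["significant"]].reset_index(drop=True)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.df[["roi_i", "roi_j"]].itertuples(index=False)))


def _edge_index(roi_labels: list[str]) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    n = len(roi_labels)
    iu, ju = np.triu_indices(n, k=1)
    pairs = [(roi_labels[i], roi_labels[j]) for i, j in zip(iu, ju)]
    return iu, ju, pairs


def _contrast_values(z_by_interval: np.ndarray, segmentation: ConditionSegmentation,
                     first_of: str, terminal: tuple[str, str],
                     roi_labels: list[str]):
    idx = {(iv.condition, iv.index): m for m, iv in enumerate(segmentation)}
    conds = segmentation.counts()
    for cond in {first_of, *terminal}:
        if conds.get(cond, 0) < 1:
            raise ValueError(f"condition {cond!r} has no intervals")
    m_first = idx[(first_of, 0)]
    m_t1 = idx[(terminal[0], conds[terminal[0]] - 1)]
    m_t2 = idx[(terminal[1], conds[terminal[1]] - 1)]
    iu, ju, pairs = _edge_index(roi_labels)
    x = z_by_interval[:, m_first, iu, ju]                       # (n_animals, n_edges)
    y = 0.5 * (z_by_interval[:, m_t1, iu, ju] + z_by_interval[:, m_t2, iu, ju])
    return x, y, pairs


def amylin_contrast_values(z_by_interval: np.ndarray,
                           segmentation: ConditionSegmentation,
                           roi_labels: list[str]):
    """Paired (x, y) per animal per edge for the drug contrast.

    x = z of the first drug interval; y = mean of z over the last vehicle
    and last drug intervals. ``z_by_interval`` is the ``interval_fc``
    stack (z-space, shape ``(n_animals, n_intervals, n_roi, n_roi)``).
    Returns ``(x, y, edge_pairs)`` with x, y of shape (n_animals, n_edges).
    """
    return _contrast_values(z_by_interval, segmentation, "drug",
                            ("vehicle", "drug"), roi_labels)


def vehicle_mirror_contrast_values(z_by_interval: np.ndarray,
                                   segmentation: ConditionSegmentation,
                                   roi_labels: list[str]):
    """Mirrored contrast used for artifact flagging.

    x = z of the first vehicle interval; y = mean of z over the last
    baseline and last vehicle intervals — the symmetric construction of
    the drug contrast, applied to the vehicle injection.
    """
    return _contrast_values(z_by_interval, segmentation, "vehicle",
                            ("baseline", "vehicle"), roi_labels)


def paired_t(diffs: np.ndarray) -> PairedTResult:
    """One-sample t on paired differences: t = mean / (sd / sqrt(n)),
    df = n - 1, two-sided p.

    All-zero differences give t = 0, p = 1; zero variance with non-zero
    mean is flagged degenerate with p -> 0.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 finite paired differences")
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(0.0, df, 1.0, False)
        return PairedTResult(np.inf if mean > 0 else -np.inf, df, 0.0, True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTResult(float(t), df, float(min(p, 1.0)), False)


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (monotone, capped at 1).

    NaN inputs are excluded from the adjustment and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.sum():
        _, adj, _, _ = multipletests(p[finite], method="fdr_bh")
        out[finite] = adj
    return out


def edge_contrast_table(x: np.ndarray, y: np.ndarray,
                        edge_pairs: list[tuple[str, str]],
                        alpha: float = 0.01,
                        contrast: str = "drug") -> EdgeContrastTable:
    """Build the per-edge paired-contrast table from (x, y) values."""
    d = x - y
    n_edges = d.shape[1]
    if len(edge_pairs) != n_edges:
        raise ValueError("edge list does not match value columns")
    rows = []
    for e in range(n_edges):
        res = paired_t(d[:, e])
        rows.append({
            "roi_i": edge_pairs[e][0], "roi_j": edge_pairs[e][1],
            "mean_diff_z": float(np.nanmean(d[:, e])),
            "t_stat": res.t, "df": res.df, "p_raw": res.p,
            "direction": "increase" if np.nanmean(d[:, e]) >= 0 else "decrease",
            "degenerate": res.degenerate,
        })
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_bh(table["p_raw"].to_numpy())
    table["artifact_flag"] = False
    table["significant"] = table["p_fdr"] < alpha
    return EdgeContrastTable(table, alpha=alpha, contrast=contrast)


def flag_injection_artifacts(vehicle_table: EdgeContrastTable,
                             drug_table: EdgeContrastTable) -> EdgeContrastTable:
    """Exclude injection-mediated effects from the drug table.

    An edge significant in BOTH the mirrored vehicle contrast and the
    drug contrast with matching direction is marked ``artifact_flag`` and
    loses its significance call (conservative: opposite-direction edges
    are retained).
    """
    if vehicle_table.edge_set() != drug_table.edge_set():
        raise ValueError("vehicle and drug tables must share the edge set")
    veh = vehicle_table.df.set_index(["roi_i", "roi_j"])
    out = drug_table.df.copy()
    key = list(map(tuple, out[["roi_i", "roi_j"]].itertuples(index=False)))
    veh_sig = veh.loc[key, "significant"].to_numpy()
    veh_dir = veh.loc[key, "direction"].to_numpy()
    flag = veh_sig & out["significant"].to_numpy() & (veh_dir == out["direction"].to_numpy())
    out["artifact_flag"] = flag
    out.loc[flag, "significant"] = False
    return EdgeContrastTable(out, alpha=drug_table.alpha, contrast=drug_table.contrast)


def export_edges(table: EdgeContrastTable, path: str | Path) -> tuple[Path, Path]:
    """Write the full table plus a significant-edge list.

    The edge list (source, target, direction, p_fdr) is consumable by
    external connectogram / brain-render tools; rows are ordered by ROI
    label lexicographically for determinism.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    full = table.df.sort_values(["roi_i", "roi_j"]).reset_index(drop=True)
    full_f = path / "edge_contrast_full.csv"
    full.to_csv(full_f, index=False, float_format="%.10g")
    sig = full[full["significant"]][["roi_i", "roi_j", "direction", "p_fdr"]]
    sig = sig.rename(columns={"roi_i": "source", "roi_j": "target"})
    sig_f = path / "significant_edges.csv"
    sig.to_csv(sig_f, index=False, float_format="%.10g")
    return full_f, sig_f


def read_edges(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for ``export_edges`` output."""
    return pd.read_csv(Path(path))
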