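"""Paired edge contrast, t statistics, BH-FDR and artifact exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import pharmfc as pf
from pharmfc.containers import ConditionSegmentation, Interval

from .conftest import bh_stepup_oracle


def _default_seg():
    ivs = []
    pos = 0
    for cond, n in (("baseline", 2), ("vehicle", 3), ("drug", 3)):
        for j in range(n):
            ivs.append(Interval(cond, j, pos, pos + 600))
            pos += 600
    return ConditionSegmentation(ivs, 600.0, 1.0)


def _zstack_with(edge_vals: dict[int, float], n_roi=3, n_animals=1):
    """z stack with one controllable edge (0,1) per interval index."""
    z = np.zeros((n_animals, 8, n_roi, n_roi))
    for m, v in edge_vals.items():
        z[:, m, 0, 1] = z[:, m, 1, 0] = v
    return z


class TestContrastValues:
    def test_hand_example(self):
        # vehicle3 z = 0.2, drug3 z = 0.4, drug1 z = 0.9 -> (0.9, 0.3)
        z = _zstack_with({4: 0.2, 7: 0.4, 5: 0.9})
        x, y, pairs = pf.amylin_contrast_values(z, _default_seg(), ["A", "B", "C"])
        e = pairs.index(("A", "B"))
        assert x[0, e] == pytest.approx(0.9)
        assert y[0, e] == pytest.approx(0.3)

    def test_zero_difference_when_first_equals_terminal_mean(self):
        z = _zstack_with({4: 0.2, 7: 0.4, 5: 0.3})
        x, y, _ = pf.amylin_contrast_values(z, _default_seg(), ["A", "B", "C"])
        assert x[0, 0] - y[0, 0] == pytest.approx(0.0)

    def test_vehicle_mirror_uses_baseline_and_vehicle_terminals(self):
        z = _zstack_with({1: 0.6, 4: 0.2, 2: 0.9})
        x, y, _ = pf.vehicle_mirror_contrast_values(z, _default_seg(),
                                                    ["A", "B", "C"])
        assert x[0, 0] == pytest.approx(0.9)   # first vehicle interval
        assert y[0, 0] == pytest.approx(0.4)   # mean(last baseline, last vehicle)

    def test_mean_paired_difference_tracks_injected_envelope(self, preprocessed):
        pre, seg, z, gt = preprocessed
        wt = np.array([g == "WT" for g in pre.genotypes])
        x, y, pairs = pf.amylin_contrast_values(z[wt], seg, pre.roi_labels)
        for (a, b), delta, *_ in gt.modulated_edges:
            e = pairs.index((a, b)) if (a, b) in pairs else pairs.index((b, a))
            d = (x[:, e] - y[:, e]).mean()
            assert np.sign(d) == np.sign(delta)
            assert abs(d) > 0.3   # transient peak minus terminal residual


class TestPairedT:
    def test_degenerate_and_symmetric_cases(self):
        res = pf.paired_t(np.array([1.0, 1.0, 1.0, 1.0]))
        assert res.degenerate and res.p == 0.0
        res = pf.paired_t(np.array([-1.0, 1.0]))
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        res = pf.paired_t(np.zeros(5))
        assert res.t == 0.0 and res.p == 1.0 and not res.degenerate

    def test_textbook_formula_oracle(self):
        d = np.array([0.3, 0.1, 0.4, 0.2, 0.5, 0.1, 0.2])
        res = pf.paired_t(d)
        n = d.size
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        assert res.t == pytest.approx(t_hand, abs=1e-10)
        assert res.df == n - 1
        t_sp, p_sp = stats.ttest_1samp(d, 0.0)
        assert res.t == pytest.approx(t_sp, abs=1e-10)
        assert res.p == pytest.approx(p_sp, abs=1e-12)

    def test_published_critical_value_at_df6(self):
        # |t| >= 2.447 <=> p <= 0.05 for 7 animals (df = 6)
        for t_val, sig in ((2.5, True), (2.447, True), (2.4, False)):
            base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
            shift = base - base.mean() + t_val * base.std(ddof=1) / np.sqrt(7)
            res = pf.paired_t(shift)
            assert res.t == pytest.approx(t_val, abs=1e-10)
            assert (res.p <= 0.05) == sig

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            pf.paired_t(np.array([1.0]))


class TestFdrBh:
    def test_hand_stepup_example_all_rejected(self):
        adj = pf.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert np.all(adj < 0.05)

    def test_single_p_unchanged(self):
        assert pf.fdr_bh(np.array([0.123]))[0] == pytest.approx(0.123)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 60))
    def test_matches_stepup_oracle_and_is_monotone(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m)
        adj = pf.fdr_bh(p)
        assert adj == pytest.approx(bh_stepup_oracle(p), abs=1e-12)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_nan_excluded_and_returned_nan(self):
        adj = pf.fdr_bh(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(adj[1])
        assert adj[[0, 2]] == pytest.approx(bh_stepup_oracle(np.array([0.01, 0.04])))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            pf.fdr_bh(np.array([0.1, 1.2]))

    def test_empirical_fdr_controlled_under_uniform_null(self):
        # 200 replicates of m = 500 null edges, n = 7 paired differences:
        # p values computed with the textbook t formula (oracle path),
        # adjusted by the package; empirical FDR <= q + 2 x MC SE.
        rng = np.random.default_rng(11)
        q, reps, m, n = 0.05, 200, 500, 7
        fdp = []
        for _ in range(reps):
            d = rng.standard_normal((n, m))
            t = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(n))
            p = 2 * stats.t.sf(np.abs(t), n - 1)
            fdp.append(float(np.mean(pf.fdr_bh(p) < q) > 0))
        mc_se = np.sqrt(q * (1 - q) / reps)
        assert np.mean(fdp) <= q + 2 * mc_se


class TestContrastTableAndArtifacts:
    @staticmethod
    def _table(sig_edges, directions, pairs, alpha=0.01):
        rows = []
        for e, pair in enumerate(pairs):
            s = pair in sig_edges
            rows.append({
                "roi_i": pair[0], "roi_j": pair[1],
                "mean_diff_z": 0.5 if directions.get(pair, "increase") == "increase" else -0.5,
                "t_stat": 8.0 if s else 0.5, "df": 6,
                "p_raw": 1e-5 if s else 0.6, "p_fdr": 1e-4 if s else 0.9,
                "direction": directions.get(pair, "increase"),
                "artifact_flag": False, "significant": s})
        return pf.EdgeContrastTable(pd.DataFrame(rows), alpha=alpha)

    PAIRS = [("A", "B"), ("A", "C"), ("B", "C")]

    def test_drug_only_edge_retained(self):
        veh = self._table(set(), {}, self.PAIRS)
        drug = self._table({("A", "B")}, {}, self.PAIRS)
        out = pf.flag_injection_artifacts(veh, drug)
        row = out.df.set_index(["roi_i", "roi_j"]).loc[("A", "B")]
        assert row["significant"] and not row["artifact_flag"]

    def test_common_edge_with_matching_direction_flagged(self):
        veh = self._table({("A", "B")}, {}, self.PAIRS)
        drug = self._table({("A", "B"), ("B", "C")}, {}, self.PAIRS)
        out = pf.flag_injection_artifacts(veh, drug)
        idx = out.df.set_index(["roi_i", "roi_j"])
        assert idx.loc[("A", "B"), "artifact_flag"]
        assert not idx.loc[("A", "B"), "significant"]
        assert idx.loc[("B", "C"), "significant"]

    def test_opposite_direction_not_flagged(self):
        veh = self._table({("A", "B")}, {("A", "B"): "decrease"}, self.PAIRS)
        drug = self._table({("A", "B")}, {("A", "B"): "increase"}, self.PAIRS)
        out = pf.flag_injection_artifacts(veh, drug)
        assert not out.df["artifact_flag"].any()

    def test_empty_vehicle_significance_leaves_table_unchanged(self):
        veh = self._table(set(), {}, self.PAIRS)
        drug = self._table({("A", "C")}, {}, self.PAIRS)
        out = pf.flag_injection_artifacts(veh, drug)
        pd.testing.assert_frame_equal(out.df, drug.df)

    def test_edge_set_mismatch_rejected(self):
        veh = self._table(set(), {}, self.PAIRS)
        drug = self._table(set(), {}, [("A", "B"), ("A", "D"), ("B", "D")])
        with pytest.raises(ValueError, match="edge set"):
            pf.flag_injection_artifacts(veh, drug)

    def test_synthetic_artifact_edges_flagged_in_both_genotypes(self, preprocessed):
        pre, seg, z, gt = preprocessed
        for genotype in ("WT", "KO"):
            mask = np.array(
                [g == genotype for g in pre.genotypes])
            x, y, pairs = pf.amylin_contrast_values(z[mask], seg, pre.roi_labels)
            drug = pf.edge_contrast_table(x, y, pairs, alpha=0.01)
            xv, yv, _ = pf.vehicle_mirror_contrast_values(z[mask], seg, pre.roi_labels)
            veh = pf.edge_contrast_table(xv, yv, pairs, alpha=0.01)
            out = pf.flag_injection_artifacts(veh, drug)
            flagged = {frozenset((r.roi_i, r.roi_j))
                       for r in out.df[out.df.artifact_flag].itertuples()}
            assert {frozenset(e) for e in gt.artifact_pairs()} <= flagged


class TestExport:
    def test_empty_table_and_roundtrip(self, tmp_path):
        pairs = [("A", "B")]
        tab = TestContrastTableAndArtifacts._table(set(), {}, pairs)
        full_f, sig_f = pf.export_edges(tab, tmp_path)
        sig = pd.read_csv(sig_f)
        assert len(sig) == 0
        assert list(sig.columns) == ["source", "target", "direction", "p_fdr"]
        back = pd.read_csv(full_f)
        assert len(back) == 1

    def test_significant_edge_count_matches_ground_truth(self, preprocessed, tmp_path):
        pre, seg, z, gt = preprocessed
        wt = np.array([g == "WT" for g in pre.genotypes])
        x, y, pairs = pf.amylin_contrast_values(z[wt], seg, pre.roi_labels)
        drug = pf.edge_contrast_table(x, y, pairs, alpha=0.01)
        xv, yv, _ = pf.vehicle_mirror_contrast_values(z[wt], seg, pre.roi_labels)
        veh = pf.edge_contrast_table(xv, yv, pairs, alpha=0.01)
        out = pf.flag_injection_artifacts(veh, drug)
        _, sig_f = pf.export_edges(out, tmp_path)
        sig = pd.read_csv(sig_f)
        assert len(sig) == int(out.df["significant"].sum())
        # deterministic lexicographic row ordering
        full = pd.read_csv(tmp_path / "edge_contrast_full.csv")
        key = list(zip(full["roi_i"], full["roi_j"]))
        assert key == sorted(key)
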