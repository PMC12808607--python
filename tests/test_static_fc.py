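"""Static FC: Pearson matrices, Fisher z, contrasts, FC variability."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pharmfc as pf
from pharmfc.containers import ConditionSegmentation, Interval

from .conftest import pearson_oracle


class TestFcMatrix:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 50))
        fc = pf.fc_matrix(x)
        for i in range(5):
            for j in range(5):
                assert fc.values[i, j] == pytest.approx(
                    pearson_oracle(x[i], x[j]), abs=1e-12)

    def test_perfect_and_anti_correlation(self):
        x = np.vstack([np.arange(10.0), np.arange(10.0), -np.arange(10.0)])
        fc = pf.fc_matrix(x)
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)
        assert np.allclose(fc.values, fc.values.T)
        assert np.all(np.diag(fc.values) == 1.0)

    def test_hand_example(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0]])
        expected = pearson_oracle(x[0], x[1])
        assert pf.fc_matrix(x).values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_constant_roi_gives_nan_with_warning(self, caplog):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        with caplog.at_level("WARNING", logger="pharmfc.static_fc"):
            fc = pf.fc_matrix(x)
        assert np.isnan(fc.values[0, 1])
        assert "constant" in caplog.text

    def test_too_short_interval_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            pf.fc_matrix(np.zeros((2, 3)))

    def test_roi_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 80))
        perm = rng.permutation(6)
        a = pf.fc_matrix(x).values[np.ix_(perm, perm)]
        b = pf.fc_matrix(x[perm]).values
        assert a == pytest.approx(b, abs=1e-12)


class TestFisherZ:
    def test_closed_form_values(self):
        r = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -0.3], [0.5, -0.3, 1.0]])
        z = pf.fisher_z(pf.FcMatrix(r, "r"))
        assert z.space == "z"
        assert z.values[0, 1] == 0.0
        assert z.values[0, 2] == pytest.approx(np.arctanh(0.5))
        assert z.values[1, 2] == pytest.approx(np.arctanh(-0.3))
        assert np.all(np.isnan(np.diag(z.values)))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_roundtrip_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((4, 30))
        fc = pf.fc_matrix(x)
        back = pf.inverse_fisher_z(pf.fisher_z(fc))
        assert back.values == pytest.approx(fc.values, abs=1e-12)

    def test_extreme_r_clamped_finite(self, caplog):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        with caplog.at_level("WARNING", logger="pharmfc.static_fc"):
            z = pf.fisher_z(pf.FcMatrix(r, "r"))
        assert np.isfinite(z.values[0, 1])
        assert "clamp" in caplog.text

    def test_space_contracts_enforced(self):
        r = pf.FcMatrix(np.eye(2), "r")
        with pytest.raises(ValueError):
            pf.inverse_fisher_z(r)
        z = pf.fisher_z(r)
        with pytest.raises(ValueError):
            pf.fisher_z(z)


class TestIntervalDifference:
    def test_identical_matrices_zero(self):
        m = pf.FcMatrix(np.full((3, 3), 0.4), "z")
        assert np.all(pf.interval_difference(m, m).values == 0.0)

    def test_space_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pf.interval_difference(pf.FcMatrix(np.eye(3), "r"),
                                   pf.FcMatrix(np.eye(3), "z"))

    def test_stationary_group_mean_difference_near_zero(self, null_cohort):
        full, gt = null_cohort
        ts = full.subset("WT")   # KO twins share the same random streams
        seg = pf.segment_conditions(ts)
        z = pf.interval_fc(ts, seg)
        diff = z[:, 1] - z[:, 0]          # two baseline intervals
        iu = np.triu_indices(ts.n_roi, 1)
        # the iid Fisher-z SE applies to white-spectrum ROIs; edges that
        # touch the narrow-band oscillator ROIs carry extra autocorrelation
        osc = {ts.roi_index(r) for r in gt.config.oscillator_spec[0].rois}
        keep = np.array([i not in osc and j not in osc
                         for i, j in zip(iu[0], iu[1])])
        gm = diff[:, iu[0][keep], iu[1][keep]].mean(axis=0)
        se = np.sqrt(2.0 / (600 - 3) / ts.n_animals)
        assert np.mean(np.abs(gm) < 3 * se) > 0.98
        assert np.abs(gm).mean() < se

    def test_modulated_edges_show_sign_correct_deltas(self, preprocessed):
        pre, seg, z, gt = preprocessed
        wt = np.array([g == "WT" for g in pre.genotypes])
        m_drug1 = next(m for m, iv in enumerate(seg)
                       if iv.condition == "drug" and iv.index == 0)
        m_veh3 = next(m for m, iv in enumerate(seg)
                      if iv.condition == "vehicle" and iv.index == 2)
        diff = np.nanmean(z[wt, m_drug1] - z[wt, m_veh3], axis=0)
        for (a, b), delta, *_ in gt.modulated_edges:
            i, j = pre.roi_index(a), pre.roi_index(b)
            assert np.sign(diff[i, j]) == np.sign(delta)
            assert abs(diff[i, j]) > 0.2


class TestGenotypeBaselineContrast:
    def test_identical_groups_zero_and_single_animal_difference(self):
        rng = np.random.default_rng(2)
        z1 = rng.standard_normal((4, 4))
        z1 = (z1 + z1.T) / 2
        m1 = pf.FcMatrix(z1, "z")
        zero = pf.genotype_baseline_contrast([m1], [m1])
        assert np.all(zero.values == 0.0)
        z2 = pf.FcMatrix(z1 + 1.0, "z")
        single = pf.genotype_baseline_contrast([m1], [z2])
        assert single.values == pytest.approx(np.ones((4, 4)))

    def test_altered_ko_block_dominates_map(self):
        no_art = pf.InjectionArtifactSpec(edges=(), global_amplitude=0.0)
        wt_cfg = pf.SimulationConfig(seed=31, n_animals_per_genotype=2,
                                     drug_effect_edges=[],
                                     injection_artifact_spec=no_art)
        ko_cfg = pf.SimulationConfig(
            seed=32, n_animals_per_genotype=2, drug_effect_edges=[],
            injection_artifact_spec=no_art,
            baseline_covariance_spec=pf.BlockCovarianceSpec(within_r=0.55))
        seg = None
        mats = {}
        for name, cfg in (("WT", wt_cfg), ("KO", ko_cfg)):
            ts, _ = pf.simulate_cohort(cfg)
            sub = ts.subset("WT")  # one genotype's animals from each cohort
            seg = pf.segment_conditions(sub)
            z = pf.interval_fc(sub, seg)
            mats[name] = [pf.FcMatrix(z[k, m], "z")
                          for k in range(sub.n_animals) for m in (0, 1)]
        contrast = pf.genotype_baseline_contrast(mats["WT"], mats["KO"])
        block = pf.SimulationConfig().block_of()
        iu = np.triu_indices(30, 1)
        within = block[iu[0]] == block[iu[1]]
        vals = contrast.values[iu]
        assert vals[within].mean() > 0.2
        assert abs(vals[~within].mean()) < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pf.genotype_baseline_contrast([], [pf.FcMatrix(np.eye(2), "z")])


class TestFcVariability:
    @staticmethod
    def _one_interval_seg():
        return ConditionSegmentation(
            intervals=[Interval("baseline", 0, 0, 600)],
            interval_length_s=600.0, tr_s=1.0)

    def test_equal_edges_zero_variance(self):
        z = np.zeros((1, 1, 3, 3))
        z[0, 0] += 0.5
        out = pf.fc_variability(z, self._one_interval_seg(), "baseline")
        assert out[0] == 0.0

    def test_hand_oracle_population_variance(self):
        z = np.zeros((1, 1, 3, 3))
        z[0, 0, 0, 1] = z[0, 0, 1, 0] = 0.1
        z[0, 0, 0, 2] = z[0, 0, 2, 0] = 0.2
        z[0, 0, 1, 2] = z[0, 0, 2, 1] = 0.6
        out = pf.fc_variability(z, self._one_interval_seg(), "baseline")
        vals = np.array([0.1, 0.2, 0.6])
        assert out[0] == pytest.approx(((vals - vals.mean()) ** 2).mean())

    def test_invariant_to_roi_ordering(self, preprocessed):
        pre, seg, z, _ = preprocessed
        perm = np.random.default_rng(3).permutation(pre.n_roi)
        zp = z[:, :, perm][:, :, :, perm]
        a = pf.fc_variability(z, seg, "vehicle")
        b = pf.fc_variability(zp, seg, "vehicle")
        assert a == pytest.approx(b, abs=1e-12)

    def test_identical_cohorts_give_t_near_zero(self, preprocessed):
        pre, seg, z, _ = preprocessed
        table = pf.fc_variability_table(pre, z, seg)
        clone = table.copy()
        clone["genotype"] = ["KO" if g == "WT" else "WT" for g in clone["genotype"]]
        import pandas as pd
        both = pd.concat([table[table.genotype == "WT"],
                          clone[clone.genotype == "KO"]])
        t, df, p, _ = pf.compare_variability(both, "baseline")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert df == 12
        assert p == pytest.approx(1.0)

    def test_vehicle_variability_reflects_injection_artifacts(self):
        # paired comparison at the same seed: the injection-common edge
        # shifts widen the spread of vehicle-condition edge z values in
        # both genotypes, while baseline is untouched
        with_art = pf.SimulationConfig(seed=41, drug_effect_edges=[])
        without_art = pf.SimulationConfig(
            seed=41, drug_effect_edges=[],
            injection_artifact_spec=pf.InjectionArtifactSpec(
                edges=(), global_amplitude=0.0))
        tables = {}
        for name, cfg in (("with", with_art), ("without", without_art)):
            ts, _ = pf.simulate_cohort(cfg)
            seg = pf.segment_conditions(ts)
            z = pf.interval_fc(ts, seg)
            tables[name] = pf.fc_variability_table(ts, z, seg)
        for genotype in ("WT", "KO"):
            for name in ("with", "without"):
                tables[name + genotype] = tables[name][
                    tables[name].genotype == genotype]
            veh_w = tables["with" + genotype].query(
                "condition == 'vehicle'")["variability"].mean()
            veh_wo = tables["without" + genotype].query(
                "condition == 'vehicle'")["variability"].mean()
            base_w = tables["with" + genotype].query(
                "condition == 'baseline'")["variability"].mean()
            base_wo = tables["without" + genotype].query(
                "condition == 'baseline'")["variability"].mean()
            assert veh_w > veh_wo
            assert base_w == pytest.approx(base_wo, rel=0.05)
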