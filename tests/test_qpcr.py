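"""qPCR QC rules, delta-Cq normalizations, recalibration, platform mapping."""

import numpy as np
import pandas as pd
import pytest

from mirsig import (
    CqMatrix,
    SearchConfig,
    choose_references,
    generate_cq,
    global_mean_normalize,
    impute_undetected,
    map_external_platform,
    mlp_predict,
    mlp_search,
    qc_filter,
    recalibrate_signature,
    reference_dcq,
)
from mirsig.qpcr import ReferenceSet, dcq_expression
from tests.conftest import make_expression


def _cq(values, efficiency=None, melt=None, negctrl=None):
    values = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"a{i}" for i in range(np.shape(values)[0])],
        columns=[f"s{j}" for j in range(np.shape(values)[1])],
    )
    eff = pd.DataFrame(
        efficiency if efficiency is not None else np.full(values.shape, 1.9),
        index=values.index,
        columns=values.columns,
    )
    mf = pd.DataFrame(
        melt if melt is not None else np.zeros(values.shape, bool),
        index=values.index,
        columns=values.columns,
    )
    neg = pd.Series(
        negctrl if negctrl is not None else np.full(len(values), 60.0),
        index=values.index,
    )
    return CqMatrix(values, eff, mf, neg)


class TestQcFilter:
    def test_efficiency_boundary(self):
        eff = np.array([[1.59, 1.60]])
        cq, log = qc_filter(_cq([[30.0, 30.0]], efficiency=eff))
        assert np.isnan(cq.cq.iloc[0, 0]) and cq.cq.iloc[0, 1] == 30.0
        assert log["efficiency"] == 1

    def test_negative_control_proximity(self):
        # negctrl 35: Cq 31 removed (31 >= 30), Cq 29 kept
        cq, log = qc_filter(_cq([[31.0, 29.0]], negctrl=[35.0]))
        assert np.isnan(cq.cq.iloc[0, 0]) and cq.cq.iloc[0, 1] == 29.0
        assert log["negative_control"] == 1

    def test_melt_flag_removes_clean_reaction(self):
        melt = np.array([[True, False]])
        cq, log = qc_filter(_cq([[25.0, 25.0]], melt=melt))
        assert np.isnan(cq.cq.iloc[0, 0])
        assert log == {"melt": 1, "efficiency": 0, "negative_control": 0}

    def test_missing_annotation_rejected(self):
        bad = _cq([[25.0, 26.0]])
        bad.efficiency.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="efficiency"):
            qc_filter(bad)

    def test_planted_violations_removed_exactly(self):
        """Cross-module: generator-planted QC failures equal filter removals."""
        rng = np.random.default_rng(0)
        em = make_expression(rng.uniform(50, 5000, size=(30, 40)))
        cq, planted = generate_cq(
            em, None, seed=1, frac_efficiency_fail=0.05, frac_melt_fail=0.03
        )
        _, log = qc_filter(cq)
        assert log == planted
        assert log["efficiency"] > 0 and log["melt"] > 0


class TestImpute:
    def test_rules(self):
        cq = _cq([[np.nan, 36.5, 38.2]])
        out = impute_undetected(cq)
        assert out.cq.iloc[0].tolist() == [37.0, 36.5, 37.0]


class TestGlobalMean:
    def test_single_universal_assay_self_reference(self):
        cq = _cq([[30.0, 32.0], [np.nan, 20.0]])
        dcq, universal = global_mean_normalize(cq)
        assert universal == ["a0"]
        assert dcq.loc["a0"].tolist() == [0.0, 0.0]

    def test_per_sample_shift_invariance(self):
        vals = np.random.default_rng(1).uniform(20, 30, size=(4, 5))
        base, _ = global_mean_normalize(_cq(vals))
        shifted, _ = global_mean_normalize(_cq(vals + np.array([0, 2, 0, -1, 3.0])))
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_three_by_three_hand_table(self):
        vals = [[20.0, 22.0, 24.0], [25.0, 25.0, 25.0], [30.0, 28.0, 26.0]]
        dcq, universal = global_mean_normalize(_cq(vals))
        assert universal == ["a0", "a1", "a2"]
        assert dcq.loc["a0", "s0"] == pytest.approx(25.0 - 20.0)
        assert dcq.loc["a2", "s2"] == pytest.approx(25.0 - 26.0)

    def test_no_universal_assay_rejected(self):
        with pytest.raises(ValueError):
            global_mean_normalize(_cq([[np.nan, 20.0], [20.0, np.nan]]))


class TestReferenceDcq:
    def test_target_equal_to_reference_mean_gives_zero(self):
        cq = _cq([[24.0], [26.0], [25.0]])
        refs = ReferenceSet(["a0", "a1"], ["a0", "a1"], None)
        dcq = reference_dcq(cq, refs)
        assert dcq.loc["a2", "s0"] == 0.0

    def test_two_cycles_below_reference_gives_plus_two(self):
        cq = _cq([[24.0], [26.0], [23.0]])
        refs = ReferenceSet(["a0", "a1"], ["a0", "a1"], None)
        assert reference_dcq(cq, refs).loc["a2", "s0"] == pytest.approx(2.0)

    def test_sample_missing_reference_dropped_with_warning(self):
        cq = _cq([[24.0, np.nan], [26.0, 25.0], [23.0, 22.0]])
        refs = ReferenceSet(["a0", "a1"], ["a0", "a1"], None)
        with pytest.warns(UserWarning, match="reference"):
            dcq = reference_dcq(cq, refs)
        assert list(dcq.columns) == ["s0"]

    def test_stable_planted_references_recovered(self):
        """Cross-module: stability ranking on simulated Cq picks the planted
        stable assays as the reference pair."""
        from mirsig import SimulationConfig, generate_counts, tpm_normalize

        cfg = SimulationConfig(n_samples=80, n_features=200, seed=21)
        cm, sheet, truth = generate_counts(cfg)
        tpm = tpm_normalize(cm)
        assays = truth.planted_feature_ids + truth.stable_reference_ids
        cq, _ = generate_cq(
            tpm.subset_features(assays), truth, seed=3, frac_melt_fail=0, frac_efficiency_fail=0
        )
        cq = impute_undetected(cq)
        candidates = truth.planted_feature_ids[:4] + truth.stable_reference_ids
        refs = choose_references(
            cq, candidates, groups=sheet["invasive"].to_numpy()
        )
        assert set(refs.chosen) <= set(truth.stable_reference_ids)


class TestRecalibration:
    def test_cross_platform_auc_within_tolerance(self):
        """Same latent signal measured on both platforms: the recalibrated
        network's held-out AUC tracks the sequencing model's within 0.1, and
        their probabilities are rank-correlated."""
        from scipy.stats import spearmanr

        from mirsig import (
            SimulationConfig,
            combat_adjust,
            generate_counts,
            log_transform,
            stratified_split,
            tpm_normalize,
        )

        cfg = SimulationConfig(n_samples=250, n_features=400, seed=31)
        cm, sheet, truth = generate_counts(cfg)
        tpm = tpm_normalize(cm)
        tpm.sheet = sheet
        adj = combat_adjust(log_transform(tpm), sheet["batch"])
        split = stratified_split(sheet, seed=31)
        signature = truth.planted_feature_ids
        scfg = SearchConfig(restarts=30, seed=31)
        seq_model, _ = mlp_search(
            adj.subset_samples(split.train_ids),
            adj.subset_samples(split.test_ids),
            signature,
            scfg,
        )
        cq, _ = generate_cq(
            tpm.subset_features(signature + truth.stable_reference_ids), truth, seed=32
        )
        cq = impute_undetected(qc_filter(cq)[0])
        refs = choose_references(
            cq, truth.stable_reference_ids, groups=sheet["invasive"].to_numpy()
        )
        dem = dcq_expression(reference_dcq(cq, refs).loc[signature], sheet)
        recal, _ = recalibrate_signature(
            signature,
            dem.subset_samples(split.train_ids),
            dem.subset_samples(split.test_ids),
            scfg,
        )
        from mirsig import mann_whitney_auc

        y_test = sheet.loc[split.test_ids, "invasive"].to_numpy()
        seq_auc = mann_whitney_auc(
            mlp_predict(seq_model, adj.subset_samples(split.test_ids)), y_test
        )
        q_auc = mann_whitney_auc(
            mlp_predict(recal, dem.subset_samples(split.test_ids)), y_test
        )
        assert abs(seq_auc - q_auc) <= 0.1
        rho = spearmanr(
            mlp_predict(seq_model, adj.subset_samples(split.test_ids)),
            mlp_predict(recal, dem.subset_samples(split.test_ids)),
        ).statistic
        assert rho >= 0.7
        assert recal.platform == "qpcr"

    def test_single_feature_signature_rejected(self):
        em = make_expression([[1.0, 2.0, 3.0, 4.0]], scale="log10", labels=[0, 0, 1, 1])
        with pytest.raises(ValueError):
            recalibrate_signature(["f0"], em, em, SearchConfig(restarts=1))


class TestExternalMapping:
    @staticmethod
    def _model_and_data(seed=41):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 100)
        X = rng.normal(size=(100, 3)) + np.outer(y, [2.0, -1.5, 0.0])
        em = make_expression(X.T, scale="log10", labels=y)
        # train with the whole matrix as the fit set so the model standardizer
        # is the cohort standardizer (required for the exact round trip)
        model, _ = mlp_search(
            em,
            em,
            ["f0", "f1", "f2"],
            SearchConfig(restarts=4, max_iter=60, selection_policy="test_set"),
        )
        return model, em, y

    def test_round_trip_identity(self):
        model, em, _ = self._model_and_data()
        mapped = map_external_platform(em, model)
        np.testing.assert_allclose(
            mlp_predict(model, mapped), mlp_predict(model, em), atol=1e-12
        )

    def test_affine_transformed_copy_same_roc_ordering(self):
        model, em, y = self._model_and_data()
        warped = em.values.mul([2.0, 0.5, 3.0], axis=0).add([10.0, -4.0, 1.0], axis=0)
        warped_em = make_expression(warped.to_numpy(), scale="log10", labels=y)
        mapped = map_external_platform(warped_em, model)
        base = mlp_predict(model, map_external_platform(em, model))
        np.testing.assert_allclose(mlp_predict(model, mapped), base, atol=1e-9)

    def test_missing_signature_feature_named(self):
        model, em, _ = self._model_and_data()
        with pytest.raises(KeyError, match="f2"):
            map_external_platform(em.subset_features(["f0", "f1"]), model)
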