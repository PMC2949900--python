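"""Preprocessing: background, quantile normalization, median polish,
RMA summarization and the frozen-reference train/apply route."""

import numpy as np
import pandas as pd
import pytest

from asymdex.manifest import PlatformMap
from asymdex.normalize import (
    ReferenceModel,
    background_adjust,
    median_polish,
    qq_concordance,
    quantile_normalize,
    refrma_apply,
    refrma_train,
    rma_summarize,
)
from asymdex.synthetic import SimConfig, StudyDesign, simulate_probe_level


class TestBackgroundAdjust:
    def test_zero_offset_floors_small_values(self):
        t = pd.DataFrame({"a": [0.5, 10.0]})
        out = background_adjust(t, 0.0)
        assert list(out["a"]) == [1.0, 10.0]

    def test_subtraction_with_floor(self):
        t = pd.DataFrame({"a": [101.0, 50.0]})
        out = background_adjust(t, 100.0)
        assert list(out["a"]) == [1.0, 1.0]

    def test_median_shifts_by_offset(self):
        cfg = SimConfig(
            n_genes=200, probes_per_gene=2, de_fraction=0.0,
            background_mean=100.0, background_sd=0.0,
            studies=[StudyDesign("t", 2, 2, study_shift_sd=0.0)], seed=3,
        )
        tables, _, _, _ = simulate_probe_level(cfg)
        col = tables[0].iloc[:, 0]
        adjusted = background_adjust(tables[0], 100.0).iloc[:, 0]
        assert adjusted.median() == pytest.approx(col.median() - 100.0, rel=1e-6)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        t = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(t), t)

    def test_hand_example(self):
        t = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [9.0, 5.0, 1.0]})
        out = quantile_normalize(t)
        assert list(out["a"]) == [1.5, 4.5, 7.5]
        assert list(out["b"]) == [7.5, 4.5, 1.5]  # rank order preserved

    def test_columns_share_sorted_vector_exactly(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.lognormal(5, 1, size=(100, 5)))
        out = quantile_normalize(t).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.array_equal(np.sort(out[:, j]), ref)

    def test_ties_get_mean_of_target_quantiles(self):
        t = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(t)
        # tied pair shares one value: the mean of the two lowest targets
        assert out["a"].iloc[0] == out["a"].iloc[1]
        target = np.sort(t.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].iloc[0] == pytest.approx(target[:2].mean())

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="ReferenceModel"):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestMedianPolish:
    def test_constant_matrix(self):
        e, a, m, resid = median_polish(np.full((3, 4), 7.0))
        assert m == pytest.approx(7.0)
        assert np.allclose(e, 0) and np.allclose(a, 0) and np.allclose(resid, 0)

    def test_exact_recovery_on_additive_2x2(self):
        # block[j, i] = col_effect[i] + row_effect[j] with cols [0,1], rows [0,2]
        block = np.array([[0.0, 1.0], [2.0, 3.0]])
        e, a, m, resid = median_polish(block)
        assert np.allclose(resid, 0, atol=1e-12)
        assert np.allclose(e - e.mean(), [-0.5, 0.5])
        assert np.allclose(a - a.mean(), [-1.0, 1.0])
        fitted = m + a[:, None] + e[None, :]
        assert np.allclose(fitted, block, atol=1e-12)

    def test_additive_matrices_have_zero_residuals(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            rows = rng.normal(size=6)
            cols = rng.normal(size=4)
            block = rows[:, None] + cols[None, :] + rng.normal()
            _, _, _, resid = median_polish(block, max_iter=20, tol=1e-9)
            assert np.abs(resid).max() < 1e-9

    def test_single_outlier_confined_to_its_cell(self):
        rows = np.arange(5.0)
        cols = np.arange(5.0) / 2
        block = rows[:, None] + cols[None, :]
        block[2, 3] += 10.0
        _, _, _, resid = median_polish(block, max_iter=20, tol=1e-9)
        mask = np.zeros_like(block, dtype=bool)
        mask[2, 3] = True
        assert resid[mask][0] == pytest.approx(10.0, abs=1e-6)
        assert np.abs(resid[~mask]).max() < 1e-6

    def test_probe_effects_median_centered(self):
        rng = np.random.default_rng(2)
        _, a, _, _ = median_polish(rng.normal(size=(7, 5)), max_iter=30, tol=1e-8)
        assert np.median(a) == pytest.approx(0.0, abs=1e-8)


@pytest.fixture
def noiseless_probe_data():
    cfg = SimConfig(
        n_genes=40, probes_per_gene=3, de_fraction=0.0, noise_sd=0.0,
        probe_affinity_sd=0.6, background_mean=0.0, background_sd=0.0,
        studies=[StudyDesign("t", 3, 3, study_shift_sd=0.0)], seed=9,
    )
    tables, pmap, _, _ = simulate_probe_level(cfg)
    return tables[0], pmap


class TestRmaSummarize:
    def test_recovers_generator_gene_values(self, noiseless_probe_data):
        table, pmap = noiseless_probe_data
        out = rma_summarize(table, pmap)
        truth = np.log2(table).groupby(pmap.probe_to_gene).median()
        # agreement up to a per-gene constant; noiseless columns identical
        diff = out - truth.loc[out.index, out.columns]
        assert (diff.max(axis=1) - diff.min(axis=1)).max() < 1e-6

    def test_single_probe_gene_is_log2_of_normalized(self):
        t = pd.DataFrame({"a": [4.0, 16.0], "b": [4.0, 16.0]})
        t.index = ["p1", "p2"]
        pmap = PlatformMap("x", {"p1": "g1", "p2": "g2"})
        out = rma_summarize(t, pmap)
        assert np.allclose(out.loc["g1"], 2.0)
        assert np.allclose(out.loc["g2"], 4.0)

    def test_sample_permutation_equivariance(self, noiseless_probe_data):
        table, pmap = noiseless_probe_data
        out = rma_summarize(table, pmap)
        perm = list(table.columns[::-1])
        out_perm = rma_summarize(table[perm], pmap)
        pd.testing.assert_frame_equal(out[perm], out_perm)

    def test_orphan_probe_errors(self, noiseless_probe_data):
        table, pmap = noiseless_probe_data
        bad = PlatformMap("x", {p: g for p, g in pmap.probe_to_gene.items()
                                if p != table.index[0]})
        with pytest.raises(KeyError, match="absent"):
            rma_summarize(table, bad)


class TestRefRMA:
    def test_training_on_identical_arrays(self):
        t = pd.DataFrame({"a": [2.0, 8.0, 4.0], "b": [2.0, 8.0, 4.0]},
                         index=["p1", "p2", "p3"])
        pmap = PlatformMap("x", {"p1": "g1", "p2": "g1", "p3": "g2"})
        model = refrma_train([t], pmap)
        assert np.allclose(model.reference_quantiles, [2.0, 4.0, 8.0])
        assert model.n_training_arrays == 2

    def test_affinities_match_generator(self, noiseless_probe_data):
        table, pmap = noiseless_probe_data
        model = refrma_train([table], pmap)
        # recover each probe's affinity up to its gene's centering constant
        truth = np.log2(table.iloc[:, 0]) - np.log2(table.iloc[:, 0]).groupby(
            pmap.probe_to_gene
        ).transform("median")
        assert np.abs(model.probe_affinities - truth).max() < 0.02

    def test_apply_is_array_independent(self, noiseless_probe_data):
        table, pmap = noiseless_probe_data
        model = refrma_train([table], pmap)
        joint = refrma_apply(table, model)
        singles = pd.concat(
            [refrma_apply(table[[c]], model) for c in table.columns], axis=1
        )
        pd.testing.assert_frame_equal(joint, singles)

    def test_identity_case(self):
        # array already matching the reference, zero affinities, 1 probe/gene
        t = pd.DataFrame({"a": [2.0, 4.0, 8.0]}, index=["p1", "p2", "p3"])
        pmap = PlatformMap("x", {"p1": "g1", "p2": "g2", "p3": "g3"})
        model = ReferenceModel(
            platform_id="x",
            probe_affinities=pd.Series(0.0, index=["p1", "p2", "p3"]),
            reference_quantiles=np.array([2.0, 4.0, 8.0]),
            probe_to_gene=dict(pmap.probe_to_gene),
            n_training_arrays=2,
        )
        out = refrma_apply(t, model)
        assert np.allclose(out["a"].to_numpy(), np.log2([2.0, 4.0, 8.0]))

    def test_held_out_arrays_recover_truth(self):
        cfg = SimConfig(
            n_genes=50, probes_per_gene=3, de_fraction=0.0, noise_sd=0.05,
            probe_affinity_sd=0.5, studies=[
                StudyDesign("t", 4, 4, study_shift_sd=0.0),
                StudyDesign("t", 2, 2, study_shift_sd=0.0),
            ], seed=4,
        )
        tables, pmap, _, _ = simulate_probe_level(cfg)
        model = refrma_train([tables[0]], pmap)
        out = refrma_apply(tables[1], model)
        truth = np.log2(tables[1]).groupby(pmap.probe_to_gene).median()
        diff = out - truth.loc[out.index, out.columns]
        centered = diff.sub(diff.mean(axis=1), axis=0)
        assert np.abs(centered.to_numpy()).max() < 3 * 0.05 + 0.1

    def test_model_roundtrip(self, tmp_path, noiseless_probe_data):
        table, pmap = noiseless_probe_data
        model = refrma_train([table], pmap)
        model.save(tmp_path)
        again = ReferenceModel.load(tmp_path)
        assert np.allclose(again.reference_quantiles, model.reference_quantiles)
        assert np.allclose(
            again.probe_affinities[model.probe_affinities.index],
            model.probe_affinities,
        )
        out1 = refrma_apply(table, model)
        out2 = refrma_apply(table, again)
        assert np.allclose(out1.to_numpy(), out2.to_numpy())


class TestQQConcordance:
    def test_self_comparison(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        stat = qq_concordance(x, x)
        assert stat.max_abs_quantile_diff == 0.0
        assert stat.quantile_correlation == pytest.approx(1.0)

    def test_location_shift(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        stat = qq_concordance(x, x + 1)
        assert stat.max_abs_quantile_diff == pytest.approx(1.0)
        assert stat.quantile_correlation == pytest.approx(1.0)

    def test_frozen_reference_tightens_cross_study_qq(self):
        # arrays from two shifted studies agree better after reference
        # normalization than after per-study RMA
        cfg = SimConfig(
            n_genes=120, probes_per_gene=3, de_fraction=0.0, noise_sd=0.1,
            studies=[StudyDesign("t", 3, 3, study_shift_sd=0.8),
                     StudyDesign("t", 3, 3, study_shift_sd=0.8)], seed=21,
        )
        tables, pmap, _, _ = simulate_probe_level(cfg)
        per_study = [rma_summarize(t, pmap) for t in tables]
        model = refrma_train(list(tables), pmap)
        ref = [refrma_apply(t, model) for t in tables]
        d_rma = qq_concordance(per_study[0].iloc[:, 0], per_study[1].iloc[:, 0])
        d_ref = qq_concordance(ref[0].iloc[:, 0], ref[1].iloc[:, 0])
        assert d_ref.max_abs_quantile_diff < d_rma.max_abs_quantile_diff
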