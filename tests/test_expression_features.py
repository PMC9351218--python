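import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from essprot import expression_features as ef
from essprot import nn
from essprot.io_formats import ExpressionTable, SampleAnnotation


class TestPearson:
    def test_self_correlation_is_one(self):
        assert ef.pearson_cc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_negative(self):
        assert ef.pearson_cc([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x, y = np.array([1, 2, 4, 3.0]), np.array([2, 1, 4, 5.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert ef.pearson_cc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ef.pearson_cc([1.0, 1.0, 1.0], [1, 2, 3])

    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    def test_invariant_to_positive_affine_rescaling(self, a, b):
        x = np.array([1.0, 2.0, 4.0, 3.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 5.0, 3.0])
        assert ef.pearson_cc(a * x + b, y) == pytest.approx(
            ef.pearson_cc(x, y), abs=1e-9
        )


def _table(values: dict, annotations: dict) -> ExpressionTable:
    return ExpressionTable(values=pd.DataFrame(values).T, annotations=annotations)


def _annotations(conditions=("ctrl", "treat"), replicates=(1, 2, 3), timepoints=(0.0, 3.0)):
    return {
        f"{c}_r{r}_t{int(t)}": SampleAnnotation(c, r, t)
        for c in conditions
        for r in replicates
        for t in timepoints
    }


class TestAggregateProbes:
    def _two_probe_table(self):
        anns = _annotations(replicates=(1,), timepoints=(0.0, 3.0))
        values = {
            "probeA": {k: v for k, v in zip(anns, [5.0, 5.0, 5.0, 5.0])},
            "probeB": {k: v for k, v in zip(anns, [3.0, 3.0, 3.0, 3.0])},
            "probeC": {k: v for k, v in zip(anns, [9.0, 1.0, 2.0, 2.0])},
        }
        return _table(values, anns)

    def test_keeps_max_mean_probe_row(self):
        table = self._two_probe_table()
        out = ef.aggregate_probes(table, {"probeA": "G1", "probeB": "G1"})
        assert list(out.values.index) == ["G1"]
        np.testing.assert_allclose(out.values.loc["G1"], 5.0)

    def test_single_probe_gene_unchanged(self):
        table = self._two_probe_table()
        out = ef.aggregate_probes(table, {"probeC": "G2"})
        np.testing.assert_allclose(
            out.values.loc["G2"], table.values.loc["probeC"]
        )

    def test_unmapped_probe_dropped_and_empty_mapping_rejected(self):
        table = self._two_probe_table()
        out = ef.aggregate_probes(table, {"probeA": "G1"})
        assert "probeC" not in out.values.index
        with pytest.raises(ValueError, match="empty"):
            ef.aggregate_probes(table, {})

    def test_per_sample_max_alternative(self):
        table = self._two_probe_table()
        out = ef.aggregate_probes(
            table, {"probeA": "G1", "probeC": "G1"}, method="per_sample_max"
        )
        np.testing.assert_allclose(out.values.loc["G1"], [9.0, 5.0, 5.0, 5.0])


class TestAssembleTensor:
    def test_dense_layout_all_present(self):
        anns = _annotations(timepoints=(0.0, 3.0, 6.0))
        rng = np.random.default_rng(0)
        values = {"P1": {k: rng.normal() for k in anns}}
        tensors = ef.assemble_expression_tensor(_table(values, anns), ["P1"], (2, 3, 3))
        assert tensors.values.shape == (1, 2, 3, 3)
        assert tensors.presence[0]
        # spot-check slot placement
        assert tensors.values[0, 0, 1, 2] == values["P1"]["ctrl_r2_t6"]

    def test_timesteps_padded_with_zeros_at_tail(self):
        anns = _annotations(replicates=(1, 2, 3), timepoints=(0.0, 3.0, 6.0, 9.0, 12.0))
        values = {"P1": {k: 1.0 for k in anns}}
        tensors = ef.assemble_expression_tensor(
            _table(values, anns), ["P1"], (2, 3, 5), pad_to=8
        )
        assert tensors.values.shape == (1, 2, 3, 8)
        np.testing.assert_allclose(tensors.values[0, :, :, :5], 1.0)
        np.testing.assert_allclose(tensors.values[0, :, :, 5:], 0.0)

    def test_absent_protein_zero_with_presence_false(self):
        anns = _annotations(timepoints=(0.0, 3.0))
        values = {"P1": {k: 1.0 for k in anns}}
        tensors = ef.assemble_expression_tensor(
            _table(values, anns), ["P1", "P9"], (2, 3, 2)
        )
        assert not tensors.presence[1]
        np.testing.assert_allclose(tensors.values[1], 0.0)

    def test_missing_replicate_error_lists_available(self):
        anns = _annotations(replicates=(1, 2), timepoints=(0.0,))
        values = {"P1": {k: 1.0 for k in anns}}
        with pytest.raises(ValueError, match=r"available.*\[1, 2\]"):
            ef.assemble_expression_tensor(
                _table(values, anns), ["P1"], (2, 2, 1), replicate_selection=[1, 5]
            )

    def test_replicate_selection_subset(self):
        # five replicates measured, first three selected (human protocol)
        anns = _annotations(replicates=(1, 2, 3, 4, 5), timepoints=(0.0,))
        values = {"P1": {k: float(a.replicate) for k, a in anns.items()}}
        tensors = ef.assemble_expression_tensor(
            _table(values, anns), ["P1"], (2, 3, 1), replicate_selection=[1, 2, 3]
        )
        np.testing.assert_allclose(tensors.values[0, 0, :, 0], [1.0, 2.0, 3.0])


class TestPCCProfile:
    def _tensorset(self, values, presence=None):
        n = values.shape[0]
        return ef.ExpressionTensorSet(
            proteins=[f"P{i}" for i in range(n)],
            values=values,
            presence=np.ones(n, bool) if presence is None else presence,
            conditions=["c1", "c2"],
            replicates=[1, 2, 3],
            timepoints=list(range(values.shape[3])),
        )

    def test_exact_replicate_copies_give_unit_pcc(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(5, 2, 1, 8))
        values = np.repeat(base, 3, axis=2)
        prof = ef.replicate_condition_pcc_profile(self._tensorset(values))
        np.testing.assert_allclose(prof["replicate_pcc"], 1.0, atol=1e-12)

    def test_independent_conditions_center_near_zero(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(300, 2, 3, 8))
        prof = ef.replicate_condition_pcc_profile(self._tensorset(values))
        assert abs(np.median(prof["cross_condition_pcc"])) < 0.1

    def test_generator_calibration_matches_target_bands(self, default_dataset):
        prof = ef.replicate_condition_pcc_profile(default_dataset.tensors)
        assert 0.6 <= prof["replicate_summary"]["median"] <= 0.9
        assert 0.1 <= prof["cross_condition_summary"]["median"] <= 0.6


def _tiny_weights(rng, n_cond=2, n_rep=3, filters=2, T=4):
    return ef.BranchWeights(
        conv_kernels=[rng.normal(size=(3, n_rep, filters)) for _ in range(n_cond)],
        conv_biases=[rng.normal(size=filters) for _ in range(n_cond)],
        bn_gamma=[np.ones(filters) for _ in range(n_cond)],
        bn_beta=[np.zeros(filters) for _ in range(n_cond)],
        bn_mean=[np.zeros(filters) for _ in range(n_cond)],
        bn_var=[np.ones(filters) for _ in range(n_cond)],
        bn_eps=1e-3,
        pointwise_kernel=rng.normal(size=(1, n_cond * filters, filters)),
        pointwise_bias=rng.normal(size=filters),
        dense_weights=rng.normal(size=(filters, 16)),
        dense_bias=rng.normal(size=16),
    )


class TestExpressionBranchForward:
    def test_output_shape_and_sign(self):
        rng = np.random.default_rng(3)
        weights = _tiny_weights(rng)
        out = ef.expression_branch_forward(rng.normal(size=(2, 3, 4)), weights)
        assert out.shape == (16,)
        assert (out >= 0).all()

    def test_zero_input_zero_biases_gives_zero_output(self):
        rng = np.random.default_rng(4)
        weights = _tiny_weights(rng)
        for c in range(2):
            weights.conv_biases[c][:] = 0.0
        weights.pointwise_bias[:] = 0.0
        weights.dense_bias[:] = 0.0
        out = ef.expression_branch_forward(np.zeros((2, 3, 4)), weights)
        np.testing.assert_allclose(out, 0.0)

    def test_matches_hand_stepped_forward(self):
        rng = np.random.default_rng(5)
        weights = _tiny_weights(rng)
        x = rng.normal(size=(2, 3, 4))
        streams = []
        for c in range(2):
            s = nn.conv1d_forward(
                x[c].T, weights.conv_kernels[c], weights.conv_biases[c], "relu"
            )
            s = (s - weights.bn_mean[c]) / np.sqrt(weights.bn_var[c] + weights.bn_eps)
            s = weights.bn_gamma[c] * s + weights.bn_beta[c]
            s = np.maximum(s[0::2], s[1::2])  # pool size 2
            streams.append(s)
        h = np.concatenate(streams, axis=1)
        h = nn.conv1d_forward(h, weights.pointwise_kernel, weights.pointwise_bias, "relu")
        h = h.max(axis=0)
        expected = np.maximum(h @ weights.dense_weights + weights.dense_bias, 0.0)
        out = ef.expression_branch_forward(x, weights, mode="infer")
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_inference_is_deterministic(self):
        rng = np.random.default_rng(6)
        weights = _tiny_weights(rng)
        x = rng.normal(size=(5, 2, 3, 4))
        a = ef.expression_branch_forward(x, weights, mode="infer")
        b = ef.expression_branch_forward(x, weights, mode="infer")
        np.testing.assert_array_equal(a, b)

    def test_shape_ledger_for_default_layout(self):
        # (8 x 3) per condition -> conv (8 x 64) -> pool (4 x 64)
        # -> concat (4 x 128) -> pointwise (4 x 64) -> gmp (64) -> dense (16)
        rng = np.random.default_rng(7)
        weights = ef.BranchWeights(
            conv_kernels=[rng.normal(size=(3, 3, 64)) * 0.1 for _ in range(2)],
            conv_biases=[np.zeros(64) for _ in range(2)],
            bn_gamma=[np.ones(64)] * 2,
            bn_beta=[np.zeros(64)] * 2,
            bn_mean=[np.zeros(64)] * 2,
            bn_var=[np.ones(64)] * 2,
            bn_eps=1e-3,
            pointwise_kernel=rng.normal(size=(1, 128, 64)) * 0.1,
            pointwise_bias=np.zeros(64),
            dense_weights=rng.normal(size=(64, 16)) * 0.1,
            dense_bias=np.zeros(16),
        )
        out = ef.expression_branch_forward(rng.normal(size=(2, 3, 8)), weights)
        assert out.shape == (16,)
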