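"""Cost matrix, instance weighting, and the backprop network."""

import numpy as np
import pytest

from psmrescore import (
    AnnHyperparams,
    CostMatrix,
    PSMDataset,
    SyntheticConfig,
    generate_psm_dataset,
    load_model,
    make_instance_weights,
    predict_probabilities,
    save_model,
    train_cost_ann,
)

from conftest import make_record


def separable_dataset(n=200, seed=0):
    """Two well-separated clouds: class 1 high xcorr/delta_cn, class 0 low."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        cls = i % 2
        recs.append(
            make_record(
                i,
                cls=cls,
                xcorr=float(rng.normal(4.5 if cls else 1.0, 0.15)),
                delta_cn=float(np.clip(rng.normal(0.4 if cls else 0.02, 0.02), 0, 1)),
            )
        )
    return PSMDataset(recs)


class TestCostMatrix:
    def test_published_defaults(self):
        cm = CostMatrix()
        assert (cm.cfp, cm.cfn, cm.ctn, cm.ctp) == (10.0, 1.0, 0.0, 0.0)

    @pytest.mark.parametrize("kwargs", [dict(cfp=0.5), dict(cfp=1, cfn=2), dict(ctn=1)])
    def test_invalid_matrices_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CostMatrix(**kwargs)


class TestInstanceWeights:
    def test_table_costs(self):
        ds = PSMDataset([make_record(0, cls=0), make_record(1, cls=1)])
        w = make_instance_weights(ds, CostMatrix(cfp=10, cfn=1))
        assert w.tolist() == [10.0, 1.0]

    def test_unit_costs_are_uniform(self):
        ds = PSMDataset([make_record(i, cls=i % 2) for i in range(6)])
        assert set(make_instance_weights(ds, CostMatrix(cfp=1, cfn=1))) == {1.0}

    def test_total_weight(self):
        ds = PSMDataset(
            [make_record(i, cls=0) for i in range(2)]
            + [make_record(i + 2, cls=1) for i in range(3)]
        )
        assert make_instance_weights(ds, CostMatrix(cfp=4)).sum() == 11.0


class TestTraining:
    def test_separable_data_high_accuracy(self):
        ds = separable_dataset()
        model = train_cost_ann(ds, CostMatrix(cfp=1), AnnHyperparams(seed=3))
        probs = np.array([r.raw_prob for r in predict_probabilities(model, ds)])
        acc = ((probs >= 0.5).astype(int) == np.array(ds.labels())).mean()
        assert acc >= 0.99

    def test_deterministic_given_seed(self):
        ds = separable_dataset(n=60)
        hp = AnnHyperparams(epochs=50, seed=9)
        m1 = train_cost_ann(ds, CostMatrix(), hp)
        m2 = train_cost_ann(ds, CostMatrix(), hp)
        for f in ("w1", "b1", "w2", "b2"):
            np.testing.assert_array_equal(getattr(m1, f), getattr(m2, f))

    def test_single_class_rejected(self):
        ds = PSMDataset([make_record(i, cls=1) for i in range(5)])
        with pytest.raises(ValueError, match="both classes"):
            train_cost_ann(ds, CostMatrix())

    def test_nan_score_names_record(self):
        recs = [make_record(0, cls=0), make_record(1, cls=1)]
        recs[1].xcorr = float("nan")
        ds = PSMDataset(recs)
        with pytest.raises(ValueError, match="s1"):
            train_cost_ann(ds, CostMatrix())

    def test_weight_equals_duplication(self):
        """Training with an integer instance weight w must equal training on
        the dataset with that record class replicated w times."""
        base = [make_record(i, cls=i % 2, xcorr=2.0 + 0.3 * i, delta_cn=0.05 * i)
                for i in range(8)]
        ds = PSMDataset(base)
        w = 3
        dup = list(base)
        k = len(base)
        for r in base:
            if r.class_label == 0:
                for j in range(w - 1):
                    dup.append(r.copy(spectrum_id=f"dup{k}"))
                    k += 1
        ds_dup = PSMDataset(dup)
        hp = AnnHyperparams(epochs=100, seed=5)
        m_w = train_cost_ann(ds, CostMatrix(cfp=w, cfn=1), hp)
        m_dup = train_cost_ann(ds_dup, CostMatrix(cfp=1, cfn=1), hp)
        for f in ("w1", "b1", "w2", "b2"):
            np.testing.assert_allclose(
                getattr(m_w, f), getattr(m_dup, f), rtol=1e-10, atol=1e-12
            )

    def test_higher_fp_cost_biases_toward_class_0(self):
        """Raising the false-positive cost must not increase the number of
        records called class 1 (beyond a small tolerance), seed by seed."""
        for seed in range(5):
            ds, _ = generate_psm_dataset(
                SyntheticConfig(n_targets=500, n_decoys=500, frac_correct=0.15, seed=seed)
            )
            hp = AnnHyperparams(epochs=200, seed=seed)
            counts = []
            for cfp in (1, 10):
                model = train_cost_ann(ds, CostMatrix(cfp=cfp), hp)
                p = np.array([r.raw_prob for r in predict_probabilities(model, ds)])
                counts.append(int((p >= 0.5).sum()))
            assert counts[1] <= counts[0] + 0.05 * len(ds)


class TestPrediction:
    def test_outputs_strictly_inside_unit_interval(self, small_synthetic):
        ds, _ = small_synthetic
        model = train_cost_ann(ds, CostMatrix(), AnnHyperparams(epochs=30, seed=0))
        out = predict_probabilities(model, ds)
        for r in out:
            assert 0.0 < r.raw_prob < 1.0

    def test_idempotent_and_nondestructive(self):
        ds = separable_dataset(n=40)
        model = train_cost_ann(ds, CostMatrix(), AnnHyperparams(epochs=30, seed=1))
        once = predict_probabilities(model, ds)
        twice = predict_probabilities(model, once)
        assert [r.raw_prob for r in once] == [r.raw_prob for r in twice]
        assert [r.xcorr for r in once] == [r.xcorr for r in ds]

    def test_zero_weights_give_half(self):
        ds = separable_dataset(n=10)
        model = train_cost_ann(ds, CostMatrix(), AnnHyperparams(epochs=1, seed=0))
        for f in ("w1", "b1", "w2", "b2"):
            getattr(model, f)[:] = 0.0
        probs = [r.raw_prob for r in predict_probabilities(model, ds)]
        assert probs == [0.5] * len(ds)


def test_model_serialization_roundtrip(tmp_path):
    ds = separable_dataset(n=30)
    model = train_cost_ann(ds, CostMatrix(cfp=7), AnnHyperparams(epochs=20, seed=2))
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    for f in ("norm_min", "norm_max", "w1", "b1", "w2", "b2"):
        np.testing.assert_array_equal(getattr(model, f), getattr(back, f))
    assert back.hyperparams == model.hyperparams
    assert back.cost_matrix == model.cost_matrix
    np.testing.assert_array_equal(model.forward(ds.scores_frame().to_numpy()),
                                  back.forward(ds.scores_frame().to_numpy()))
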