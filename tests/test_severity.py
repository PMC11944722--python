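"""Severity labelling, metric closed forms, and the repeated-evaluation protocol."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef, precision_score, recall_score

import oracles
from oxiscale.severity import (
    ConfigError,
    compute_metrics,
    label_severity,
    repeat_experiments,
    run_experiment,
)


class TestLabelSeverity:
    @pytest.mark.parametrize(
        "ahi,binaries,cls",
        [
            (4.9, (0, 0, 0), 0),
            (5.0, (1, 0, 0), 1),
            (15.0, (1, 1, 0), 2),
            (29.9, (1, 1, 0), 2),
            (31.0, (1, 1, 1), 3),
        ],
    )
    def test_cutoffs_inclusive(self, ahi, binaries, cls):
        y = label_severity(pd.DataFrame({"subject_id": ["s"], "ahi": [ahi]}))
        row = y.iloc[0]
        assert (row.cutoff5, row.cutoff15, row.cutoff30) == binaries
        assert row.multiclass == cls

    def test_multiclass_consistent_with_binaries(self, rng):
        ahi = rng.uniform(0, 60, 500)
        y = label_severity(pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(500)], "ahi": ahi}))
        np.testing.assert_array_equal(
            y.multiclass, y.cutoff5 + y.cutoff15 + y.cutoff30)

    def test_negative_ahi_rejected(self):
        with pytest.raises(ValueError):
            label_severity(pd.DataFrame({"subject_id": ["s"], "ahi": [-1.0]}))


class TestMetrics:
    def test_perfect_confusion(self):
        m = compute_metrics(np.array([[50, 0], [0, 50]]))
        assert (m.acc, m.pre, m.sen, m.f1, m.mcc) == (1, 1, 1, 1, 1)

    def test_all_predicted_positive(self):
        m = compute_metrics(np.array([[0, 50], [0, 50]]))
        assert m.sen == 1.0 and m.pre == 0.5 and m.mcc == 0.0

    def test_binary_closed_form_oracle(self):
        tp, fn, fp, tn = 40, 10, 20, 30
        m = compute_metrics(np.array([[tn, fp], [fn, tp]]))
        assert m.mcc == pytest.approx(oracles.mcc_binary(tp, fn, fp, tn), abs=1e-12)
        assert m.pre == pytest.approx(tp / (tp + fp), abs=1e-12)
        assert m.sen == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert m.f1 == pytest.approx(2 * m.pre * m.sen / (m.pre + m.sen), abs=1e-12)
        assert m.acc == pytest.approx((tp + tn) / 100, abs=1e-12)

    def test_binary_against_sklearn(self, rng):
        y_true = rng.integers(0, 2, 300)
        y_pred = rng.integers(0, 2, 300)
        c = np.zeros((2, 2), dtype=int)
        for t, p in zip(y_true, y_pred):
            c[t, p] += 1
        m = compute_metrics(c)
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
        assert m.pre == pytest.approx(precision_score(y_true, y_pred), abs=1e-12)
        assert m.sen == pytest.approx(recall_score(y_true, y_pred), abs=1e-12)
        assert m.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-12)

    def test_gorodkin_multiclass_against_sklearn(self, rng):
        y_true = rng.integers(0, 4, 400)
        y_pred = rng.integers(0, 4, 400)
        c = np.zeros((4, 4), dtype=int)
        for t, p in zip(y_true, y_pred):
            c[t, p] += 1
        m = compute_metrics(c)
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
        assert m.pre == pytest.approx(
            precision_score(y_true, y_pred, average="macro", zero_division=0), abs=1e-12)
        assert m.sen == pytest.approx(
            recall_score(y_true, y_pred, average="macro"), abs=1e-12)
        assert m.auc is None

    def test_multiclass_constant_predictor_mcc_zero(self):
        c = np.zeros((4, 4), dtype=int)
        c[:, 2] = [10, 20, 30, 40]
        assert compute_metrics(c).mcc == 0.0

    def test_auc_from_scores(self, rng):
        y = np.array([0] * 50 + [1] * 50)
        scores = y + rng.normal(0, 0.5, 100)
        pred = (scores > 0.5).astype(int)
        c = np.zeros((2, 2), dtype=int)
        for t, p in zip(y, pred):
            c[t, p] += 1
        m = compute_metrics(c, scores=scores, y_true=y)
        from sklearn.metrics import roc_auc_score

        assert m.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def separable_data(n=120, n_feat=4, seed=0):
    """Cohort whose features separate the AHI classes cleanly."""
    r = np.random.default_rng(seed)
    ahi = r.uniform(0, 60, n)
    ids = [f"s{i}" for i in range(n)]
    feats = {
        f"f{j}@1s": ahi * (j + 1) + r.normal(0, 1.0, n) for j in range(n_feat)
    }
    m = pd.DataFrame(feats, index=ids)
    m.index.name = "subject_id"
    labels = label_severity(pd.DataFrame({"subject_id": ids, "ahi": ahi}))
    return m, labels


class TestExperiments:
    def test_determinism_same_seed(self):
        m, y = separable_data()
        a = run_experiment(m, y, "cutoff15", "LR", seed=5)
        b = run_experiment(m, y, "cutoff15", "LR", seed=5)
        assert a.as_dict() == b.as_dict()
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_separable_cohort_near_perfect(self):
        m, y = separable_data()
        res = run_experiment(m, y, "cutoff15", "DT", seed=1)
        assert res.acc >= 0.95 and res.mcc >= 0.9

    def test_unknown_model_rejected(self):
        m, y = separable_data()
        with pytest.raises(ConfigError):
            run_experiment(m, y, "cutoff15", "SVM9000", seed=0)

    def test_unknown_task_rejected(self):
        m, y = separable_data()
        with pytest.raises(ConfigError):
            run_experiment(m, y, "cutoff99", "LR", seed=0)

    def test_missing_cells_imputed(self):
        m, y = separable_data()
        m = m.copy()
        m.iloc[::7, 0] = np.nan
        res = run_experiment(m, y, "cutoff15", "LR", seed=2)
        assert res.acc > 0.8

    def test_stratified_split_preserves_proportions(self):
        from sklearn.model_selection import train_test_split

        m, y = separable_data(n=200)
        target = y["multiclass"].to_numpy()
        _, _, y_tr, y_te = train_test_split(
            m.to_numpy(), target, test_size=0.2, random_state=0, stratify=target)
        for cls in np.unique(target):
            expected = (target == cls).sum() * 0.2
            assert abs((y_te == cls).sum() - expected) <= 1

    def test_repeat_report_shape_and_sd(self):
        m, y = separable_data(n=80)
        rep = repeat_experiments(m, y, ["cutoff15"], ["LR"], n_repeats=1, base_seed=3)
        assert set(rep.metric) >= {"acc", "pre", "sen", "f1", "mcc", "auc"}
        assert (rep.sd == 0).all()
        conf = rep.attrs["confusion_pct"][("LR", "cutoff15")]
        assert conf.sum() == pytest.approx(100.0)

    def test_forced_equal_seeds_zero_sd(self):
        m, y = separable_data(n=80)
        a = run_experiment(m, y, "cutoff15", "LR", seed=11)
        b = run_experiment(m, y, "cutoff15", "LR", seed=11)
        metrics = np.array([[a.as_dict()[k], b.as_dict()[k]] for k in ("acc", "mcc")])
        assert np.all(metrics.std(axis=1) == 0)
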