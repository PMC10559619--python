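"""Batch adjustment, feature elimination, ensemble and metric checks."""

import numpy as np
import pandas as pd
import pytest

from gemmomics import subtype as st
from gemmomics import synthdata as sd
from gemmomics.expression import ExpressionMatrix


def two_batch_cfg(seed=7, n_genes=120, per_class=40, offset=2.0, scale=1.5,
                  class_sep=0.0):
    means = (
        {"c1": [class_sep] * 6 + [0.0] * 6, "c2": [0.0] * 6 + [class_sep] * 6}
        if class_sep
        else {"c1": [0.0] * 4, "c2": [0.0] * 4}
    )
    return sd.SynthConfig(
        seed=seed,
        n_genes=n_genes,
        n_samples_per_class={"c1": per_class, "c2": per_class},
        class_means=means,
        noise_sd=1.0,
        batch_offsets={"b1": 0.0, "b2": offset},
        batch_scales={"b1": 1.0, "b2": scale},
    )


class TestBatchAdjust:
    def test_removes_location_and_scale(self):
        e = sd.gen_expression(two_batch_cfg(per_class=150, n_genes=300))
        adj, model = st.eb_batch_adjust(e)
        b = adj.batches()
        i1, i2 = b[b == "b1"].index, b[b == "b2"].index
        dmean = (adj.values[i1].mean(axis=1) - adj.values[i2].mean(axis=1)).abs()
        vratio = adj.values[i2].var(axis=1) / adj.values[i1].var(axis=1)
        pre = (e.values[i1].mean(axis=1) - e.values[i2].mean(axis=1)).abs()
        assert pre.mean() > 1.5  # the batch effect was really there
        assert dmean.mean() < 0.1
        assert 0.8 <= vratio.mean() <= 1.25

    def test_single_batch_identity(self, small_cfg):
        e = sd.gen_expression(small_cfg)
        with pytest.warns(UserWarning, match="single batch"):
            adj, model = st.eb_batch_adjust(e)
        assert model is None
        assert np.abs(adj.values.to_numpy() - e.values.to_numpy()).max() < 1e-8

    def test_grand_mean_preserved(self):
        e = sd.gen_expression(two_batch_cfg(per_class=30, n_genes=80))
        adj, _ = st.eb_batch_adjust(e)
        before = e.values.mean(axis=1)
        after = adj.values.mean(axis=1)
        assert np.abs(before - after).max() < 1e-6

    def test_class_effect_preserved_with_balanced_batches(self):
        cfg = two_batch_cfg(seed=8, per_class=100, n_genes=200, offset=2.0,
                            scale=1.0, class_sep=3.0)
        clean_cfg = sd.SynthConfig(
            **{**cfg.__dict__, "batch_offsets": {"b1": 0.0, "b2": 0.0}}
        )
        clean = sd.gen_expression(clean_cfg)
        adj, _ = st.eb_batch_adjust(sd.gen_expression(cfg))

        def smd(em, gene):
            a = em.values.loc[gene, em.samples_in_group("c1")]
            b = em.values.loc[gene, em.samples_in_group("c2")]
            return (a.mean() - b.mean()) / np.sqrt((a.var() + b.var()) / 2)

        genes = clean.genes[:12]
        ratio = np.array([smd(adj, g) / smd(clean, g) for g in genes])
        assert np.abs(ratio - 1.0).max() < 0.10

    def test_matches_scanpy_combat(self):
        import scanpy as sc
        from anndata import AnnData

        e = sd.gen_expression(two_batch_cfg(seed=12, per_class=40, n_genes=60))
        adj, _ = st.eb_batch_adjust(e)
        ad = AnnData(
            e.values.to_numpy().T.astype(np.float64),
            obs=pd.DataFrame({"batch": e.batches().to_numpy()},
                             index=e.samples),
        )
        sc.pp.combat(ad, key="batch")
        theirs = ad.X.T
        ours = adj.values.to_numpy()
        # identical model up to our final grand-mean recentering
        assert np.abs(ours - theirs).max() < 0.05


class TestMetrics:
    def test_mcc_worked_examples(self):
        assert st.mcc_multiclass(np.diag([2, 2])) == pytest.approx(1.0)
        assert st.mcc_multiclass(np.array([[2, 0], [2, 0]])) == 0.0
        cm = np.array([[3, 2], [1, 4]])  # TP=3 FN=2 FP=1 TN=4
        tp, fn, fp, tn = 3, 2, 1, 4
        closed = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert st.mcc_multiclass(cm) == pytest.approx(closed)

    def test_mcc_matches_sklearn_on_random_predictions(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(20):
            y_true = rng.integers(0, 4, 60)
            y_pred = rng.integers(0, 4, 60)
            cm = st._confusion(
                y_true.astype(str), y_pred.astype(str), [str(k) for k in range(4)]
            )
            assert st.mcc_multiclass(cm) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )

    def test_weighted_f1_worked_examples(self):
        assert st.weighted_f1(np.diag([3, 5])) == pytest.approx(1.0)
        # balanced binary, class 2 fully missed into class 1:
        # F1_present = 2*5/(5+10) ... support-weighted: 0.5 * F1_present
        cm = np.array([[5, 0], [5, 0]])
        f1_present = 2 * 5 / (2 * 5 + 0 + 5)
        assert st.weighted_f1(cm) == pytest.approx(0.5 * f1_present)

    def test_weighted_f1_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score

        for _ in range(20):
            y_true = rng.integers(0, 3, 50)
            y_pred = rng.integers(0, 3, 50)
            cm = st._confusion(
                y_true.astype(str), y_pred.astype(str), ["0", "1", "2"]
            )
            assert st.weighted_f1(cm) == pytest.approx(
                f1_score(y_true, y_pred, average="weighted", zero_division=0),
                abs=1e-12,
            )

    def test_weighted_equals_macro_when_balanced(self):
        cm = np.array([[4, 1, 0], [1, 3, 1], [0, 2, 3]])
        f1s = []
        for k in range(3):
            tp = cm[k, k]
            f1s.append(2 * tp / (cm[:, k].sum() + cm[k].sum()))
        assert st.weighted_f1(cm) == pytest.approx(np.mean(f1s))


def _six_class_expr(seed=3, per_class=30, sep=3.0, n_noise=6):
    classes = list(st.SUBTYPE_ORDER)
    n_inf = 2 * len(classes)
    means = {
        c: [sep if j // 2 == i else 0.0 for j in range(n_inf)]
        for i, c in enumerate(classes)
    }
    cfg = sd.SynthConfig(
        seed=seed,
        n_genes=n_inf + n_noise,
        n_samples_per_class={c: per_class for c in classes},
        class_means=means,
        noise_sd=1.0,
        n_informative=n_inf,
    )
    return sd.gen_expression(cfg), cfg


@pytest.fixture(scope="module")
def fitted():
    e, _ = _six_class_expr(per_class=20)
    model, metrics = st.fit_voting_ensemble(
        e, e.groups(), n_instantiations=3, seed=5
    )
    return e, model, metrics


class TestVotingEnsemble:
    def test_high_accuracy_on_separated_classes(self, fitted):
        _, _, metrics = fitted
        assert metrics.accuracy >= 0.9

    def test_metrics_consistent_with_confusion(self, fitted):
        _, _, m = fitted
        assert m.pooled_accuracy == pytest.approx(
            np.trace(m.confusion) / m.confusion.sum()
        )
        assert abs(m.pooled_f1_weighted - m.f1_weighted) < 0.1
        assert abs(m.pooled_mcc - m.mcc) < 0.1

    def test_confusion_row_sums_match_test_supports(self, fitted):
        e, _, m = fitted
        # 3 instantiations x 30% of 20 per class = 18 per class
        assert (m.confusion.sum(axis=1) == 18).all()

    def test_stratified_splits_preserve_proportions(self):
        from sklearn.model_selection import StratifiedShuffleSplit

        e, _ = _six_class_expr(per_class=20)
        labels = np.asarray(e.groups())
        X = e.values.to_numpy().T
        sss = StratifiedShuffleSplit(n_splits=1, train_size=0.7, random_state=5)
        train, test = next(sss.split(X, labels))
        for cls in st.SUBTYPE_ORDER:
            n_train = (labels[train] == cls).sum()
            assert abs(n_train - 0.7 * 20) <= 1

    def test_singleton_class_rejected(self):
        e, _ = _six_class_expr(per_class=4)
        labels = list(e.groups())
        labels[0] = "ODDBALL"
        with pytest.raises(ValueError, match="stratify"):
            st.fit_voting_ensemble(e, labels, n_instantiations=2, seed=0)

    def test_deterministic_for_fixed_seed(self):
        e, _ = _six_class_expr(per_class=12)
        _, m1 = st.fit_voting_ensemble(e, e.groups(), n_instantiations=2, seed=9)
        _, m2 = st.fit_voting_ensemble(e, e.groups(), n_instantiations=2, seed=9)
        assert m1.accuracy == m2.accuracy
        assert (m1.confusion == m2.confusion).all()


class TestAssignment:
    class _Uniform:
        classes_ = np.array(["BASAL", "CLAUDIN_LOW", "HER2"])

        def predict_proba(self, X):
            return np.full((len(X), 3), 1.0 / 3)

    def test_uniform_probabilities_tie_break_to_first_class(self):
        model = st.EnsembleModel(
            features=["g1"],
            class_order=("BASAL", "CLAUDIN_LOW", "HER2"),
            instantiations=[{"stub": self._Uniform()}],
        )
        mouse = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["m1", "m2"])
        )
        assignments, props = st.assign_mouse_subtypes(model, mouse)
        assert (assignments["assigned"] == "BASAL").all()

    def test_missing_feature_listed(self):
        model = st.EnsembleModel(
            features=["gA", "gB"], class_order=("BASAL", "HER2")
        )
        mouse = ExpressionMatrix(pd.DataFrame([[1.0]], index=["gA"],
                                              columns=["m1"]))
        with pytest.raises(KeyError, match="gB"):
            st.assign_mouse_subtypes(model, mouse)

    def test_cross_domain_recovery_and_proportions(self):
        e, cfg = _six_class_expr(seed=13, per_class=20)
        model, _ = st.fit_voting_ensemble(e, e.groups(), n_instantiations=3,
                                          seed=13)
        # "mouse" samples drawn from the same class-conditional model
        mouse_cfg = sd.SynthConfig(**{**cfg.__dict__, "seed": 999})
        mouse = sd.gen_expression(mouse_cfg)
        mouse.meta["group"] = "mouse_cohort"
        assignments, props = st.assign_mouse_subtypes(model, mouse)
        truth = sd.gen_expression(mouse_cfg).groups()
        correct = (assignments["assigned"] == truth.loc[assignments.index]).mean()
        assert correct >= 0.9
        assert props.loc["mouse_cohort"].sum() == pytest.approx(1.0)


class TestRfecv:
    def test_single_separating_feature_always_kept(self):
        rng = np.random.default_rng(0)
        n = 40
        labels = ["a"] * n + ["b"] * n
        sep = np.concatenate([rng.normal(0, 0.2, n), rng.normal(5, 0.2, n)])
        noise = rng.normal(size=(3, 2 * n))
        values = pd.DataFrame(
            np.vstack([sep, noise]),
            index=["hit", "n1", "n2", "n3"],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        meta = pd.DataFrame({"group": labels, "batch": "b0"},
                            index=values.columns)
        e = ExpressionMatrix(values, meta)
        for seed in range(3):
            sel, curve = st.rfecv_select(e, labels, folds=4, seed=seed)
            assert "hit" in sel

    def test_single_class_rejected(self, small_cfg):
        e = sd.gen_expression(small_cfg)
        with pytest.raises(ValueError, match="classes"):
            st.rfecv_select(e, ["same"] * len(e.samples), folds=3)

    def test_curve_covers_all_feature_counts(self):
        e, _ = _six_class_expr(seed=1, per_class=8, n_noise=2)
        sel, curve = st.rfecv_select(e, e.groups(), folds=4, seed=1)
        assert list(curve["n_features"]) == list(range(e.shape[0], 0, -1))
        assert 1 <= len(sel) <= e.shape[0]
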