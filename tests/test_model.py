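"""Grouped CV, grid training, confusion metrics, AUC and subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import accuracy_score, matthews_corrcoef

from dicerscan import (
    CleavageSVM,
    ConfusionCounts,
    ModelConfig,
    balanced_subsample,
    compute_metrics,
    grouped_kfold,
    roc_auc,
)
from dicerscan.model import COST_GRID, GAMMA_GRID, JFACTOR_GRID


class TestGroupedKFold:
    def test_five_families_of_two_give_one_family_per_fold(self):
        ids = [f"h{i}" for i in range(10)]
        fam = {f"h{i}": f"f{i // 2}" for i in range(10)}
        folds = grouped_kfold(ids, fam, k=5, seed=0)
        for fold in folds:
            assert len({fam[ids[i]] for i in fold}) == 1

    def test_greedy_largest_first_balances_sizes(self):
        sizes = {"a": 4, "b": 3, "c": 2, "d": 1, "e": 1, "f": 1}
        ids, fam = [], {}
        for name, size in sizes.items():
            for i in range(size):
                hid = f"{name}{i}"
                ids.append(hid)
                fam[hid] = name
        for seed in range(5):
            folds = grouped_kfold(ids, fam, k=3, seed=seed)
            assert sorted(len(f) for f in folds) == [4, 4, 4]

    def test_no_family_spans_two_folds_random_maps(self):
        rng = np.random.default_rng(0)
        for trial in range(25):
            n = int(rng.integers(20, 60))
            ids = [f"h{i}" for i in range(n)]
            fam = {h: f"f{rng.integers(0, max(6, n // 3))}" for h in ids}
            folds = grouped_kfold(ids, fam, k=5, seed=trial)
            assert sorted(np.concatenate(folds)) == list(range(n))
            seen: dict[str, int] = {}
            for fi, fold in enumerate(folds):
                for i in fold:
                    f = fam[ids[i]]
                    assert seen.setdefault(f, fi) == fi

    def test_fewer_families_than_folds_rejected(self):
        with pytest.raises(ValueError, match="families"):
            grouped_kfold(["a", "b", "c"], {"a": "f", "b": "f", "c": "f"}, k=2)

    def test_deterministic_given_seed(self):
        ids = [f"h{i}" for i in range(30)]
        fam = {h: f"f{i % 9}" for i, h in enumerate(ids)}
        a = grouped_kfold(ids, fam, k=5, seed=42)
        b = grouped_kfold(ids, fam, k=5, seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestMetrics:
    def test_perfect_and_antiperfect_endpoints(self):
        perfect = compute_metrics(ConfusionCounts(5, 0, 5, 0))
        assert (perfect.sn, perfect.sp, perfect.ac, perfect.mcc) == (100, 100, 100, 1)
        worst = compute_metrics(ConfusionCounts(0, 5, 0, 5))
        assert worst.mcc == -1 and worst.ac == 0

    def test_hand_case(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert (m.sn, m.sp, m.ac) == (60.0, 80.0, 70.0)
        assert m.mcc == pytest.approx(10 / np.sqrt(600), abs=1e-12)

    def test_zero_denominator_flagged_not_zeroed(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert m.sn is None and "sn" in m.undefined and "mcc" in m.undefined
        assert m.ac == 100.0

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_agrees_with_recount_oracle(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        # independent route: expand to (label, prediction) pairs and recount
        y = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        p = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert m.ac == pytest.approx(100 * accuracy_score(y, p))
        if m.mcc is not None:
            assert m.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-9)
        if m.sn is not None and m.sp is not None:
            assert min(m.sn, m.sp) - 1e-9 <= m.ac <= max(m.sn, m.sp) + 1e-9

    def test_accuracy_between_sn_and_sp(self):
        m = compute_metrics(ConfusionCounts(tp=8, fp=3, tn=7, fn=2))
        assert min(m.sn, m.sp) <= m.ac <= max(m.sn, m.sp)


def _pairs_auc(scores, labels):
    """All-pairs probability estimator: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_separated_and_degenerate_scores(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_hand_case(self):
        assert roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_matches_all_pairs_estimator_with_ties(self, data):
        n = data.draw(st.integers(4, 50))
        scores = data.draw(
            st.lists(st.integers(0, 8), min_size=n, max_size=n)
        )  # integer scores force ties
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        assert roc_auc(scores, labels) == pytest.approx(_pairs_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.4).astype(int)
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(3 * scores) - 2, labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestBalancedSubsample:
    def test_size_and_determinism(self):
        pos, neg = list("abcde"), [f"n{i}" for i in range(100)]
        s1 = balanced_subsample(pos, neg, seed=3)
        s2 = balanced_subsample(pos, neg, seed=3)
        assert len(s1) == 10 and s1 == s2 and s1[:5] == pos
        assert len(set(s1[5:])) == 5  # without replacement

    def test_fewer_negatives_rejected(self):
        with pytest.raises(ValueError):
            balanced_subsample([1, 2, 3], [1], seed=0)

    def test_coverage_over_seeds(self):
        neg = list(range(40))
        seen = set()
        for seed in range(200):
            seen.update(balanced_subsample([0, 1, 2], neg, seed=seed)[3:])
        assert seen == set(neg)


class TestGridTraining:
    def test_declared_grid_has_300_configs(self):
        assert len(GAMMA_GRID) * len(COST_GRID) * len(JFACTOR_GRID) == 300

    def test_config_outside_declared_sets_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(g=0.5, c=1, j=1)
        with pytest.raises(ValueError):
            ModelConfig(g=0.01, c=11, j=1)

    @pytest.fixture(scope="class")
    @staticmethod
    def toy_problem():
        rng = np.random.default_rng(5)
        n = 120
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 8)) + 1.2 * y[:, None]
        ids = [f"h{i}" for i in range(n)]
        fam = {h: f"f{i % 12}" for i, h in enumerate(ids)}
        return X, y, ids, fam

    def test_selected_config_in_grid_and_cv_table_complete(self, toy_problem):
        X, y, ids, fam = toy_problem
        model = CleavageSVM(X, y, ids, family_map=fam,
                            gammas=(0.01, 0.1), costs=(1, 2), j_factors=(1, 2))
        res = model.fit(seed=0)
        assert len(res.cv_table) == 8
        assert res.config.g in (0.01, 0.1)
        assert res.config.c in (1, 2) and res.config.j in (1, 2)
        assert res.cv_metrics.ac > 75  # separable toy signal is recovered

    def test_deterministic_given_seed(self, toy_problem):
        X, y, ids, fam = toy_problem
        kw = dict(gammas=(0.01,), costs=(1, 2), j_factors=(1,))
        r1 = CleavageSVM(X, y, ids, family_map=fam, **kw).fit(seed=9)
        r2 = CleavageSVM(X, y, ids, family_map=fam, **kw).fit(seed=9)
        assert r1.cv_table.equals(r2.cv_table)
        assert r1.config == r2.config

    def test_permuted_labels_give_chance_level(self, toy_problem):
        X, y, ids, fam = toy_problem
        rng = np.random.default_rng(11)
        accs = []
        for rep in range(5):
            yp = rng.permutation(y)
            if yp.sum() in (0, len(yp)):
                continue
            res = CleavageSVM(X, yp, ids, family_map=fam,
                              gammas=(0.01,), costs=(1,), j_factors=(1,)).fit(seed=rep)
            accs.append(res.cv_table["cv_accuracy_mean"].iloc[0])
        assert 35 < np.mean(accs) < 65

    def test_single_class_rejected(self, toy_problem):
        X, y, ids, fam = toy_problem
        with pytest.raises(ValueError, match="both classes"):
            CleavageSVM(X, np.zeros_like(y), ids, family_map=fam)

    def test_nan_features_rejected(self, toy_problem):
        X, y, ids, fam = toy_problem
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            CleavageSVM(Xn, y, ids, family_map=fam)

    def test_train_test_families_disjoint_in_cv(self, toy_problem):
        X, y, ids, fam = toy_problem
        folds = grouped_kfold(ids, fam, k=5, seed=2)
        for fold in folds:
            test_fams = {fam[ids[i]] for i in fold}
            train_fams = {
                fam[ids[i]] for other in folds if other is not fold for i in other
            }
            assert not test_fams & train_fams


def test_save_load_roundtrip(tmp_path, small_signal_dataset):
    from dicerscan import CleavageSVMResults, build_training_windows

    ds = small_signal_dataset
    wins = build_training_windows(ds.hairpins, ds.annotations)
    res = CleavageSVM.from_windows(
        wins, "extbinary_struct", family_map=ds.family_map,
        gammas=(0.01,), costs=(1,), j_factors=(1,),
    ).fit(seed=0)
    path = tmp_path / "model.joblib"
    res.save(path)
    loaded = CleavageSVMResults.load(path)
    assert loaded.config == res.config
    assert loaded.scheme == res.scheme and loaded.width == res.width
    X = np.vstack([res.model.X[:5]])
    np.testing.assert_allclose(
        loaded.decision_function(X), res.decision_function(X)
    )
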