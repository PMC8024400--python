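"""ECOC classification, F1 scoring, protocols, stacking, sparse selection."""

import numpy as np
import pytest

import netstate as ns
from netstate.classification import (_code_matrix, _mode_vote,
                                     _scramble_within_subject, _subject_split)


def simplex_toy(n_classes=3, n_per_class=40, noise=0.05, n_subjects=8, seed=0):
    """Linearly separable toy: class means at simplex vertices, tiny noise."""
    rng = np.random.default_rng(seed)
    X, y, g = [], [], []
    for c in range(n_classes):
        mean = np.eye(n_classes)[c]
        X.append(mean + noise * rng.standard_normal((n_per_class, n_classes)))
        y.extend([c] * n_per_class)
        g.extend(rng.integers(0, n_subjects, size=n_per_class))
    return ns.FeatureTable(np.vstack(X), np.array(y), np.array(g))


class TestEcoc:
    def test_separable_toy_is_perfect(self):
        tab = simplex_toy()
        tr = np.arange(tab.n_events) % 2 == 0
        model = ns.fit_ecoc(tab.subset(np.where(tr)[0]))
        pred = model.predict(tab.X[~tr])
        assert np.all(pred == tab.y[~tr])

    def test_scrambled_labels_give_chance(self):
        """Held-out F1 on the same toy with scrambled labels ~ 1/3."""
        tab = simplex_toy(n_per_class=60)
        rng = np.random.default_rng(1)
        scores = []
        for _ in range(30):
            y_scr = rng.permutation(tab.y)
            tr = rng.random(tab.n_events) < 0.5
            model = ns.EcocModel("ova").fit(tab.X[tr], y_scr[tr])
            rep = ns.f1_scores(model.predict(tab.X[~tr]), y_scr[~tr],
                               classes=np.arange(3))
            scores.append(rep.f1_macro)
        assert abs(np.mean(scores) - 1 / 3) < 0.06

    def test_ovo_learner_count(self):
        """OVO on 12 classes trains 66 binary learners."""
        assert _code_matrix(12, "ovo").shape == (12, 66)
        rng = np.random.default_rng(2)
        X = rng.standard_normal((240, 5)) + np.repeat(np.eye(12, 5), 20, axis=0)
        y = np.repeat(np.arange(12), 20)
        model = ns.EcocModel("ovo").fit(X, y)
        assert len(model.learners_) == 66

    def test_ova_pbs_dimensionality(self):
        tab = simplex_toy()
        model = ns.fit_ecoc(tab, scheme="ova")
        scores = model.decision_scores(tab.X[:5])
        assert scores.shape == (5, 3)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            ns.EcocModel().fit(np.zeros((10, 2)), np.zeros(10))

    def test_ties_break_to_lowest_class(self):
        code = _code_matrix(4, "ova")
        assert np.allclose(code.sum(axis=1), -2.0)  # 1 positive, 3 negative
        votes = np.array([[2, 1, 1], [0, 0, 3]])
        # one-vote ties resolve to the lowest label
        assert list(_mode_vote(votes)) == [0, 0, 1]


class TestF1:
    def test_perfect_prediction(self):
        rep = ns.f1_scores(np.arange(12), np.arange(12))
        assert np.all(rep.f1_minor == 1.0)
        assert rep.f1_macro == 1.0

    def test_harmonic_mean_of_equals(self):
        """p = r = 0.5 for both classes -> f1 = 0.5 each."""
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 1, 0])
        rep = ns.f1_scores(pred, truth)
        assert np.allclose(rep.f1_minor, 0.5)

    def test_hand_computed_confusion(self):
        """Confusion [[8,2],[4,6]]: f1 = (0.7273, 0.6667), macro 0.6970."""
        truth = np.array([0] * 10 + [1] * 10)
        pred = np.array([0] * 8 + [1] * 2 + [0] * 4 + [1] * 6)
        rep = ns.f1_scores(pred, truth)
        assert rep.f1_minor[0] == pytest.approx(0.7273, abs=1e-4)
        assert rep.f1_minor[1] == pytest.approx(0.6667, abs=1e-4)
        assert rep.f1_macro == pytest.approx(0.6970, abs=1e-4)
        assert np.array_equal(rep.confusion, [[8, 2], [4, 6]])

    def test_fuzz_against_sklearn(self, rng):
        """200 random label vectors match sklearn's macro F1 exactly."""
        from sklearn.metrics import f1_score
        for _ in range(200):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(10, 60))
            truth = rng.integers(0, k, size=n)
            pred = rng.integers(0, k, size=n)
            rep = ns.f1_scores(pred, truth, classes=np.arange(k))
            skl = f1_score(truth, pred, labels=np.arange(k), average="macro",
                           zero_division=0)
            assert rep.f1_macro == pytest.approx(skl, abs=1e-12)


class TestEmpiricalP:
    @pytest.mark.parametrize("b,m,expected", [(0, 100, 1 / 101), (99, 99, 1.0),
                                              (4, 99, 0.05)])
    def test_formula_cases(self, b, m, expected):
        dist = ns.PermutationDistribution(
            true_scores=np.array([0.5]),
            null_scores=np.concatenate([np.full(b, 0.9), np.full(m - b, 0.1)]))
        assert ns.empirical_p(dist) == pytest.approx(expected)

    def test_bounds(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            dist = ns.PermutationDistribution(rng.random(5), rng.random(m))
            p = ns.empirical_p(dist)
            assert 1 / (m + 1) <= p <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ns.empirical_p(ns.PermutationDistribution(np.array([]), np.array([])))


class TestProtocol:
    def test_subject_split_never_leaks(self, rng):
        subjects = np.arange(17)
        for _ in range(50):
            tr, te = _subject_split(subjects, 0.75, rng)
            assert np.intersect1d(tr, te).size == 0
            assert len(tr) + len(te) == 17

    def test_scramble_preserves_within_subject_multiset(self, rng):
        y = np.tile(np.arange(4), 6)
        g = np.repeat(np.arange(3), 8)
        y_scr = _scramble_within_subject(y, g, rng)
        for s in range(3):
            assert sorted(y_scr[g == s]) == sorted(y[g == s])

    def test_heldout_eval_structure(self, ba_table):
        res = ns.repeated_heldout_eval(ba_table, n_rep=3, seed=0)
        assert len(res.dist.true_scores) == 3
        assert len(res.dist.null_scores) == 3
        assert len(res.cv_scores) == 3
        assert res.dist.true_scores.mean() > res.dist.null_scores.mean()
        # every event either never or some times tested, counts consistent
        assert np.all(res.event_correct <= res.event_tested)

    def test_signal_beats_null_with_significance(self, ba_table):
        res = ns.repeated_heldout_eval(ba_table, n_rep=10, seed=3, with_cv=False)
        assert res.p == pytest.approx(1 / 11)

    def test_too_few_subjects_rejected(self):
        tab = ns.FeatureTable(np.zeros((12, 2)), np.tile([0, 1], 6),
                              np.repeat([0, 1, 2], 4))
        with pytest.raises(ValueError, match="8 subjects"):
            ns.repeated_heldout_eval(tab)


class TestStack:
    def test_stage2_feature_count_is_24(self, small_cohort, ba_table, dfc_table):
        """Two metrics x 12 classes -> 24 stack features."""
        from netstate.classification import _group_kfold, _stage1_pbs
        rng = np.random.default_rng(0)
        subjects = np.unique(ba_table.groups)
        tr_subj, te_subj = _subject_split(subjects, 0.75, rng)
        tr = np.isin(ba_table.groups, tr_subj)
        folds = _group_kfold(tr_subj, 5, rng)
        oof_ba, _ = _stage1_pbs(ba_table, tr, ~tr, folds, 1.0)
        oof_dfc, _ = _stage1_pbs(dfc_table, tr, ~tr, folds, 1.0)
        stacked = np.hstack([oof_ba, oof_dfc])
        assert stacked.shape == (tr.sum(), 24)

    def test_duplicated_metric_matches_single(self, ba_table):
        """Identical PBS from both metrics reproduces the single-metric
        stack prediction."""
        single = ns.stack_heldout_eval({"a": ba_table}, n_rep=2, seed=5)
        double = ns.stack_heldout_eval({"a": ba_table, "b": ba_table},
                                       n_rep=2, seed=5)
        assert np.allclose(single.dist.true_scores, double.dist.true_scores)

    def test_stack_not_destroyed_by_noise_metric(self, ba_table, rng):
        """One pure-noise metric plus one signal metric: the stack stays at
        or above the noise metric alone (paired over repetitions)."""
        noise_tab = ns.FeatureTable(rng.standard_normal(ba_table.X.shape),
                                    ba_table.y, ba_table.groups)
        stack = ns.stack_heldout_eval({"sig": ba_table, "noise": noise_tab},
                                      n_rep=5, seed=2)
        noise_only = ns.repeated_heldout_eval(noise_tab, n_rep=5, seed=2,
                                              with_cv=False, with_null=False)
        assert stack.dist.true_scores.mean() >= noise_only.dist.true_scores.mean()

    def test_misaligned_tables_rejected(self, ba_table):
        other = ns.FeatureTable(ba_table.X, np.roll(ba_table.y, 1), ba_table.groups)
        with pytest.raises(ValueError, match="aligned"):
            ns.stack_heldout_eval({"a": ba_table, "b": other}, n_rep=1)


class TestPairwiseBinary:
    def test_66_pairs_and_negative_association(self, small_cohort, ba_table):
        """All 66 task pairs are evaluated and pair accuracy anticorrelates
        with planted psychometric similarity."""
        psy = ns.psychometric_similarity(small_cohort.ground_truth.factor_loadings)
        res = ns.pairwise_binary_eval(ba_table, psy, n_rep=3, seed=0)
        assert len(res.pair_accuracies) == 66
        assert res.association.r < 0
        assert res.association.tail == "left"

    def test_indistinguishable_pair_at_chance(self):
        """Identical class-conditional generators -> mean pair accuracy ~0.5
        (averaged over independent data draws; a single small sample has
        subject-level accuracy noise of ~0.1)."""
        means = []
        for seed in range(3):
            local = np.random.default_rng(seed)
            X = local.standard_normal((240, 6))
            y = np.tile(np.arange(12), 20)
            g = np.repeat(np.arange(20), 12)
            tab = ns.FeatureTable(X, y, g)
            v = local.random((12, 12)); v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            psy = ns.SimilarityMatrix(values=v, kind="psychometric")
            res = ns.pairwise_binary_eval(tab, psy, n_rep=3, seed=1)
            means.append(np.mean(list(res.pair_accuracies.values())))
        assert abs(np.mean(means) - 0.5) < 0.06


class TestMetaClass:
    def test_identity_scheme_reduces_to_multiway(self, ba_table):
        """Singleton classes reproduce the plain 12-way protocol."""
        scheme = ns.MetaClassScheme("identity", {t: t for t in range(12)})
        res = ns.metaclass_eval(ba_table, scheme, n_rep=2, n_perm=2, seed=4)
        plain = ns.repeated_heldout_eval(ba_table, n_rep=2, seed=4, with_cv=False)
        assert np.allclose(res.true_scores, plain.dist.true_scores)

    def test_null_three_balanced_classes_at_chance(self, ba_table):
        """Scrambled labels on 3 balanced meta-classes -> F1 ~ 1/3."""
        scheme = ns.MetaClassScheme("psychometric", {t: t % 3 for t in range(12)})
        res = ns.metaclass_eval(ba_table, scheme, n_rep=6, n_perm=2, seed=0)
        assert abs(res.null_scores.mean() - 1 / 3) < 0.08

    def test_factor_scheme_beats_size_preserving_permutations(self, small_cohort,
                                                              ba_table):
        """Meta-classes aligned with the planted factors outperform random
        task-to-class assignments of the same sizes."""
        gt = small_cohort.ground_truth
        scheme = ns.MetaClassScheme("psychometric",
                                    {t: int(gt.task_factor[t]) for t in range(12)})
        res = ns.metaclass_eval(ba_table, scheme, n_rep=5, n_perm=12, seed=1)
        assert res.true_scores.mean() > res.perm_scores.mean()
        assert res.p_vs_perm < 0.2

    def test_degenerate_scheme_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ns.MetaClassScheme("broken", {t: 0 for t in range(12)})


class TestSparseSelection:
    def test_planted_feature_recovered(self, rng):
        """A single informative feature per task dominates the positive
        selection frequencies."""
        n_subj, n_feat = 12, 40
        y = np.tile(np.arange(4), n_subj * 3)
        g = np.repeat(np.arange(n_subj), 12)
        X = 0.3 * rng.standard_normal((len(y), n_feat))
        for t in range(4):
            X[y == t, t] += 2.0  # feature t fires for task t only
        tab = ns.FeatureTable(X, y, g)
        summary = ns.sparse_connection_selection(tab)
        assert np.all(np.argsort(-summary.pos_frequency)[:4] < 4)
        # a feature informative for exactly 1 of 4 tasks tops out at 0.25
        # after averaging the binarised maps across tasks
        assert summary.pos_frequency[:4].min() > 0.15
        assert summary.pos_frequency[4:].max() < summary.pos_frequency[:4].min()

    def test_all_zero_features_empty_selection(self):
        tab = ns.FeatureTable(np.zeros((120, 10)), np.tile(np.arange(4), 30),
                              np.repeat(np.arange(10), 12))
        with pytest.warns(UserWarning, match="all-zero"):
            summary = ns.sparse_connection_selection(tab)
        assert summary.pos_frequency.max() == 0
        assert summary.top_pos.size == 0

    def test_too_few_subjects_rejected(self, rng):
        tab = ns.FeatureTable(rng.standard_normal((24, 4)),
                              np.tile([0, 1], 12), np.repeat(np.arange(4), 6))
        with pytest.raises(ValueError, match="10 subjects"):
            ns.sparse_connection_selection(tab)
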