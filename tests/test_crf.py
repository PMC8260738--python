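import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import enum_best_path, enum_log_partition, enum_marginals

from conftest import random_chain_instance
from sleepreact import crf
from sleepreact.design import EXCLUDED, LabelSeries


def make_model(lam, mu, states=None, uniform=False, l2=0.0):
    lam = np.asarray(lam, float)
    mu = np.asarray(mu, float)
    states = states or [f"s{i}" for i in range(mu.shape[0])]
    return crf.CRFModel(states=states, lam=lam, mu=mu, transitions_uniform=uniform, l2=l2)


def feats_of(x):
    x = np.asarray(x, float)
    return crf.FeatureMatrix(x, np.zeros(x.shape[1]), np.ones(x.shape[1]))


class TestFeaturize:
    def test_zero_variance_column_becomes_zero_with_warning(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            f = crf.featurize(x)
        assert np.all(f.values[:, 1] == 0)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        f1 = crf.featurize(rng.normal(size=(50, 4)))
        f2 = crf.featurize(f1.values)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-12)

    def test_train_stats_applied_to_test_leave_offset(self):
        rng = np.random.default_rng(1)
        train = rng.normal(size=(100, 3))
        test = rng.normal(loc=0.5, size=(100, 3))
        ftr = crf.featurize(train)
        fte = crf.featurize(test, ftr.stats)
        assert np.abs(fte.values.mean(axis=0)).min() > 0.01

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            crf.featurize(np.array([[1.0, np.inf]]))


class TestSequenceScore:
    def test_zero_weights_scores_zero(self):
        m = make_model(np.zeros((2, 2)), np.zeros((2, 3)))
        f = feats_of(np.random.default_rng(0).normal(size=(4, 2)))
        assert crf.sequence_score(m, f, np.array(["s0", "s1", "s0", "s0"], object)) == 0.0

    def test_single_scan_has_no_transition_term(self):
        mu = np.array([[1.0, 2.0, 0.5], [0.0, -1.0, 0.2]])
        m = make_model(np.full((2, 2), 100.0), mu)
        f = feats_of([[2.0, 3.0]])
        expected = mu[1] @ [2.0, 3.0, 1.0]
        assert crf.sequence_score(m, f, np.array(["s1"], object)) == pytest.approx(expected)

    def test_hand_computed_three_scan_chain(self):
        lam = np.array([[0.1, 0.2], [0.3, 0.4]])
        mu = np.array([[1.0, 0.5], [-1.0, 0.25]])  # 1 feature + bias
        m = make_model(lam, mu)
        f = feats_of([[1.0], [2.0], [3.0]])
        # y = (s0, s1, s1):
        # state terms: (1*1+0.5) + (-1*2+0.25) + (-1*3+0.25)
        # transitions: lam[0,1] + lam[1,1]
        expected = 1.5 + (-1.75) + (-2.75) + 0.2 + 0.4
        assert crf.sequence_score(m, f, np.array(["s0", "s1", "s1"], object)) == pytest.approx(expected)

    def test_excluded_label_rejected(self):
        m = make_model(np.zeros((2, 2)), np.zeros((2, 2)))
        f = feats_of([[1.0], [1.0]])
        with pytest.raises(ValueError, match="Excluded"):
            crf.sequence_score(m, f, np.array(["s0", EXCLUDED], object))


class TestLogPartition:
    def test_zero_weights_gives_T_log_S(self):
        m = make_model(np.zeros((3, 3)), np.zeros((3, 4)))
        f = feats_of(np.random.default_rng(0).normal(size=(5, 3)))
        assert crf.log_partition(m, f) == pytest.approx(5 * np.log(3))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        m = make_model(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
        f = feats_of(rng.normal(size=(3, 2)))
        assert crf.log_partition(m, f) == pytest.approx(
            enum_log_partition(m.lam, m.state_scores(f)), abs=1e-10
        )

    def test_bias_shift_adds_T_times_c(self):
        rng = np.random.default_rng(3)
        m = make_model(rng.normal(size=(2, 2)), rng.normal(size=(2, 3)))
        f = feats_of(rng.normal(size=(4, 2)))
        z0 = crf.log_partition(m, f)
        m.mu[:, -1] += 0.7
        assert crf.log_partition(m, f) == pytest.approx(z0 + 4 * 0.7)

    def test_normalizes_sequence_probability(self):
        rng = np.random.default_rng(4)
        m = make_model(rng.normal(size=(2, 2)), rng.normal(size=(2, 3)))
        f = feats_of(rng.normal(size=(3, 2)))
        logz = crf.log_partition(m, f)
        total = 0.0
        import itertools

        for p in itertools.product(["s0", "s1"], repeat=3):
            total += np.exp(crf.sequence_score(m, f, np.array(p, object)) - logz)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_convex_along_random_directions(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m0 = make_model(rng.normal(size=(2, 2)), rng.normal(size=(2, 3)))
            f = feats_of(rng.normal(size=(4, 2)))
            d_lam = rng.normal(size=(2, 2))
            d_mu = rng.normal(size=(2, 3))
            eps = 1e-3

            def z(s):
                m = make_model(m0.lam + s * d_lam, m0.mu + s * d_mu)
                return crf.log_partition(m, f)

            second = (z(eps) - 2 * z(0) + z(-eps)) / eps**2
            assert second >= -1e-8


class TestLogLikelihood:
    def test_zero_weights_uniform_likelihood(self):
        m = make_model(np.zeros((5, 5)), np.zeros((5, 3)), uniform=True)
        f = feats_of(np.random.default_rng(0).normal(size=(7, 2)))
        labels = LabelSeries(np.array(["s0"] * 7, object), tr=1.0)
        L, _ = crf.log_likelihood(m, [(f, labels)])
        assert L == pytest.approx(-7 * np.log(5))

    @pytest.mark.parametrize("uniform", [True, False])
    def test_gradient_matches_finite_differences(self, uniform):
        rng = np.random.default_rng(6)
        lam = np.zeros((2, 2)) if uniform else rng.normal(size=(2, 2))
        mu = rng.normal(size=(2, 3))
        f = feats_of(rng.normal(size=(4, 2)))
        labels = LabelSeries(np.array(["s0", "s1", "s1", "s0"], object), tr=1.0)
        m = make_model(lam, mu, uniform=uniform, l2=0.1)
        _, (g_lam, g_mu) = crf.log_likelihood(m, [(f, labels)])
        eps = 1e-6
        for i in range(2):
            for j in range(3):
                mp = make_model(lam, mu.copy(), uniform=uniform, l2=0.1)
                mp.mu[i, j] += eps
                mm = make_model(lam, mu.copy(), uniform=uniform, l2=0.1)
                mm.mu[i, j] -= eps
                fd = (crf.log_likelihood(mp, [(f, labels)])[0] - crf.log_likelihood(mm, [(f, labels)])[0]) / (2 * eps)
                assert g_mu[i, j] == pytest.approx(fd, abs=1e-6)
        if not uniform:
            for i in range(2):
                for j in range(2):
                    mp = make_model(lam.copy(), mu, l2=0.1)
                    mp.lam[i, j] += eps
                    mm = make_model(lam.copy(), mu, l2=0.1)
                    mm.lam[i, j] -= eps
                    fd = (crf.log_likelihood(mp, [(f, labels)])[0] - crf.log_likelihood(mm, [(f, labels)])[0]) / (2 * eps)
                    assert g_lam[i, j] == pytest.approx(fd, abs=1e-6)

    def test_gradient_small_at_fitted_optimum(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(60, 2))
        y = np.where(x[:, 0] + 0.5 * x[:, 1] > 0, "s0", "s1").astype(object)
        dataset = [(feats_of(x), LabelSeries(y, tr=1.0))]
        model = crf.fit_crf(dataset, states=["s0", "s1"], l2=1e-2)
        _, (_, g_mu) = crf.log_likelihood(model, dataset)
        assert np.max(np.abs(g_mu)) / len(y) < 1e-4


class TestInference:
    def test_uniform_zero_weights_give_uniform_marginals(self):
        m = make_model(np.zeros((5, 5)), np.zeros((5, 3)), uniform=True)
        f = feats_of(np.random.default_rng(0).normal(size=(6, 2)))
        lik = crf.posterior_marginals(m, f)
        np.testing.assert_allclose(lik.probs, 0.2)

    def test_marginals_match_enumeration(self):
        rng = np.random.default_rng(8)
        m = make_model(rng.normal(size=(2, 2)), rng.normal(size=(2, 3)))
        f = feats_of(rng.normal(size=(4, 2)))
        got = crf.posterior_marginals(m, f).probs
        want = enum_marginals(m.lam, m.state_scores(f))
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_extreme_bias_saturates_marginal(self):
        rng = np.random.default_rng(9)
        m = make_model(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
        m.mu[1, -1] += 50.0
        f = feats_of(rng.normal(scale=0.1, size=(5, 2)))
        lik = crf.posterior_marginals(m, f)
        assert np.all(lik.probs[:, 1] > 1 - 1e-9)

    def test_uniform_viterbi_is_per_scan_argmax(self):
        rng = np.random.default_rng(10)
        m = make_model(np.zeros((3, 3)), rng.normal(size=(3, 4)), uniform=True)
        f = feats_of(rng.normal(size=(10, 3)))
        path = crf.viterbi_decode(m, f)
        want = np.argmax(m.state_scores(f), axis=1)
        assert [m.states[i] for i in want] == list(path.labels)

    def test_viterbi_matches_brute_force(self):
        rng = np.random.default_rng(11)
        m = make_model(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
        f = feats_of(rng.normal(size=(5, 2)))
        got = crf.viterbi_decode(m, f)
        want = enum_best_path(m.lam, m.state_scores(f))
        assert list(got.labels) == [m.states[i] for i in want]

    def test_exact_tie_breaks_to_lower_state_index(self):
        m = make_model(np.zeros((3, 3)), np.zeros((3, 2)), uniform=True)
        f = feats_of(np.zeros((4, 1)))
        path = crf.viterbi_decode(m, f)
        assert all(l == "s0" for l in path.labels)

    def test_uniform_viterbi_equals_marginal_argmax(self):
        rng = np.random.default_rng(12)
        m = make_model(np.zeros((4, 4)), rng.normal(size=(4, 3)), uniform=True)
        f = feats_of(rng.normal(size=(20, 2)))
        path = crf.viterbi_decode(m, f)
        marg = crf.posterior_marginals(m, f).probs
        assert [m.states[i] for i in np.argmax(marg, axis=1)] == list(path.labels)


class TestChainPropertyChecks:
    """Randomized agreement between dynamic programming and enumeration."""

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), scale=st.floats(0.1, 3.0))
    def test_row_stochastic_marginals_for_arbitrary_models(self, seed, scale):
        rng = np.random.default_rng(seed)
        model, f = random_chain_instance(rng, T=int(rng.integers(1, 30)), scale=scale)
        probs = crf.posterior_marginals(model, f).probs
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.min() >= 0.0

    def test_forward_backward_agrees_with_enumeration_on_100_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            model, f = random_chain_instance(rng)
            scores = model.state_scores(f)
            assert crf.log_partition(model, f) == pytest.approx(
                enum_log_partition(model.lam, scores), abs=1e-10
            )
            got = crf.posterior_marginals(model, f).probs
            np.testing.assert_allclose(got, enum_marginals(model.lam, scores), atol=1e-10)
            np.testing.assert_allclose(got.sum(axis=1), 1.0, atol=1e-9)
            assert list(crf.viterbi_decode(model, f).labels) == [
                model.states[i] for i in enum_best_path(model.lam, scores)
            ]


class TestFit:
    def test_separable_two_state_toy_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(14)
        x = np.concatenate([rng.normal(-3, 0.3, size=(30, 1)), rng.normal(3, 0.3, size=(30, 1))])
        y = np.array(["lo"] * 30 + ["hi"] * 30, object)
        dataset = [(feats_of(x), LabelSeries(y, tr=1.0))]
        model = crf.fit_crf(dataset, states=["lo", "hi"], l2=1e-3)
        pred = crf.viterbi_decode(model, feats_of(x))
        assert np.mean(pred.labels == y) == 1.0

    def test_uniform_transition_posteriors_match_softmax_regression(self):
        """With lambda pinned at 0 the CRF is a multinomial logistic model;
        an independently fitted sklearn softmax regression with the same l2
        must produce the same posteriors."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(15)
        n, l2 = 300, 1e-2
        x = rng.normal(size=(n, 4))
        w_true = rng.normal(size=(3, 4))
        y_idx = np.argmax(x @ w_true.T + rng.normal(scale=0.5, size=(n, 3)), axis=1)
        states = ["a", "b", "c"]
        y = np.array([states[i] for i in y_idx], object)
        dataset = [(feats_of(x), LabelSeries(y, tr=1.0))]
        model = crf.fit_crf(dataset, states=states, l2=l2, max_iter=2000, grad_tol=1e-9)

        x1 = np.hstack([x, np.ones((n, 1))])
        sk = LogisticRegression(
            C=1.0 / l2, fit_intercept=False, tol=1e-10, max_iter=5000
        ).fit(x1, y_idx)
        probs_sk = sk.predict_proba(x1)
        probs_crf = crf.posterior_marginals(model, feats_of(x)).probs
        np.testing.assert_allclose(probs_crf, probs_sk, atol=1e-4)

    def test_missing_state_raises(self):
        y = np.array(["a", "a", "b"], object)
        dataset = [(feats_of(np.eye(3)), LabelSeries(y, tr=1.0))]
        with pytest.raises(ValueError, match="missing state"):
            crf.fit_crf(dataset, states=["a", "b", "c"])

    def test_model_json_roundtrip(self):
        rng = np.random.default_rng(16)
        m = make_model(rng.normal(size=(2, 2)), rng.normal(size=(2, 3)))
        m.feature_mean = np.array([0.0, 1.0])
        m.feature_sd = np.array([1.0, 2.0])
        m2 = crf.CRFModel.from_json(m.to_json())
        np.testing.assert_array_equal(m2.mu, m.mu)
        np.testing.assert_array_equal(m2.feature_sd, m.feature_sd)


class TestCrossValidation:
    def test_duplicate_noiseless_subjects_decode_perfectly(self):
        from sleepreact.design import STATES
        from sleepreact.simulate import default_patterns

        # features exactly equal to each scan's state pattern: any fold
        # trains on identical copies of the distribution it tests
        pat = default_patterns(8, seed=1)
        rng = np.random.default_rng(0)
        labels = np.array([STATES[i] for i in rng.integers(0, 5, size=120)], object)
        x = np.vstack([pat.row(l) for l in labels])
        lab = LabelSeries(labels, tr=1.0)
        cm, acc = crf.cross_validate([(x, lab)] * 3, l2=1e-3)
        for state in STATES:
            assert acc[state] == pytest.approx(1.0)

    def test_confusion_rows_match_held_out_label_counts(self, tiny_game_cohort):
        data = [(s.game_ts.values, s.game_labels) for s in tiny_game_cohort.subjects]
        cm, _ = crf.cross_validate(data)
        from collections import Counter

        want = Counter()
        for _, lab in data:
            want.update(l for l in lab.labels if l != EXCLUDED)
        for i, state in enumerate(cm.states):
            assert cm.counts[i].sum() == want[state]

    def test_pre_states_mostly_confused_with_rest(self, tiny_game_cohort):
        data = [(s.game_ts.values, s.game_labels) for s in tiny_game_cohort.subjects]
        cm, _ = crf.cross_validate(data)
        for pre in ("PreFace", "PreMaze"):
            row = cm.counts[cm.states.index(pre)]
            assert row[cm.states.index("Rest")] > row.sum() / 2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            crf.cross_validate([(np.zeros((4, 2)), LabelSeries(np.array(["a"] * 4, object), 1.0))])
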