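import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bodycues as bc
from bodycues.classify import (
    LIE,
    TRUTH,
    WindowDataset,
    feature_p_values,
    feature_votes,
    majority_vote,
    majority_votes,
)


def _two_class_data(rng, n_per_class=30, n_features=8, shift=0.0):
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(n_per_class, n_features)),
            rng.normal(shift, 1.0, size=(n_per_class, n_features)),
        ]
    )
    y = np.array([TRUTH] * n_per_class + [LIE] * n_per_class)
    return X, y


class TestFit:
    def test_hand_arithmetic(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        y = np.array([TRUTH, TRUTH, LIE, LIE])
        m = bc.fit(X, y)
        assert m.mu[TRUTH, 0] == pytest.approx(1.0)
        assert m.mu[LIE, 0] == pytest.approx(11.0)
        assert m.sigma[TRUTH, 0] == pytest.approx(np.sqrt(2.0))
        assert m.sigma[LIE, 0] == pytest.approx(np.sqrt(2.0))
        assert m.n_per_class == (2, 2)

    def test_deterministic(self, rng):
        X, y = _two_class_data(rng)
        a, b = bc.fit(X, y), bc.fit(X, y)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_matches_independent_mean_sd(self, rng):
        """Plain-Python statistics module as the independent oracle."""
        X, y = _two_class_data(rng, n_per_class=50, n_features=2)
        m = bc.fit(X, y)
        for c in (TRUTH, LIE):
            for f in range(2):
                vals = [X[i, f] for i in range(len(y)) if y[i] == c]
                assert m.mu[c, f] == pytest.approx(statistics.fmean(vals), abs=1e-12)
                assert m.sigma[c, f] == pytest.approx(statistics.stdev(vals), abs=1e-12)

    def test_requires_two_samples_per_class(self):
        with pytest.raises(ValueError, match=">= 2"):
            bc.fit(np.zeros((3, 1)), np.array([TRUTH, TRUTH, LIE]))

    def test_constant_feature_sigma_floored(self):
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        y = np.array([TRUTH, TRUTH, LIE, LIE])
        m = bc.fit(X, y)
        assert (m.sigma > 0).all()
        # classification still well defined
        votes = feature_votes(m, np.array([[1.0]]))
        assert votes[0, 0] in (TRUTH, LIE)


class TestClassifyFeature:
    def test_value_at_class_mean(self):
        m = bc.fit(np.array([[0.0], [0.2], [2.0], [2.2]]),
                   np.array([TRUTH, TRUTH, LIE, LIE]))
        assert bc.classify_feature(m, 0, m.mu[TRUTH, 0]) == "truth"
        assert bc.classify_feature(m, 0, m.mu[LIE, 0]) == "lie"

    def test_exact_midpoint_tie_goes_to_truth(self):
        m = bc.PerFeatureGaussianModel(
            mu=np.array([[0.0], [2.0]]), sigma=np.array([[1.0], [1.0]]),
            n_per_class=(5, 5),
        )
        assert bc.classify_feature(m, 0, 1.0) == "truth"

    def test_wider_class_wins_in_the_tail(self):
        # N(3; 0, 1) ~ 0.00443 < N(3; 0, 2) ~ 0.0648
        m = bc.PerFeatureGaussianModel(
            mu=np.array([[0.0], [0.0]]), sigma=np.array([[1.0], [2.0]]),
            n_per_class=(5, 5),
        )
        assert bc.classify_feature(m, 0, 3.0) == "lie"

    def test_votes_agree_with_log_density_oracle(self, rng):
        mu = rng.normal(size=(2, 50))
        sigma = rng.uniform(0.1, 3.0, size=(2, 50))
        m = bc.PerFeatureGaussianModel(mu=mu, sigma=sigma, n_per_class=(5, 5))
        X = rng.normal(size=(200, 50))
        votes = feature_votes(m, X)
        from scipy.stats import norm

        ll_t = norm.logpdf(X, mu[TRUTH], sigma[TRUTH])
        ll_l = norm.logpdf(X, mu[LIE], sigma[LIE])
        assert np.array_equal(votes, (ll_l > ll_t).astype(int))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mu_t=st.floats(-5, 5), gap=st.floats(0.1, 5),
        sigma=st.floats(0.1, 3), x_off=st.floats(-4, 4),
    )
    def test_equal_sigma_boundary_is_midpoint(self, mu_t, gap, sigma, x_off):
        mu_l = mu_t + gap
        m = bc.PerFeatureGaussianModel(
            mu=np.array([[mu_t], [mu_l]]), sigma=np.array([[sigma], [sigma]]),
            n_per_class=(5, 5),
        )
        x = mu_t + x_off
        predicted = bc.classify_feature(m, 0, x)
        midpoint = (mu_t + mu_l) / 2
        if x < midpoint:
            assert predicted == "truth"
        elif x > midpoint:
            assert predicted == "lie"


class TestSelection:
    def test_identical_distributions_not_selected(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.concatenate([vals, vals])[:, None]
        y = np.array([TRUTH] * 4 + [LIE] * 4)
        sel = bc.select_features(X, y, alpha=0.05)
        assert sel.p_values[0] == pytest.approx(1.0)
        assert len(sel) == 0

    def test_separated_classes_selected(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 1)), rng.normal(10, 1, (50, 1))])
        y = np.array([TRUTH] * 50 + [LIE] * 50)
        sel = bc.select_features(X, y, alpha=0.01)
        assert list(sel.indices) == [0]
        # cross-check the p-value against the reference test implementation
        from scipy.stats import ttest_ind

        expect = ttest_ind(X[y == TRUTH, 0], X[y == LIE, 0], equal_var=False).pvalue
        assert sel.p_values[0] == pytest.approx(expect, abs=1e-15)

    def test_alpha_one_selects_all(self, rng):
        X, y = _two_class_data(rng, n_features=335)
        sel = bc.select_features(X, y, alpha=1.0)
        assert len(sel) == 335

    def test_stat99_subset_of_stat95(self, rng):
        X, y = _two_class_data(rng, n_features=100, shift=0.5)
        s95 = bc.select_features(X, y, alpha=0.05)
        s99 = bc.select_features(X, y, alpha=0.01)
        assert set(s99.indices) <= set(s95.indices)

    def test_degenerate_zero_variance_gets_p_one(self):
        X = np.array([[1.0], [1.0], [2.0], [2.0]])
        y = np.array([TRUTH, TRUTH, LIE, LIE])
        assert feature_p_values(X, y)[0] == 1.0

    def test_alternative_tests_available(self, rng):
        X, y = _two_class_data(rng, n_features=5, shift=2.0)
        for method in ("student", "mannwhitney"):
            sel = bc.select_features(X, y, alpha=0.01, method=method)
            assert len(sel) == 5


class TestSorting:
    def test_ascending_p_order(self):
        sel = bc.FeatureSelection(
            indices=np.array([0, 1, 2]),
            alpha=1.0,
            p_values=np.array([0.5, 0.001, 0.2]),
        )
        assert list(bc.sort_features_by_significance(sel)) == [1, 2, 0]

    def test_ties_break_by_catalogue_order(self):
        sel = bc.FeatureSelection(
            indices=np.array([2, 0, 1]),
            alpha=1.0,
            p_values=np.array([0.3, 0.3, 0.3]),
        )
        assert list(bc.sort_features_by_significance(sel)) == [0, 1, 2]

    def test_topk_prefix_property(self, rng):
        p = rng.uniform(size=40)
        sel = bc.FeatureSelection(indices=np.arange(40), alpha=1.0, p_values=p)
        order = bc.sort_features_by_significance(sel)
        for k in range(1, 40):
            assert list(order[:k]) == list(order[: k + 1])[:-1]


class TestMajorityVote:
    def test_simple_majority(self):
        assert majority_vote(np.array([TRUTH, TRUTH, LIE]), np.arange(3)) == TRUTH
        assert majority_vote(np.array([LIE, LIE, TRUTH]), np.arange(3)) == LIE

    def test_tie_goes_to_truth(self):
        assert majority_vote(np.array([TRUTH, LIE]), np.arange(2)) == TRUTH

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            majority_vote(np.array([TRUTH]), np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            majority_votes(np.zeros((2, 3), dtype=int), np.array([], dtype=int))

    def test_odd_count_never_ties(self, rng):
        votes = rng.integers(0, 2, size=335)
        lie_share = votes.sum()
        assert 2 * lie_share != 335  # parity: an odd electorate cannot tie


@pytest.fixture(scope="module")
def separable_dataset():
    rng = np.random.default_rng(0)
    n_people = 8
    rows, y, person, kind = [], [], [], []
    for i in range(n_people):
        label = i % 2
        for k in ("game", "wallet"):
            rows.append(rng.normal(10.0 * label, 0.5, size=4))
            y.append(label)
            person.append(f"p{i}")
            kind.append(k)
    return WindowDataset(
        X=np.array(rows), y=np.array(y),
        interviewee=np.array(person), kind=np.array(kind),
    )


class TestLoocv:
    def test_fold_count_and_training_size(self, separable_dataset):
        res = bc.loocv(separable_dataset, alpha=1.0)
        assert len(res.folds) == 8
        for f in res.folds:
            # trains on the other 7 pairs: 14 windows, 6/8 split by class
            assert sum(f.model.n_per_class) == 14
            assert sorted(f.model.n_per_class) == [6, 8]

    def test_separable_corpus_fully_recovered(self, separable_dataset):
        res = bc.loocv(separable_dataset, alpha=1.0)
        assert res.detection_rate == 1.0

    def test_rate_invariant_to_session_order(self, separable_dataset):
        rng = np.random.default_rng(5)
        perm = rng.permutation(separable_dataset.n_windows)
        shuffled = WindowDataset(
            X=separable_dataset.X[perm], y=separable_dataset.y[perm],
            interviewee=separable_dataset.interviewee[perm],
            kind=separable_dataset.kind[perm],
        )
        a = bc.loocv(separable_dataset, alpha=1.0).detection_rate
        b = bc.loocv(shuffled, alpha=1.0).detection_rate
        assert a == b

    def test_kind_restrictions(self, separable_dataset):
        res = bc.loocv(
            separable_dataset, train_kinds=("game",), test_kinds=("wallet",), alpha=1.0
        )
        assert len(res.folds) == 8
        for f in res.folds:
            assert f.test_true.shape == (1,)  # one wallet session per person

    def test_confusion_matrix_percentages(self, separable_dataset):
        res = bc.loocv(separable_dataset, alpha=1.0)
        cm = res.confusion()
        assert cm.sum() == pytest.approx(100.0)
        assert np.trace(cm) == pytest.approx(100.0)  # perfect separation
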