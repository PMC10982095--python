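"""Per-feature Gaussian Naive Bayes with majority voting and LOOCV.

Each of the 335 window features gets its own two-class Gaussian classifier:
for class :math:`c` (truth or lie) and feature :math:`i`, the training
samples yield a mean :math:`\\mu_{ci}` and sample standard deviation
:math:`\\sigma_{ci}`, and a test value :math:`x_i` is assigned to

.. math::

    \\hat{c}_i = \\operatorname{argmax}_c
        \\frac{1}{\\sigma_{ci}\\sqrt{2\\pi}}
        e^{-(x_i - \\mu_{ci})^2 / (2\\sigma_{ci}^2)}

with equal prior probabilities for the two classes. A window is classified
by the majority vote of the per-feature decisions, either over all features
(*all*) or only over those whose truth/lie training distributions differ
significantly at the 5% (*stat-95*) or 1% (*stat-99*) level.

Evaluation is leave-one-interviewee-out cross-validation: each fold trains
on the windows of all other interviewees (optionally restricted to Game or
Wallet sessions) and tests on the held-out interviewee's windows.

Exact density ties and exact vote ties resolve to "truth" — a deterministic,
conservative rule in line with the truth bias of such classifiers; seeded
random tie-breaking is available via ``tie_break="random"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .windows import N_DIMS, WindowVector

CLASSES = ("truth", "lie")
TRUTH, LIE = 0, 1

#: relative floor applied to degenerate (zero) class standard deviations
_SIGMA_FLOOR_REL = 1e-9


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class WindowDataset:
    """Flat matrix view of a corpus's window vectors.

    ``X`` is ``(n_windows, 335)``; ``y`` holds 0 (truth) / 1 (lie);
    ``interviewee`` and ``kind`` carry the grouping metadata used by the
    cross-validation folds and kind restrictions.
    """

    X: np.ndarray
    y: np.ndarray
    interviewee: np.ndarray
    kind: np.ndarray
    window_length: float | str = "session"
    column_names: list[str] | None = None

    @classmethod
    def from_vectors(cls, vectors: list[WindowVector], column_names=None) -> "WindowDataset":
        if not vectors:
            raise ValueError("no window vectors")
        labels = []
        for v in vectors:
            if v.condition not in CLASSES:
                raise ValueError(
                    f"window of interviewee {v.interviewee_id!r} has no truth/lie label"
                )
            labels.append(CLASSES.index(v.condition))
        return cls(
            X=np.array([v.values for v in vectors]),
            y=np.array(labels, dtype=int),
            interviewee=np.array([v.interviewee_id for v in vectors]),
            kind=np.array([v.session_kind for v in vectors]),
            window_length=vectors[0].window_length,
            column_names=column_names,
        )

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def interviewees(self) -> np.ndarray:
        return np.unique(self.interviewee)


# ---------------------------------------------------------------------------
# model fitting and per-feature decisions


@dataclass
class PerFeatureGaussianModel:
    """Per-class, per-feature Gaussian parameters.

    ``mu`` and ``sigma`` have shape ``(2, n_features)`` with row 0 = truth,
    row 1 = lie. ``sigma`` is the sample standard deviation (n-1), floored
    at ``1e-9`` times the pooled training sd (or ``1e-9`` absolute if that
    is zero) so the density stays defined for constant features.
    """

    mu: np.ndarray
    sigma: np.ndarray
    n_per_class: tuple[int, int]
    pooled_sd: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_features(self) -> int:
        return self.mu.shape[1]


def fit(X: np.ndarray, y: np.ndarray) -> PerFeatureGaussianModel:
    """Estimate per-class mean and sample sd for every feature.

    Requires at least 2 training samples per class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = [int((y == c).sum()) for c in (TRUTH, LIE)]
    if min(counts) < 2:
        raise ValueError(
            f"need >= 2 training samples per class, got truth={counts[0]}, lie={counts[1]}"
        )
    mu = np.stack([X[y == c].mean(axis=0) for c in (TRUTH, LIE)])
    sigma = np.stack([X[y == c].std(axis=0, ddof=1) for c in (TRUTH, LIE)])
    pooled = X.std(axis=0, ddof=1)
    floor = np.where(pooled > 0, _SIGMA_FLOOR_REL * pooled, _SIGMA_FLOOR_REL)
    sigma = np.maximum(sigma, floor)
    return PerFeatureGaussianModel(
        mu=mu, sigma=sigma, n_per_class=(counts[0], counts[1]), pooled_sd=pooled
    )


def feature_log_density(model: PerFeatureGaussianModel, X: np.ndarray) -> np.ndarray:
    """Log Gaussian density of each value under each class.

    Returns ``(2, n_samples, n_features)``; the constant ``-log sqrt(2 pi)``
    is omitted (identical across classes).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = model.mu[:, None, :]
    sigma = model.sigma[:, None, :]
    return -np.log(sigma) - (X[None, :, :] - mu) ** 2 / (2.0 * sigma**2)


def feature_votes(
    model: PerFeatureGaussianModel,
    X: np.ndarray,
    tie_break: str = "truth",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-feature class decisions, ``(n_samples, n_features)`` of 0/1.

    The class with the larger density wins; exact ties go to truth (or are
    drawn uniformly with ``tie_break="random"``).
    """
    ll = feature_log_density(model, X)
    votes = (ll[LIE] > ll[TRUTH]).astype(int)
    ties = ll[LIE] == ll[TRUTH]
    if tie_break == "random" and ties.any():
        rng = rng or np.random.default_rng()
        votes[ties] = rng.integers(0, 2, size=int(ties.sum()))
    return votes


def classify_feature(model: PerFeatureGaussianModel, i: int, x_i: float) -> str:
    """Classify one value with the single-feature Gaussian classifier."""
    ll = [
        -np.log(model.sigma[c, i]) - (x_i - model.mu[c, i]) ** 2 / (2 * model.sigma[c, i] ** 2)
        for c in (TRUTH, LIE)
    ]
    return CLASSES[LIE] if ll[LIE] > ll[TRUTH] else CLASSES[TRUTH]


# ---------------------------------------------------------------------------
# significance-based feature selection


@dataclass
class FeatureSelection:
    """Indices of features whose class distributions differ at level alpha."""

    indices: np.ndarray
    alpha: float
    p_values: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def feature_p_values(
    X: np.ndarray, y: np.ndarray, method: str = "welch"
) -> np.ndarray:
    """Two-sample p-value per feature for a truth/lie location difference.

    ``method``: ``"welch"`` (default; unequal-variance t-test),
    ``"student"`` (pooled-variance t-test) or ``"mannwhitney"``.
    Features with zero variance in both classes get p = 1 (no basis for a
    distributional difference).
    """
    import warnings

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    a, b = X[y == TRUTH], X[y == LIE]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant features trip scipy's catastrophic-cancellation
        # warning; those p-values are overridden below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "welch":
            p = _stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
        elif method == "student":
            p = _stats.ttest_ind(a, b, axis=0, equal_var=True).pvalue
        elif method == "mannwhitney":
            p = _stats.mannwhitneyu(a, b, axis=0, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown significance test {method!r}")
    p = np.asarray(p, dtype=float)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    p[degenerate | ~np.isfinite(p)] = 1.0
    return p


def select_features(
    X: np.ndarray, y: np.ndarray, alpha: float, method: str = "welch"
) -> FeatureSelection:
    """Select features with p < alpha; ``alpha >= 1`` selects all features."""
    p = feature_p_values(X, y, method=method)
    if alpha >= 1.0:
        idx = np.arange(X.shape[1])
    else:
        idx = np.flatnonzero(p < alpha)
    return FeatureSelection(indices=idx, alpha=alpha, p_values=p)


def sort_features_by_significance(selection: FeatureSelection) -> np.ndarray:
    """Selected features ordered by ascending p-value, ties in catalogue order."""
    idx = selection.indices
    order = np.lexsort((idx, selection.p_values[idx]))
    return idx[order]


def majority_vote(votes: np.ndarray, selection: np.ndarray) -> int:
    """Majority class over the selected features' votes; ties go to truth."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("majority vote over an empty feature selection")
    lie_votes = int(np.asarray(votes)[selection].sum())
    return LIE if 2 * lie_votes > selection.size else TRUTH


def majority_votes(votes: np.ndarray, selection: np.ndarray) -> np.ndarray:
    """Vectorized :func:`majority_vote` over rows of ``votes``."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("majority vote over an empty feature selection")
    lie_votes = votes[:, selection].sum(axis=1)
    return (2 * lie_votes > selection.size).astype(int)


# ---------------------------------------------------------------------------
# leave-one-interviewee-out cross-validation


@dataclass
class FoldResult:
    """Everything computed for one held-out interviewee."""

    interviewee: str
    model: PerFeatureGaussianModel
    p_values: np.ndarray
    selected: np.ndarray
    test_votes: np.ndarray  # (n_test, n_features)
    test_true: np.ndarray  # (n_test,)
    test_pred: np.ndarray  # (n_test,)
    test_X: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def accuracy(self) -> float:
        return float((self.test_pred == self.test_true).mean())


@dataclass
class LoocvResult:
    """Cross-validation outcome: mean per-fold accuracy plus fold details."""

    detection_rate: float
    folds: list[FoldResult]
    alpha: float
    train_kinds: tuple[str, ...]
    test_kinds: tuple[str, ...]

    def confusion(self) -> np.ndarray:
        """2x2 actual-by-guessed percentage matrix over all test windows."""
        cm = np.zeros((2, 2))
        for f in self.folds:
            for t, p in zip(f.test_true, f.test_pred):
                cm[t, p] += 1
        return 100.0 * cm / cm.sum()

    def mean_selection_size(self) -> float:
        return float(np.mean([len(f.selected) for f in self.folds]))


def loocv(
    dataset: WindowDataset,
    *,
    train_kinds: tuple[str, ...] = ("game", "wallet"),
    test_kinds: tuple[str, ...] = ("game", "wallet"),
    alpha: float = 1.0,
    method: str = "welch",
    top_k: int | None = None,
    feature_subset: np.ndarray | None = None,
    keep_test_X: bool = False,
) -> LoocvResult:
    """Leave-one-interviewee-out evaluation of the voting classifier.

    Per fold: fit the per-feature Gaussians and the significance test on all
    windows of the remaining interviewees (restricted to ``train_kinds``),
    then classify each held-out window (restricted to ``test_kinds``) by
    majority vote over the selected features. The detection rate is the
    mean of per-fold accuracies.

    ``top_k`` keeps only the k most significant selected features;
    ``feature_subset`` restricts voting to a fixed index set (intersected
    with the significance selection), as in the per-category breakdowns.
    """
    folds: list[FoldResult] = []
    train_kinds = tuple(train_kinds)
    test_kinds = tuple(test_kinds)
    for person in dataset.interviewees():
        test_mask = (dataset.interviewee == person) & np.isin(dataset.kind, test_kinds)
        if not test_mask.any():
            continue  # interviewee has no session of the requested kind
        train_mask = (dataset.interviewee != person) & np.isin(dataset.kind, train_kinds)
        assert not (train_mask & test_mask).any(), "leakage: window in both sets"
        X_tr, y_tr = dataset.X[train_mask], dataset.y[train_mask]
        model = fit(X_tr, y_tr)
        selection = select_features(X_tr, y_tr, alpha, method=method)
        selected = sort_features_by_significance(selection)
        if feature_subset is not None:
            keep = np.isin(selected, feature_subset)
            selected = selected[keep]
        if top_k is not None:
            selected = selected[:top_k]
        if selected.size == 0:
            raise ValueError(
                f"fold {person!r}: empty feature selection (alpha={alpha})"
            )
        X_te = dataset.X[test_mask]
        votes = feature_votes(model, X_te)
        pred = majority_votes(votes, selected)
        folds.append(
            FoldResult(
                interviewee=str(person),
                model=model,
                p_values=selection.p_values,
                selected=selected,
                test_votes=votes,
                test_true=dataset.y[test_mask],
                test_pred=pred,
                test_X=X_te if keep_test_X else None,
            )
        )
    if not folds:
        raise ValueError("no folds: no interviewee has sessions of the test kinds")
    rate = float(np.mean([f.accuracy for f in folds]))
    return LoocvResult(
        detection_rate=rate,
        folds=folds,
        alpha=alpha,
        train_kinds=train_kinds,
        test_kinds=test_kinds,
    )
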