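"""The systematic experiments: crossings, sweeps, breakdowns, noise.

Everything here is a pure function of (corpus, configuration, seed). The
shared pipeline is: resample each session to 5 Hz, center on the pelvis,
scale segments to corpus-average reference lengths, extract the 67 feature
streams, aggregate into 335-dimensional window vectors, then evaluate with
leave-one-interviewee-out cross-validation of the voting classifier.

The named significance levels follow the study's terminology: *all*
(alpha = 1, every feature votes), *stat-95* (alpha = 0.05) and *stat-99*
(alpha = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify
from .classify import LIE, TRUTH, WindowDataset, loocv
from .features import FeatureCatalogue, FeatureStreams, extract_all
from .io import MocapSession
from .normalize import (
    ReferenceLengths,
    center_on_root,
    compute_reference_lengths,
    resample,
    scale_segments,
)
from .skeleton import BODY_PARTS, Skeleton, default_skeleton
from .windows import (
    DEFAULT_WINDOW_LENGTHS,
    SESSION_WINDOW,
    WINDOW_TYPES,
    column_names,
    window_vectors,
)

ALPHA_LABELS = {"all": 1.0, "stat-95": 0.05, "stat-99": 0.01}
KIND_SETS = {"both": ("game", "wallet"), "game": ("game",), "wallet": ("wallet",)}


# ---------------------------------------------------------------------------
# pipeline: corpus -> feature streams -> window datasets


@dataclass
class SessionStreams:
    """Normalized feature streams of one session plus its labels."""

    streams: FeatureStreams
    interviewee_id: str
    session_kind: str
    condition: str


@dataclass
class CorpusFeatures:
    """Feature streams for a whole corpus, sharing one normalization."""

    sessions: list[SessionStreams]
    reference: ReferenceLengths
    catalogue: FeatureCatalogue
    skeleton: Skeleton = field(default_factory=default_skeleton, repr=False)

    def dataset(self, window_length: float | str = SESSION_WINDOW) -> WindowDataset:
        """Aggregate all sessions at one window length."""
        vectors = []
        for s in self.sessions:
            vectors += window_vectors(
                s.streams,
                window_length,
                interviewee_id=s.interviewee_id,
                session_kind=s.session_kind,
                condition=s.condition,
            )
        if not vectors:
            raise ValueError(
                f"no complete {window_length} s window fits any session; "
                "use a shorter window length"
            )
        ds = WindowDataset.from_vectors(vectors, column_names(self.catalogue))
        ds.window_length = window_length
        return ds


def extract_corpus(
    corpus: list[MocapSession],
    target_hz: float = 5.0,
    skeleton: Skeleton | None = None,
    reference: ReferenceLengths | None = None,
) -> CorpusFeatures:
    """Run the normalization and feature-extraction pipeline on a corpus.

    Reference segment lengths are a single corpus-wide average (computed on
    the resampled frames) unless supplied explicitly.
    """
    if not corpus:
        raise ValueError("empty corpus")
    sk = skeleton or default_skeleton()
    cat = FeatureCatalogue(sk)
    downsampled = [resample(s, target_hz) for s in corpus]
    if reference is None:
        reference = compute_reference_lengths(downsampled, sk)
    sessions = []
    for s in downsampled:
        rel = scale_segments(center_on_root(s.frames, sk), reference, sk)
        sessions.append(
            SessionStreams(
                streams=extract_all(rel, s.sample_rate_hz, sk, cat),
                interviewee_id=s.interviewee_id,
                session_kind=s.session_kind,
                condition=s.condition,
            )
        )
    return CorpusFeatures(sessions=sessions, reference=reference, catalogue=cat, skeleton=sk)


def build_dataset(
    corpus: list[MocapSession],
    window_length: float | str = SESSION_WINDOW,
    target_hz: float = 5.0,
    skeleton: Skeleton | None = None,
) -> WindowDataset:
    """Corpus straight to a window dataset (convenience wrapper)."""
    return extract_corpus(corpus, target_hz=target_hz, skeleton=skeleton).dataset(
        window_length
    )


# ---------------------------------------------------------------------------
# dimension-level category maps (335 columns = 67 features x 5 window types)


def dims_of_features(feature_indices) -> np.ndarray:
    """All 5 window-type columns of the given catalogue features."""
    f = np.asarray(feature_indices, dtype=int)
    return (f[:, None] * len(WINDOW_TYPES) + np.arange(len(WINDOW_TYPES))).reshape(-1)


def dims_of_window_type(window_type: str) -> np.ndarray:
    """All 67 columns of one window type (mean, minimum, ...)."""
    w = WINDOW_TYPES.index(window_type)
    return np.arange(67) * len(WINDOW_TYPES) + w


def dim_metadata(catalogue: FeatureCatalogue) -> pd.DataFrame:
    """Per-column metadata table for the 335 window features."""
    rows = []
    for d in catalogue:
        for w in WINDOW_TYPES:
            rows.append(
                {
                    "column": f"{d.feature_id}__{w}",
                    "feature_id": d.feature_id,
                    "feature_type": d.feature_type,
                    "window_type": w,
                    "body_parts": "|".join(d.body_parts_involved),
                    "n_body_parts_class": d.n_body_parts_class,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experiments


def run_crossings(
    dataset: WindowDataset,
    alphas: dict[str, float] = ALPHA_LABELS,
    method: str = "welch",
) -> pd.DataFrame:
    """Detection rates for all train x test session-kind crossings.

    One row per (train, test, alpha label); rates in percent.
    """
    rows = []
    for train_label, train_kinds in KIND_SETS.items():
        for test_label, test_kinds in KIND_SETS.items():
            for alpha_label, alpha in alphas.items():
                res = loocv(
                    dataset,
                    train_kinds=train_kinds,
                    test_kinds=test_kinds,
                    alpha=alpha,
                    method=method,
                )
                rows.append(
                    {
                        "train": train_label,
                        "test": test_label,
                        "alpha": alpha_label,
                        "rate_pct": 100.0 * res.detection_rate,
                        "mean_selected": res.mean_selection_size(),
                    }
                )
    return pd.DataFrame(rows)


def run_window_sweep(
    features: CorpusFeatures,
    lengths=DEFAULT_WINDOW_LENGTHS,
    alphas: dict[str, float] = ALPHA_LABELS,
    method: str = "welch",
) -> pd.DataFrame:
    """Window-level detection rate per (window length, alpha)."""
    rows = []
    for length in lengths:
        ds = features.dataset(length)
        for alpha_label, alpha in alphas.items():
            res = loocv(ds, alpha=alpha, method=method)
            rows.append(
                {
                    "window_length": length,
                    "alpha": alpha_label,
                    "rate_pct": 100.0 * res.detection_rate,
                    "n_windows": ds.n_windows,
                }
            )
    return pd.DataFrame(rows)


def _category_dims(catalogue: FeatureCatalogue) -> dict[str, dict[str, np.ndarray]]:
    """Dimension index sets for every breakdown category."""
    cats: dict[str, dict[str, np.ndarray]] = {
        "feature_type": {
            t: dims_of_features(catalogue.of_type(t))
            for t in ("movement", "joint_angle", "joint_distance", "symmetry")
        },
        "window_type": {w: dims_of_window_type(w) for w in WINDOW_TYPES},
        "body_part": {
            p: dims_of_features(catalogue.of_body_part(p)) for p in BODY_PARTS
        },
        "n_body_parts": {
            e: dims_of_features(catalogue.of_extent(e))
            for e in ("single", "two", "all")
        },
    }
    return cats


def run_breakdowns(
    dataset: WindowDataset,
    alpha: float = 0.05,
    method: str = "welch",
) -> pd.DataFrame:
    """Per-category selected percentage and voting rates.

    For each category (feature type, window type, body part, number of body
    parts involved): the percentage of its columns present in the stat-95
    selection (averaged over LOOCV folds trained on both session kinds) and
    the majority-vote rate using only that category's columns, tested on
    both/game/wallet sessions.
    """
    catalogue = FeatureCatalogue()
    cats = _category_dims(catalogue)
    base = loocv(dataset, alpha=alpha, method=method)
    rows = []
    for group, members in cats.items():
        for name, dims in members.items():
            sel_pct = 100.0 * float(
                np.mean([np.isin(dims, f.selected).mean() for f in base.folds])
            )
            row = {"category": group, "member": name, "selected_pct": sel_pct}
            for test_label, test_kinds in KIND_SETS.items():
                res = loocv(
                    dataset,
                    test_kinds=test_kinds,
                    alpha=alpha,
                    method=method,
                    feature_subset=dims,
                )
                row[f"rate_{test_label}_pct"] = 100.0 * res.detection_rate
            rows.append(row)
    return pd.DataFrame(rows)


def run_topk_sweep(
    dataset: WindowDataset,
    k_max: int = 200,
    method: str = "welch",
) -> pd.DataFrame:
    """Detection rate using the k most significant features, k = 1..k_max.

    Features are sorted per fold by ascending p-value of the truth/lie
    two-sample test on the training windows; the top-k vote by majority.
    """
    if k_max > dataset.X.shape[1]:
        raise ValueError(f"k_max must be <= {dataset.X.shape[1]}")
    fold_acc = []  # (n_folds, k_max)
    for person in dataset.interviewees():
        test_mask = dataset.interviewee == person
        train_mask = ~test_mask
        X_tr, y_tr = dataset.X[train_mask], dataset.y[train_mask]
        model = classify.fit(X_tr, y_tr)
        selection = classify.select_features(X_tr, y_tr, alpha=1.0, method=method)
        order = classify.sort_features_by_significance(selection)
        votes = classify.feature_votes(model, dataset.X[test_mask])
        # cumulative lie votes over features in significance order
        cum = np.cumsum(votes[:, order], axis=1)[:, :k_max]  # (n_test, k_max)
        ks = np.arange(1, k_max + 1)
        pred = (2 * cum > ks[None, :]).astype(int)
        truth = dataset.y[test_mask][:, None]
        fold_acc.append((pred == truth).mean(axis=0))
    rates = 100.0 * np.mean(fold_acc, axis=0)
    return pd.DataFrame({"k": np.arange(1, k_max + 1), "rate_pct": rates})


def run_per_feature_ranking(
    dataset: WindowDataset,
    alpha: float = 0.05,
    method: str = "welch",
) -> pd.DataFrame:
    """LOOCV rate of every window feature used alone (no voting).

    Also reports how often each feature enters the stat-95 selection.
    Sorted by descending rate, ties in canonical column order.
    """
    catalogue = FeatureCatalogue()
    acc = []
    sel_freq = np.zeros(dataset.X.shape[1])
    for person in dataset.interviewees():
        test_mask = dataset.interviewee == person
        train_mask = ~test_mask
        X_tr, y_tr = dataset.X[train_mask], dataset.y[train_mask]
        model = classify.fit(X_tr, y_tr)
        p = classify.feature_p_values(X_tr, y_tr, method=method)
        sel_freq += p < alpha
        votes = classify.feature_votes(model, dataset.X[test_mask])
        acc.append((votes == dataset.y[test_mask][:, None]).mean(axis=0))
    n_folds = len(acc)
    table = dim_metadata(catalogue)
    table["rate_pct"] = 100.0 * np.mean(acc, axis=0)
    table["selected_freq"] = sel_freq / n_folds
    table = table.sort_values(
        "rate_pct", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return table


def run_noise_experiment(
    dataset: WindowDataset,
    r_list=(0.0, 0.5, 1.0, 1.5, 2.0),
    repetitions: int = 100,
    seed: int = 0,
    alphas: dict[str, float] = ALPHA_LABELS,
    method: str = "welch",
    sd_basis: str = "pooled",
) -> pd.DataFrame:
    """Detection rate under Gaussian measurement noise on the test features.

    Per repetition, zero-mean Gaussian noise with standard deviation
    ``r`` times the per-feature training standard deviation is added to
    every test-window feature value before classification; rates are
    averaged over repetitions. ``sd_basis="pooled"`` (default) uses the
    class-agnostic training sd; ``"class"`` matches the noise scale to each
    test sample's true class.
    """
    if sd_basis not in ("pooled", "class"):
        raise ValueError("sd_basis must be 'pooled' or 'class'")
    rng = np.random.default_rng(seed)
    # one pass of fitting/selection per fold, reused across r and repetitions
    folds = []
    for person in dataset.interviewees():
        test_mask = dataset.interviewee == person
        X_tr, y_tr = dataset.X[~test_mask], dataset.y[~test_mask]
        model = classify.fit(X_tr, y_tr)
        selection = classify.select_features(X_tr, y_tr, alpha=1.0, method=method)
        order = classify.sort_features_by_significance(selection)
        selected = {
            label: order if a >= 1.0 else order[selection.p_values[order] < a]
            for label, a in alphas.items()
        }
        folds.append((model, selected, dataset.X[test_mask], dataset.y[test_mask]))

    rows = []
    for r in r_list:
        acc = {label: np.zeros(repetitions) for label in alphas}
        for model, selected, X_te, y_te in folds:
            if sd_basis == "pooled":
                scale = r * model.pooled_sd
            else:
                scale = r * model.sigma[y_te][:, :]  # per-sample true-class sd
            if r == 0:
                noisy = np.broadcast_to(X_te, (repetitions,) + X_te.shape)
            else:
                noise = rng.normal(size=(repetitions,) + X_te.shape)
                noisy = X_te[None, :, :] + noise * np.broadcast_to(scale, X_te.shape)
            flat = noisy.reshape(-1, X_te.shape[1])
            votes = classify.feature_votes(model, flat)
            for label, sel in selected.items():
                if sel.size == 0:
                    raise ValueError(f"empty {label} selection in a fold")
                pred = classify.majority_votes(votes, sel).reshape(
                    repetitions, X_te.shape[0]
                )
                acc[label] += (pred == y_te[None, :]).mean(axis=1)
        for label in alphas:
            per_rep = acc[label] / len(folds)
            rows.append(
                {
                    "r": r,
                    "alpha": label,
                    "rate_pct": 100.0 * float(per_rep.mean()),
                    "rate_sd_pct": 100.0 * float(per_rep.std(ddof=0)),
                }
            )
    return pd.DataFrame(rows)


def plot_rate_curve(table: pd.DataFrame, x: str, out_path, title: str = "") -> None:
    """Line plot of detection rate vs. a swept variable, one line per alpha."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if "alpha" in table.columns:
        for label, sub in table.groupby("alpha"):
            ax.plot(sub[x], sub["rate_pct"], marker="o", label=label)
        ax.legend()
    else:
        ax.plot(table[x], table["rate_pct"], marker="o")
    ax.set_xlabel(x)
    ax.set_ylabel("detection rate (%)")
    ax.axhline(50, color="gray", lw=0.8, ls="--")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
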