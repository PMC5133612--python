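"""One-vs-rest RBF-SVM classification of phase segments.

The routine mirrors a standard soft-margin SVM protocol: (C, gamma) are
grid-searched by 5-fold cross-validation on a small (~10%) tuning subset that
is then discarded; the remaining calls are split 80/20 (stratified), features
are range-scaled and mean-normalized on the training portion only, and an RBF
SVM is scored on the hold-out. Each attribute's score is the unweighted mean
over its one-class-versus-rest comparisons, with the pooled rest class
randomly subsampled to the target-class size so every binary task is balanced
against the 50% chance baseline.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import ATTRIBUTES, PHASES
from .features import FeatureMatrix
from .segments import FeatureScaler, extract_segment, segment_matrix

logger = logging.getLogger(__name__)

MIN_CLASS_SIZE = 5  # below this a stratified 80/20 split is impossible


@dataclass(frozen=True)
class SvmConfig:
    """Hyperparameter search space and split fractions."""

    C_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16, 2))      # 11 values
    gamma_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-15, 4, 2))  # 10 values
    cv_folds: int = 5
    tuning_fraction: float = 0.10
    train_fraction: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.tuning_fraction < 1 or not 0 < self.train_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")


@dataclass
class ClassificationResult:
    """Percent-correct score for one (attribute, phase, window[, onset]) cell."""

    attribute: str
    phase: str
    window_ms: int
    percent_correct: float
    per_comparison_scores: list[float]
    n_train: int
    n_test: int
    seed: int
    onset_ms: float | None = None
    C: float = field(default=np.nan)
    gamma: float = field(default=np.nan)


def labels_for(meta: pd.DataFrame, attribute: str) -> np.ndarray:
    """Class labels of each clip row under one of the four label schemes."""
    col = {
        "identity": "caller_id",
        "age": "age_class",
        "social_status": "rank_class",
        "context": "context",
    }.get(attribute)
    if col is None:
        raise ValueError(f"unknown attribute {attribute!r}")
    return meta[col].to_numpy()


def derive_rng(master_seed: int, *tokens) -> np.random.Generator:
    """Independent but reproducible per-cell stream: CRC32-hashed spawn key."""
    key = tuple(zlib.crc32(str(t).encode()) for t in tokens)
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def derive_int_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def fit_predict(Xtr, ytr, Xte, C: float, gamma: float) -> np.ndarray:
    """Scale on train only, fit the RBF SVM, predict the test labels."""
    scaler = FeatureScaler.fit(np.asarray(Xtr, dtype=float))
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(scaler.transform(Xtr), ytr)
    return clf.predict(scaler.transform(Xte))


def _fit_score(Xtr, ytr, Xte, yte, C: float, gamma: float) -> float:
    return float(np.mean(fit_predict(Xtr, ytr, Xte, C, gamma) == yte))


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    config: SvmConfig | None = None,
    seed: int = 0,
    return_history: bool = False,
):
    """Exhaustive (C, gamma) grid search by k-fold CV on the tuning subset.

    Ties are broken toward smaller C, then smaller gamma. The fold count
    degrades from 5 to the smallest class count when the subset is tiny.
    """
    config = config or SvmConfig()
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("tuning subset must contain at least two classes")
    # singleton classes cannot appear on both sides of any CV split
    if counts.min() < 2:
        keep = np.isin(y, classes[counts >= 2])
        X, y = X[keep], y[keep]
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("tuning subset too small to cross-validate")
    n_folds = int(min(config.cv_folds, counts.min()))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))

    best = None
    history = []
    for C in config.C_grid:
        for gamma in config.gamma_grid:
            accs = [
                _fit_score(X[tr], y[tr], X[te], y[te], C, gamma) for tr, te in splits
            ]
            score = float(np.mean(accs))
            history.append((C, gamma, score))
            key = (-score, C, gamma)
            if best is None or key < best[0]:
                best = (key, C, gamma)
    _, C, gamma = best
    if return_history:
        return C, gamma, pd.DataFrame(history, columns=["C", "gamma", "cv_accuracy"])
    return C, gamma


def run_binary_comparison(
    X: np.ndarray,
    y_binary: np.ndarray,
    C: float,
    gamma: float,
    train_fraction: float = 0.80,
    seed: int = 0,
    balance: bool = True,
) -> float:
    """Balanced, stratified 80/20 hold-out score (percent correct).

    A single random permutation of the rows drives both the majority-class
    subsampling and the per-class test draw, so (a) train and hold-out are
    each exactly balanced — a no-signal classifier scores 50% in expectation,
    the stated chance baseline — and (b) flipping the labels selects the
    identical rows and returns the identical score.
    """
    y_bin = np.asarray(y_binary).astype(bool)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(y_bin.size)
    idx_pos = perm[y_bin[perm]]
    idx_neg = perm[~y_bin[perm]]
    if balance:
        m = min(idx_pos.size, idx_neg.size)
        idx_pos, idx_neg = idx_pos[:m], idx_neg[:m]
    if min(idx_pos.size, idx_neg.size) < MIN_CLASS_SIZE:
        raise ValueError(
            f"class with {min(idx_pos.size, idx_neg.size)} members cannot "
            f"support a stratified {train_fraction:.0%}/"
            f"{1 - train_fraction:.0%} split"
        )
    test_parts, train_parts = [], []
    for idx in (idx_pos, idx_neg):
        n_test = max(1, int(round((1.0 - train_fraction) * idx.size)))
        test_parts.append(idx[:n_test])
        train_parts.append(idx[n_test:])
    test_idx = np.concatenate(test_parts)
    train_idx = np.concatenate(train_parts)
    return 100.0 * _fit_score(
        X[train_idx], y_bin[train_idx], X[test_idx], y_bin[test_idx], C, gamma
    )


def one_vs_rest_average(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    config: SvmConfig | None = None,
    seed: int = 0,
    attribute: str = "",
    phase: str = "",
    window_ms: int = 0,
    onset_ms: float | None = None,
) -> ClassificationResult:
    """Mean percent correct over all one-class-versus-rest comparisons."""
    config = config or SvmConfig()
    y = np.asarray(y)
    # one split seed shared by all comparisons: for 2-class attributes the two
    # complementary comparisons then select identical rows and score equally
    split_seed = derive_int_seed(np.random.default_rng(seed))
    scores = []
    for cls in np.unique(y):
        scores.append(
            run_binary_comparison(
                X, y == cls, C, gamma,
                train_fraction=config.train_fraction,
                seed=split_seed,
            )
        )
    n = y.size
    n_test = int(round(n * (1.0 - config.train_fraction)))
    return ClassificationResult(
        attribute=attribute,
        phase=phase,
        window_ms=window_ms,
        onset_ms=onset_ms,
        percent_correct=float(np.mean(scores)),
        per_comparison_scores=[float(s) for s in scores],
        n_train=n - n_test,
        n_test=n_test,
        seed=seed,
        C=C,
        gamma=gamma,
    )


def split_tuning_subset(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the tuning subset and of the disjoint remainder.

    The subset holds ~``fraction`` of the clips with at least two members of
    at least two classes, so the CV grid search always has something to
    cross-validate: each class (in random order) first receives two slots
    while the budget lasts, then the remaining budget is dealt round-robin.
    """
    y = np.asarray(y)
    n = y.size
    n_tune = max(int(round(fraction * n)), 4)
    classes = np.unique(y)
    members = {
        c: rng.permutation(np.flatnonzero(y == c)) for c in classes
    }
    counts = {c: members[c].size for c in classes}
    if sum(counts[c] >= 2 for c in classes) < 2:
        raise ValueError("need two classes with two members each to tune on")
    order = list(rng.permutation(classes))
    quotas = dict.fromkeys(classes, 0)
    budget = n_tune
    for c in order:  # two per class: the minimum a CV fold pair needs
        if budget >= 2 and counts[c] >= 2:
            quotas[c] = 2
            budget -= 2
    while budget > 0:  # spread the rest, roughly proportionally
        progressed = False
        for c in order:
            if budget > 0 and quotas[c] < counts[c]:
                quotas[c] += 1
                budget -= 1
                progressed = True
        if not progressed:
            break
    tune_idx = np.concatenate([members[c][: quotas[c]] for c in classes])
    rest_idx = np.setdiff1d(np.arange(n), tune_idx)
    assert np.intersect1d(tune_idx, rest_idx).size == 0  # anti-leakage guard
    return np.sort(tune_idx), np.sort(rest_idx)


def _segments_for(
    features: dict[str, FeatureMatrix],
    clip_ids: list[str],
    window_ms: int,
    rng: np.random.Generator | None = None,
    onset_ms: float | None = None,
) -> np.ndarray:
    mode = "random" if onset_ms is None else "fixed"
    segs = [
        extract_segment(features[cid], window_ms, mode=mode, onset_ms=onset_ms, rng=rng)
        for cid in clip_ids
    ]
    return segment_matrix(segs)


def tune_cell(
    features: dict[str, FeatureMatrix],
    meta: pd.DataFrame,
    attribute: str,
    phase: str,
    windows: tuple[int, ...],
    config: SvmConfig,
    master_seed: int,
) -> tuple[float, float, pd.DataFrame]:
    """Tune (C, gamma) for one (attribute, phase) on a ~10% clip subset.

    Returns the tuned pair and the remaining (non-tuning) metadata rows. The
    tuning segments use the median window length of the sweep.
    """
    sub = meta[meta["phase"] == phase].reset_index(drop=True)
    y = labels_for(sub, attribute)
    rng = derive_rng(master_seed, "tune", attribute, phase)
    tune_idx, rest_idx = split_tuning_subset(y, config.tuning_fraction, rng)
    tune_window = int(sorted(windows)[len(windows) // 2])
    X_tune = _segments_for(
        features, list(sub.loc[tune_idx, "clip_id"]), tune_window, rng=rng
    )
    C, gamma = tune_hyperparameters(
        X_tune, y[tune_idx], config, seed=derive_int_seed(rng)
    )
    logger.debug("tuned %s/%s: C=%g gamma=%g", attribute, phase, C, gamma)
    return C, gamma, sub.loc[rest_idx].reset_index(drop=True)


def classify_grid(
    features: dict[str, FeatureMatrix],
    meta: pd.DataFrame,
    attributes: tuple[str, ...] = ATTRIBUTES,
    phases: tuple[str, ...] = PHASES,
    windows: tuple[int, ...] = (),
    config: SvmConfig | None = None,
    repeats: int = 10,
    master_seed: int = 0,
    onset_ms: float | None = None,
) -> list[ClassificationResult]:
    """Sweep attributes x phases x window lengths, averaging over repeats.

    One segment per call per repeat; hyperparameters are tuned once per
    (attribute, phase) and reused across windows. Cells whose label scheme
    cannot be stratified (too few clips in a class) are recorded as missing
    (NaN score), never fabricated.
    """
    from .segments import STANDARD_WINDOWS_MS

    config = config or SvmConfig()
    windows = tuple(windows) or STANDARD_WINDOWS_MS
    results: list[ClassificationResult] = []
    for attribute in attributes:
        for phase in phases:
            try:
                C, gamma, rest = tune_cell(
                    features, meta, attribute, phase, windows, config, master_seed
                )
            except ValueError as err:
                logger.warning("cell %s/%s missing: %s", attribute, phase, err)
                for w in windows:
                    results.append(
                        ClassificationResult(
                            attribute, phase, w, np.nan, [], 0, 0,
                            master_seed, onset_ms,
                        )
                    )
                continue
            y_rest = labels_for(rest, attribute)
            clip_ids = list(rest["clip_id"])
            for w in windows:
                rep_results = []
                for rep in range(repeats):
                    rng = derive_rng(master_seed, attribute, phase, w, rep)
                    X = _segments_for(features, clip_ids, w, rng=rng, onset_ms=onset_ms)
                    try:
                        rep_results.append(
                            one_vs_rest_average(
                                X, y_rest, C, gamma, config,
                                seed=derive_int_seed(rng),
                                attribute=attribute, phase=phase,
                                window_ms=w, onset_ms=onset_ms,
                            )
                        )
                    except ValueError as err:
                        logger.warning(
                            "cell %s/%s w=%d rep=%d missing: %s",
                            attribute, phase, w, rep, err,
                        )
                if rep_results:
                    all_scores = [s for r in rep_results for s in r.per_comparison_scores]
                    results.append(
                        ClassificationResult(
                            attribute=attribute, phase=phase, window_ms=w,
                            onset_ms=onset_ms,
                            percent_correct=float(np.mean(all_scores)),
                            per_comparison_scores=all_scores,
                            n_train=rep_results[0].n_train,
                            n_test=rep_results[0].n_test,
                            seed=master_seed, C=C, gamma=gamma,
                        )
                    )
                else:
                    results.append(
                        ClassificationResult(
                            attribute, phase, w, np.nan, [], 0, 0,
                            master_seed, onset_ms, C, gamma,
                        )
                    )
    return results


def results_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    """Long-format table of cell scores for the indices / temporal stages."""
    return pd.DataFrame(
        [{
            "attribute": r.attribute,
            "phase": r.phase,
            "window_ms": r.window_ms,
            "onset_ms": r.onset_ms,
            "percent_correct": r.percent_correct,
            "n_train": r.n_train,
            "n_test": r.n_test,
            "C": r.C,
            "gamma": r.gamma,
            "seed": r.seed,
        }
        for r in results]
    )
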