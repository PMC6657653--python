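"""Sparse logistic decoders for state reactivation.

One L1-regularized binomial classifier per state, trained on a single
post-onset time slice of labeled epochs.  Negatives are other-state
trials plus pattern-free ("null") segments, so that all classifiers can
report low probabilities simultaneously on resting data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .simulate import EpochSet, SensorRecording

DEFAULT_TRAIN_TIME_MS = 200.0
DEFAULT_L1_PENALTY = 0.02


@dataclass
class DecoderSet:
    """Per-state slope vectors and intercepts."""

    weights: np.ndarray  # n_states x n_channels
    intercepts: np.ndarray  # n_states
    train_time_ms: float
    l1_penalty: float

    @property
    def n_states(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]


@dataclass
class ReactivationMatrix:
    """Decoded reactivation probabilities, samples x states.

    Rows are independent per-timepoint binomial predictions and need not
    sum to one.
    """

    values: np.ndarray
    rate: float

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_states(self) -> int:
        return self.values.shape[1]


@dataclass
class AccuracyCurve:
    times: np.ndarray
    accuracy: np.ndarray
    chance: float


def _fit_one(X: np.ndarray, y: np.ndarray, l1_penalty: float) -> tuple[np.ndarray, float]:
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / l1_penalty, solver="liblinear", max_iter=2000,
        random_state=0,
    )
    clf.fit(X, y)
    return clf.coef_[0], float(clf.intercept_[0])


def _as_null_rows(null_segments) -> np.ndarray | None:
    if null_segments is None:
        return None
    if isinstance(null_segments, SensorRecording):
        return null_segments.data.T
    arr = np.asarray(null_segments)
    if arr.ndim != 2:
        raise ValueError("null segments must be 2-D (examples x channels)")
    return arr


def train_decoders(
    ep: EpochSet,
    null_segments=None,
    train_time_ms: float = DEFAULT_TRAIN_TIME_MS,
    l1_penalty: float = DEFAULT_L1_PENALTY,
    *,
    null_ratio: float = 1.0,
    seed: int = 0,
) -> DecoderSet:
    """Train one binomial lasso-logistic decoder per state.

    Positives for decoder *k* are trials labelled *k* at the
    ``train_time_ms`` slice; negatives are all other trials plus null
    segments subsampled to ``null_ratio`` times the positive count.
    """
    states = np.unique(ep.labels)
    if len(states) < 2:
        raise ValueError("need at least 2 states to train decoders")
    X = ep.trials[:, :, ep.time_index(train_time_ms)]
    nulls = _as_null_rows(null_segments)
    rng = np.random.default_rng(seed)
    n_states = int(states.max()) + 1
    weights = np.zeros((n_states, ep.n_channels))
    intercepts = np.zeros(n_states)
    for k in range(n_states):
        pos = X[ep.labels == k]
        if len(pos) == 0:
            raise ValueError(f"state {k} has no positive examples")
        neg = [X[ep.labels != k]]
        if nulls is not None and null_ratio > 0:
            n_null = min(len(nulls), int(round(null_ratio * len(pos))))
            neg.append(nulls[rng.choice(len(nulls), n_null, replace=False)])
        Xk = np.vstack([pos] + neg)
        yk = np.r_[np.ones(len(pos)), np.zeros(len(Xk) - len(pos))]
        weights[k], intercepts[k] = _fit_one(Xk, yk, l1_penalty)
    return DecoderSet(weights, intercepts, train_time_ms, l1_penalty)


def apply_decoders(d: DecoderSet, rec: SensorRecording) -> ReactivationMatrix:
    """Per-timepoint logistic probabilities of every state."""
    if rec.n_channels != d.n_channels:
        raise ValueError(
            f"channel mismatch: decoders have {d.n_channels}, data has {rec.n_channels}"
        )
    logits = rec.data.T @ d.weights.T + d.intercepts
    probs = 1.0 / (1.0 + np.exp(-logits))
    return ReactivationMatrix(values=probs, rate=rec.rate)


def _predict_argmax(weights, intercepts, X) -> np.ndarray:
    return np.argmax(X @ weights.T + intercepts, axis=1)


def cross_validate(
    ep: EpochSet,
    scheme: str = "leave_one_trial",
    times: np.ndarray | None = None,
    l1_penalty: float = DEFAULT_L1_PENALTY,
    *,
    stimulus_ids: np.ndarray | None = None,
) -> AccuracyCurve:
    """Cross-validated argmax decoding accuracy over a time grid.

    ``leave_one_trial`` leaves out single trials; ``leave_one_stimulus``
    leaves out all trials of one stimulus at a time (requires
    ``stimulus_ids`` and >= 2 stimuli per class), so a classifier keyed
    to sensory features of individual stimuli scores below chance.
    """
    if times is None:
        times = ep.times
    times = np.atleast_1d(np.asarray(times, dtype=float))
    states = np.unique(ep.labels)
    n_states = int(states.max()) + 1

    if scheme == "leave_one_trial":
        folds = [(np.delete(np.arange(ep.n_trials), i), np.array([i]))
                 for i in range(ep.n_trials)]
    elif scheme == "leave_one_stimulus":
        if stimulus_ids is None:
            raise ValueError("leave_one_stimulus requires stimulus_ids")
        stimulus_ids = np.asarray(stimulus_ids)
        for k in states:
            if len(np.unique(stimulus_ids[ep.labels == k])) < 2:
                raise ValueError(
                    "leave_one_stimulus needs >= 2 stimuli per class"
                )
        folds = []
        for stim in np.unique(stimulus_ids):
            test = np.flatnonzero(stimulus_ids == stim)
            folds.append((np.flatnonzero(stimulus_ids != stim), test))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    accuracy = np.zeros(len(times))
    for ti, t in enumerate(times):
        X = ep.trials[:, :, ep.time_index(t)]
        correct = 0
        for train, test in folds:
            w = np.zeros((n_states, ep.n_channels))
            b = np.zeros(n_states)
            for k in range(n_states):
                yk = (ep.labels[train] == k).astype(float)
                if yk.sum() == 0:
                    b[k] = -np.inf
                    continue
                w[k], b[k] = _fit_one(X[train], yk, l1_penalty)
            pred = _predict_argmax(w, b, X[test])
            correct += int((pred == ep.labels[test]).sum())
        accuracy[ti] = correct / ep.n_trials
    return AccuracyCurve(times=times, accuracy=accuracy, chance=1.0 / len(states))


def decoder_spatial_correlation(d: DecoderSet) -> np.ndarray:
    """Pearson correlation between decoder weight vectors."""
    if d.n_states < 2:
        raise ValueError("need at least 2 decoders")
    return np.corrcoef(d.weights)


def sensor_contribution(
    ep: EpochSet,
    n_iter: int = 2000,
    subset_size: int = 50,
    seed: int = 0,
    *,
    train_time_ms: float = DEFAULT_TRAIN_TIME_MS,
    l1_penalty: float = DEFAULT_L1_PENALTY,
    cv_folds: int = 5,
) -> np.ndarray:
    """Per-channel mean CV accuracy over random channel subsets.

    Channels never sampled get NaN.  For speed the inner loop uses
    stratified ``cv_folds``-fold CV at the training slice rather than
    full leave-one-out.
    """
    if subset_size > ep.n_channels:
        raise ValueError("subset_size exceeds channel count")
    rng = np.random.default_rng(seed)
    X = ep.trials[:, :, ep.time_index(train_time_ms)]
    states = np.unique(ep.labels)
    n_states = int(states.max()) + 1
    sums = np.zeros(ep.n_channels)
    counts = np.zeros(ep.n_channels)
    order = rng.permutation(ep.n_trials)
    fold_of = np.empty(ep.n_trials, dtype=int)
    fold_of[order] = np.arange(ep.n_trials) % cv_folds
    for _ in range(n_iter):
        chans = rng.choice(ep.n_channels, subset_size, replace=False)
        Xs = X[:, chans]
        correct = 0
        for f in range(cv_folds):
            train = fold_of != f
            w = np.zeros((n_states, subset_size))
            b = np.zeros(n_states)
            for k in range(n_states):
                yk = (ep.labels[train] == k).astype(float)
                if yk.sum() == 0 or yk.sum() == yk.size:
                    b[k] = -np.inf
                    continue
                w[k], b[k] = _fit_one(Xs[train], yk, l1_penalty)
            pred = _predict_argmax(w, b, Xs[~train])
            correct += int((pred == ep.labels[~train]).sum())
        acc = correct / ep.n_trials
        sums[chans] += acc
        counts[chans] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def residualize_factor_decoders(
    factor: DecoderSet, stim: DecoderSet, groups: dict[int, set[int]]
) -> DecoderSet:
    """Regress stimulus weight maps out of each factor decoder's weights.

    ``groups`` maps each factor class (row of ``factor.weights``) to the
    stimulus states composing it; the factor weight vector is replaced
    by its least-squares residual after projection onto those stimulus
    weight vectors (plus an intercept column).
    """
    if factor.n_channels != stim.n_channels:
        raise ValueError("channel spaces do not match")
    out = factor.weights.copy()
    for cls, members in groups.items():
        reg = np.column_stack(
            [stim.weights[m] for m in sorted(members)] + [np.ones(stim.n_channels)]
        )
        coef, *_ = np.linalg.lstsq(reg, factor.weights[cls], rcond=None)
        out[cls] = factor.weights[cls] - reg @ coef
    return DecoderSet(out, factor.intercepts.copy(), factor.train_time_ms,
                      factor.l1_penalty)


def residualize_probabilities(
    factor_y: ReactivationMatrix, stim_y: ReactivationMatrix,
    groups: dict[int, set[int]],
) -> ReactivationMatrix:
    """Alternative residualization acting on decoded time series."""
    out = factor_y.values.copy()
    for cls, members in groups.items():
        reg = np.column_stack(
            [stim_y.values[:, m] for m in sorted(members)]
            + [np.ones(stim_y.n_samples)]
        )
        coef, *_ = np.linalg.lstsq(reg, factor_y.values[:, cls], rcond=None)
        out[:, cls] = factor_y.values[:, cls] - reg @ coef
    return ReactivationMatrix(values=out, rate=factor_y.rate)
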