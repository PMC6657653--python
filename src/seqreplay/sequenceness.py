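"""Time-lagged regression measure of sequential reactivation.

For each candidate state-to-state lag dt, every state's reactivation
time series is regressed on lagged copies of all state time series
(plus nuisance copies at dt+100 ... dt+600 ms to absorb a 10 Hz
oscillation, plus a constant).  The resulting coefficient matrix
beta(dt) is an empirical transition matrix; projecting it onto a
hypothesized transition matrix P (Frobenius inner product) gives the
forward evidence Zf, onto P-transpose the backward evidence Zb, and
sequenceness is Zf - Zb.  Significance is assessed with a max-over-lags
permutation of the state labels (equivalently of P's rows and columns).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .decoding import ReactivationMatrix

DEFAULT_NUISANCE_MS = (100.0, 200.0, 300.0, 400.0, 500.0, 600.0)
DEFAULT_MAX_LAG_MS = 600.0


@dataclass
class LagGrid:
    """Ascending positive lags in ms, multiples of the sample period."""

    lags_ms: np.ndarray

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        if (self.lags_ms <= 0).any() or (np.diff(self.lags_ms) <= 0).any():
            raise ValueError("lags must be positive and strictly increasing")

    @classmethod
    def default(cls, rate: float, max_lag_ms: float = DEFAULT_MAX_LAG_MS) -> "LagGrid":
        step = 1000.0 / rate
        return cls(np.arange(step, max_lag_ms + step / 2, step))

    def samples(self, rate: float) -> np.ndarray:
        lags = self.lags_ms * rate / 1000.0
        rounded = np.round(lags)
        if np.abs(lags - rounded).max() > 1e-6:
            raise ValueError("lags must be multiples of the sample period")
        return rounded.astype(int)


@dataclass
class TransitionEstimate:
    """Empirical transition matrix beta(dt).

    Entry (i, j) is the influence of state i at t-dt on state j at t,
    i.e. evidence for the transition i -> j, oriented like the
    hypothesis matrices (so the Frobenius projection onto P measures the
    forward direction).
    """

    beta: np.ndarray
    lag_ms: float


@dataclass
class SequencenessCurve:
    lags_ms: np.ndarray
    zf: np.ndarray
    zb: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.zf - self.zb

    def peak_lag_ms(self, *, signed: str = "forward") -> float:
        """Lag of the extreme of ``diff`` (ties -> smallest lag).

        ``signed='forward'`` takes the argmax, ``'reverse'`` the argmin,
        ``'abs'`` the largest magnitude.
        """
        d = self.diff
        if signed == "forward":
            idx = int(np.argmax(d))
        elif signed == "reverse":
            idx = int(np.argmin(d))
        elif signed == "abs":
            idx = int(np.argmax(np.abs(d)))
        else:
            raise ValueError(f"unknown signed mode {signed!r}")
        return float(self.lags_ms[idx])


@dataclass
class NullDistribution:
    permutations: list[tuple[int, ...]]
    null_peaks: np.ndarray
    threshold: float = field(init=False)
    quantile: float = 1.0

    def __post_init__(self) -> None:
        self.threshold = float(np.quantile(self.null_peaks, self.quantile))


def _lagged(Y: np.ndarray, lag: int, rows: np.ndarray) -> np.ndarray:
    return Y[rows - lag]


def empirical_transitions(
    Y: ReactivationMatrix,
    lag_ms: float,
    nuisance_lags_ms: tuple[float, ...] | None = DEFAULT_NUISANCE_MS,
) -> TransitionEstimate:
    """OLS estimate of the lag-``lag_ms`` empirical transition matrix.

    Nuisance lags are offsets *added* to ``lag_ms``; lagged copies of
    all states at those offsets plus a constant enter the design.  Rows
    whose lagged values would fall before the start of the data are
    dropped listwise.  Only the coefficients at ``lag_ms`` are returned.
    """
    vals = Y.values
    n, s = vals.shape
    grid = LagGrid(np.array([lag_ms]))
    lag = int(grid.samples(Y.rate)[0])
    nuis = []
    if nuisance_lags_ms:
        nuis = [
            int(LagGrid(np.array([lag_ms + off])).samples(Y.rate)[0])
            for off in nuisance_lags_ms
        ]
    max_lag = max([lag] + nuis)
    if n <= max_lag + 1:
        raise ValueError("data too short for the requested lags")
    rows = np.arange(max_lag, n)
    cols = [_lagged(vals, lag, rows)]
    cols += [_lagged(vals, nl, rows) for nl in nuis]
    cols.append(np.ones((len(rows), 1)))
    X = np.hstack(cols)
    coef, _, rank, _ = np.linalg.lstsq(X, vals[rows], rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design at lag {lag_ms} ms: rank {rank} < {X.shape[1]} columns"
        )
    # coef is (n_predictors x s targets); the dt block is already oriented
    # predictor-state x target-state, i.e. beta[i, j] = evidence i -> j
    beta = coef[:s]
    return TransitionEstimate(beta=beta, lag_ms=lag_ms)


def project_sequenceness(b: TransitionEstimate, P: np.ndarray) -> tuple[float, float]:
    """Frobenius projections of beta onto P (forward) and P.T (backward)."""
    P = np.asarray(P, dtype=float)
    if P.shape != b.beta.shape:
        raise ValueError(f"shape mismatch: beta {b.beta.shape} vs P {P.shape}")
    zf = float(np.sum(b.beta * P))
    zb = float(np.sum(b.beta * P.T))
    return zf, zb


def sequenceness_curve(
    Y: ReactivationMatrix,
    P: np.ndarray,
    grid: LagGrid | None = None,
    nuisance_lags_ms: tuple[float, ...] | None = DEFAULT_NUISANCE_MS,
) -> SequencenessCurve:
    """Forward/backward sequenceness for every lag of the grid."""
    if grid is None:
        grid = LagGrid.default(Y.rate)
    zf = np.empty(len(grid.lags_ms))
    zb = np.empty(len(grid.lags_ms))
    for k, lag_ms in enumerate(grid.lags_ms):
        b = empirical_transitions(Y, lag_ms, nuisance_lags_ms)
        zf[k], zb[k] = project_sequenceness(b, P)
    return SequencenessCurve(lags_ms=grid.lags_ms.copy(), zf=zf, zb=zb)


def _resolve_permutations(
    s: int, perms, seed: int, exhaustive_limit: int = 5
) -> list[tuple[int, ...]]:
    identity = tuple(range(s))
    if perms is None:
        perms = "auto"
    if isinstance(perms, str) and perms == "auto":
        perms = 1000 if s > exhaustive_limit else math.factorial(s) - 1
    if isinstance(perms, int):
        total = math.factorial(s) - 1  # identity excluded
        if perms > total:
            raise ValueError(
                f"requested {perms} permutations but only {total} non-identity "
                f"permutations of {s} labels exist"
            )
        if s <= exhaustive_limit or perms == total:
            pool = [p for p in itertools.permutations(range(s)) if p != identity]
            if perms == len(pool):
                return pool
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(pool), perms, replace=False)
            return [pool[i] for i in idx]
        rng = np.random.default_rng(seed)
        seen: set[tuple[int, ...]] = set()
        while len(seen) < perms:
            p = tuple(int(x) for x in rng.permutation(s))
            if p != identity:
                seen.add(p)
        return sorted(seen)
    out = [tuple(int(x) for x in p) for p in perms]
    if not out or all(p == identity for p in out):
        raise ValueError("permutation set must contain non-identity permutations")
    return [p for p in out if p != identity]


def permute_matrix(P: np.ndarray, perm: tuple[int, ...]) -> np.ndarray:
    """Relabel states: row/column i of the result is state perm[i] of P."""
    idx = np.asarray(perm)
    return P[np.ix_(idx, idx)]


def permutation_null(
    Y: ReactivationMatrix,
    P: np.ndarray,
    grid: LagGrid | None = None,
    perms="auto",
    seed: int = 0,
    nuisance_lags_ms: tuple[float, ...] | None = DEFAULT_NUISANCE_MS,
    quantile: float = 1.0,
    betas: list[TransitionEstimate] | None = None,
) -> NullDistribution:
    """Max-over-lags permutation null for the sequenceness curve.

    Permuting the stimulus labels is equivalent to permuting rows and
    columns of P together, so the per-lag beta matrices are computed
    once and re-projected under each permuted matrix.  Each
    permutation's statistic is the max over lags of \\|zf - zb\\|; the
    threshold is the ``quantile`` (default: maximum) of those peaks.
    """
    if grid is None:
        grid = LagGrid.default(Y.rate)
    if betas is None:
        betas = [empirical_transitions(Y, lag, nuisance_lags_ms) for lag in grid.lags_ms]
    perm_list = _resolve_permutations(P.shape[0], perms, seed)
    peaks = np.empty(len(perm_list))
    for i, perm in enumerate(perm_list):
        Pp = permute_matrix(P, perm)
        diffs = [
            (lambda z: z[0] - z[1])(project_sequenceness(b, Pp)) for b in betas
        ]
        peaks[i] = np.max(np.abs(diffs))
    return NullDistribution(permutations=perm_list, null_peaks=peaks, quantile=quantile)


def lengthn_sequenceness(
    Y: ReactivationMatrix,
    paths: list[list[int]],
    grid: LagGrid | None = None,
    n: int = 3,
    nuisance_lags_ms: tuple[float, ...] | None = None,
) -> SequencenessCurve:
    """Extra evidence for length-``n`` sequences beyond shorter lengths.

    For each length-``n`` subpath (a_0, ..., a_{n-1}) of the given
    chains and each lag dt, the terminal state's series is regressed on
    the origin state lagged by (n-1) dt while controlling for every
    intermediate state at its own multiple of dt (these shorter-length
    regressors absorb pairwise evidence).  The origin coefficient,
    averaged over subpaths, is the forward evidence; the reverse variant
    runs every subpath backwards.  Returned as a curve with
    ``diff = forward - reverse``.
    """
    if n < 3:
        raise ValueError("length-n analysis requires n >= 3")
    for path in paths:
        if len(path) < n:
            raise ValueError(f"path {path} shorter than n={n}")
    if grid is None:
        grid = LagGrid.default(Y.rate, DEFAULT_MAX_LAG_MS / (n - 1))
    vals = Y.values
    N = vals.shape[0]
    lags = grid.samples(Y.rate)
    subpaths = [
        path[k : k + n] for path in paths for k in range(len(path) - n + 1)
    ]

    def _evidence(sub: list[int], lag: int) -> float:
        max_lag = (n - 1) * lag
        nuis = []
        if nuisance_lags_ms:
            gridded = LagGrid(np.asarray(nuisance_lags_ms) + 0.0)
            nuis = list(gridded.samples(Y.rate) + max_lag)
            max_lag_all = max([max_lag] + nuis)
        else:
            max_lag_all = max_lag
        if N <= max_lag_all + 1:
            raise ValueError("data too short for the requested length-n lags")
        rows = np.arange(max_lag_all, N)
        target = vals[rows, sub[-1]]
        cols = [vals[rows - max_lag, sub[0]]]
        for step, state in enumerate(sub[1:-1], start=1):
            cols.append(vals[rows - (n - 1 - step) * lag, state])
        for nl in nuis:
            cols.append(vals[rows - nl, sub[0]])
        cols.append(np.ones(len(rows)))
        X = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(X, target, rcond=None)
        return float(coef[0])

    zf = np.empty(len(lags))
    zb = np.empty(len(lags))
    for k, lag in enumerate(lags):
        zf[k] = float(np.mean([_evidence(sub, lag) for sub in subpaths]))
        zb[k] = float(np.mean([_evidence(sub[::-1], lag) for sub in subpaths]))
    return SequencenessCurve(lags_ms=grid.lags_ms.copy(), zf=zf, zb=zb)
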