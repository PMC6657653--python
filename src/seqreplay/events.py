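"""Replay event detection, event-locked spectra, and cross-code lags."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from .decoding import ReactivationMatrix
from .sequenceness import (
    LagGrid,
    NullDistribution,
    SequencenessCurve,
    _resolve_permutations,
)
from .simulate import SensorRecording


@dataclass
class StrengthSeries:
    """Momentary replay strength R(t) for one transition matrix and lag."""

    r: np.ndarray
    lag_ms: float
    direction_matrix: np.ndarray
    rate: float


@dataclass
class EventList:
    onsets: np.ndarray  # sample indices
    threshold_value: float
    refractory_ms: float
    rate: float

    @property
    def onsets_ms(self) -> np.ndarray:
        return self.onsets * 1000.0 / self.rate


@dataclass
class TFContrast:
    """Baseline-corrected event-locked power, freqs x times."""

    freqs: np.ndarray
    times_ms: np.ndarray
    power_change: np.ndarray
    n_events: int


@dataclass
class ClusterResult:
    mask: np.ndarray  # boolean map of the cluster's cells
    stat: float  # summed t within the cluster
    p_value: float


def replay_strength(
    Y: ReactivationMatrix, P: np.ndarray, lag_ms: float
) -> StrengthSeries:
    """R(t) = sum_i (Y P)(t, i) * Y(t + lag, i).

    (Y P)(t, i) is the expected activation of state i's predecessors'
    successor — large when some predecessor of i is active at t — and is
    matched against i's actual activation one lag later.  The tail that
    has no lagged partner is zero-padded so ``len(r) == N``.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (Y.n_states, Y.n_states):
        raise ValueError("transition matrix shape does not match Y")
    lag = int(LagGrid(np.array([lag_ms])).samples(Y.rate)[0])
    orig = Y.values @ P
    proj = np.zeros_like(Y.values)
    proj[:-lag] = Y.values[lag:]
    r = np.sum(orig * proj, axis=1)
    return StrengthSeries(r=r, lag_ms=lag_ms, direction_matrix=P, rate=Y.rate)


def detect_onsets(
    ss: StrengthSeries, percentile: float = 95.0, refractory_ms: float = 100.0
) -> EventList:
    """Suprathreshold samples with a replay-free preceding window.

    The threshold is the given percentile of R; a sample qualifies only
    if no sample in the preceding ``refractory_ms`` strictly exceeds the
    threshold (i.e. 100 ms of replay-free time before each onset).
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    thresh = float(np.percentile(ss.r, percentile))
    above = ss.r > thresh
    refr = int(round(refractory_ms * ss.rate / 1000.0))
    onsets = []
    for t in np.flatnonzero(above):
        if not above[max(0, t - refr) : t].any():
            onsets.append(t)
    return EventList(
        onsets=np.asarray(onsets, dtype=int),
        threshold_value=thresh,
        refractory_ms=refractory_ms,
        rate=ss.rate,
    )


def _morlet_power(
    data: np.ndarray, rate: float, freqs: np.ndarray, n_cycles: float = 7.0
) -> np.ndarray:
    """Wavelet power (freqs x channels x samples) of channels x samples."""
    n_ch, n_samp = data.shape
    out = np.empty((len(freqs), n_ch, n_samp))
    for fi, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(3 * sigma_t * rate))
        t = np.arange(-half, half + 1) / rate
        wavelet = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sigma_t**2))
        wavelet /= np.sqrt(np.sum(np.abs(wavelet) ** 2))
        for c in range(n_ch):
            conv = signal.fftconvolve(data[c], wavelet, mode="same")
            out[fi, c] = np.abs(conv) ** 2
    return out


def event_locked_power(
    rec: SensorRecording,
    ev: EventList,
    freq_max: float = 150.0,
    baseline_ms: tuple[float, float] = (-100.0, -50.0),
    *,
    window_ms: tuple[float, float] = (-100.0, 200.0),
    freq_min: float = 10.0,
    n_freqs: int = 29,
    n_cycles: float = 7.0,
) -> TFContrast:
    """Event-locked time-frequency power, baseline-corrected per frequency.

    Events whose epoch extends past the record edges, and events with
    another event inside their baseline window, are excluded.  Power is
    averaged over channels and events; the mean over the baseline window
    is subtracted per frequency.
    """
    if freq_max > rec.rate / 2:
        raise ValueError("freq_max exceeds the Nyquist frequency")
    rate = rec.rate
    lo = int(round(window_ms[0] * rate / 1000.0))
    hi = int(round(window_ms[1] * rate / 1000.0))
    base_lo = int(round(baseline_ms[0] * rate / 1000.0))

    onsets = np.sort(np.asarray(ev.onsets, dtype=int))
    keep = []
    for k, t in enumerate(onsets):
        if t + lo < 0 or t + hi >= rec.n_samples:
            continue
        others = np.delete(onsets, k)
        in_base = (others >= t + base_lo) & (others < t)
        if in_base.any():
            continue
        keep.append(t)
    if not keep:
        raise ValueError("no usable events")

    freqs = np.linspace(freq_min, freq_max, n_freqs)
    power = _morlet_power(rec.data, rate, freqs, n_cycles)
    power = power.mean(axis=1)  # average over channels -> freqs x samples

    times_ms = np.arange(lo, hi + 1) * 1000.0 / rate
    epochs = np.stack([power[:, t + lo : t + hi + 1] for t in keep])
    mean_power = epochs.mean(axis=0)
    base_mask = (times_ms >= baseline_ms[0]) & (times_ms <= baseline_ms[1])
    baseline = mean_power[:, base_mask].mean(axis=1, keepdims=True)
    return TFContrast(
        freqs=freqs,
        times_ms=times_ms,
        power_change=mean_power - baseline,
        n_events=len(keep),
    )


def cluster_permutation(
    maps: list[np.ndarray] | list[TFContrast],
    t_thresh: float = 3.1,
    n_perm: int = 5000,
    seed: int = 0,
) -> list[ClusterResult]:
    """One-sample cluster-based permutation test across subject maps.

    Cells with one-sample t above ``t_thresh`` form 4-connected
    clusters scored by summed t; the null is the max cluster score over
    random sign flips of the subject maps.  Returns clusters sorted by
    descending score with their family-wise corrected p values.
    """
    arrs = np.stack(
        [m.power_change if isinstance(m, TFContrast) else np.asarray(m) for m in maps]
    )
    if arrs.shape[0] < 2:
        raise ValueError("need at least 2 subject maps")
    rng = np.random.default_rng(seed)

    def _max_cluster(data: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        t = stats.ttest_1samp(data, 0.0, axis=0).statistic
        t = np.nan_to_num(t)
        labels, n_lab = ndimage.label(t > t_thresh)
        if n_lab == 0:
            return 0.0, labels, t
        sums = ndimage.sum_labels(t, labels, index=np.arange(1, n_lab + 1))
        return float(np.max(sums)), labels, t

    _, labels, tmap = _max_cluster(arrs)
    n_lab = labels.max()
    null = np.empty(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=arrs.shape[0])
        null[p], _, _ = _max_cluster(arrs * flips[:, None, None])

    results = []
    for lab in range(1, n_lab + 1):
        mask = labels == lab
        score = float(tmap[mask].sum())
        pval = (1 + int((null >= score).sum())) / (n_perm + 1)
        results.append(ClusterResult(mask=mask, stat=score, p_value=pval))
    results.sort(key=lambda c: -c.stat)
    return results


def _cross_beta(
    Ya: np.ndarray, Yb: np.ndarray, lag: int, nuis: list[int]
) -> np.ndarray:
    """Coefficients of lagged Ya columns predicting Yb columns, a x b."""
    n = Yb.shape[0]
    max_lag = max([lag] + nuis)
    rows = np.arange(max_lag, n)
    cols = [Ya[rows - lag]]
    cols += [Ya[rows - nl] for nl in nuis]
    cols.append(np.ones((len(rows), 1)))
    X = np.hstack(cols)
    coef, *_ = np.linalg.lstsq(X, Yb[rows], rcond=None)
    return coef[: Ya.shape[1]]


def cross_code_lag(
    Ya: ReactivationMatrix,
    Yb: ReactivationMatrix,
    pairing: dict[int, int],
    grid: LagGrid | None = None,
    nuisance_lags_ms: tuple[float, ...] | None = None,
) -> SequencenessCurve:
    """Lagged evidence that code *a* precedes its paired code *b*.

    ``pairing`` maps each a-state to its corresponding b-state (a
    rectangular 'transition' matrix).  Forward evidence at lag dt sums,
    over pairs, the coefficient of a-state at t-dt predicting its
    b-state at t (controlling for the other a-states); backward evidence
    swaps the roles.  diff > 0 means a leads b.
    """
    if Ya.n_samples != Yb.n_samples:
        raise ValueError("sample counts differ")
    if grid is None:
        grid = LagGrid.default(Ya.rate)
    M = np.zeros((Ya.n_states, Yb.n_states))
    for a, b in pairing.items():
        M[a, b] = 1.0
    lags = grid.samples(Ya.rate)
    nuis_ms = nuisance_lags_ms or ()
    zf = np.empty(len(lags))
    zb = np.empty(len(lags))
    for k, (lag, lag_ms) in enumerate(zip(lags, grid.lags_ms)):
        nuis = [
            int(LagGrid(np.array([lag_ms + off])).samples(Ya.rate)[0])
            for off in nuis_ms
        ]
        beta_f = _cross_beta(Ya.values, Yb.values, lag, nuis)  # a x b
        beta_b = _cross_beta(Yb.values, Ya.values, lag, nuis)  # b x a
        zf[k] = float(np.sum(beta_f * M))
        zb[k] = float(np.sum(beta_b.T * M))
    return SequencenessCurve(lags_ms=grid.lags_ms.copy(), zf=zf, zb=zb)


def cross_code_permutation_null(
    Ya: ReactivationMatrix,
    Yb: ReactivationMatrix,
    pairing: dict[int, int],
    grid: LagGrid | None = None,
    perms="auto",
    seed: int = 0,
    quantile: float = 1.0,
) -> NullDistribution:
    """Max-over-lags null for :func:`cross_code_lag` by permuting the pairing."""
    if grid is None:
        grid = LagGrid.default(Ya.rate)
    perm_list = _resolve_permutations(Ya.n_states, perms, seed)
    peaks = np.empty(len(perm_list))
    a_states = sorted(pairing)
    for i, perm in enumerate(perm_list):
        permuted = {a: pairing[a_states[perm[k]]] for k, a in enumerate(a_states)}
        curve = cross_code_lag(Ya, Yb, permuted, grid)
        peaks[i] = float(np.max(np.abs(curve.diff)))
    return NullDistribution(permutations=perm_list, null_peaks=peaks, quantile=quantile)


def onset_coincidence(
    x: np.ndarray, ev: EventList, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Is a reactivation time series elevated at detected onsets?

    The statistic is the mean of *x* at the onset samples minus its mean
    under circular shifts of the onset set (which preserve the series'
    autocorrelation); p is the fraction of shifts with onset mean at
    least as large as observed.
    """
    x = np.asarray(x, dtype=float)
    if len(ev.onsets) == 0:
        raise ValueError("event list is empty")
    if ev.onsets.max() >= len(x):
        raise ValueError("onsets exceed series length")
    rng = np.random.default_rng(seed)
    observed = float(x[ev.onsets].mean())
    null = np.empty(n_perm)
    for p in range(n_perm):
        shift = int(rng.integers(1, len(x)))
        null[p] = x[(ev.onsets + shift) % len(x)].mean()
    stat = observed - float(null.mean())
    pval = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return stat, pval
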