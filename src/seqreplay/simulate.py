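"""Synthetic sensor-level data with known ground truth.

Generates (a) a labeled localizer — one evoked spatial pattern per
state, peaking at a fixed post-onset latency — and (b) unlabeled
resting recordings with injected sequences of state patterns at a fixed
state-to-state lag, a shared-topography 10 Hz nuisance oscillation, and
white sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import StateSpec

DEFAULT_RATE = 100.0
DEFAULT_EVOKED_LATENCY_MS = 200.0
DEFAULT_ENVELOPE_MS = 100.0
ALPHA_HZ = 10.0


@dataclass
class PatternSet:
    """State-evoked spatial topographies, one unit-norm row per state."""

    patterns: np.ndarray  # n_states x n_channels
    evoked_latency_ms: float = DEFAULT_EVOKED_LATENCY_MS
    envelope_ms: float = DEFAULT_ENVELOPE_MS

    @property
    def n_states(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_channels(self) -> int:
        return self.patterns.shape[1]


@dataclass
class SensorRecording:
    """Multichannel time series (channels x samples)."""

    data: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Labeled trials: trials x channels x times, times in ms from onset."""

    trials: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    rate: float = DEFAULT_RATE

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    def time_index(self, time_ms: float) -> int:
        idx = int(np.argmin(np.abs(self.times - time_ms)))
        if abs(self.times[idx] - time_ms) > 1000.0 / self.rate:
            raise ValueError(f"time {time_ms} ms outside epoch window")
        return idx


@dataclass
class GroundTruthEvents:
    """Injected activations grouped into replay events."""

    event_times: np.ndarray  # sample index of each activation
    event_states: np.ndarray  # state index of each activation
    sequence_ids: np.ndarray  # replay-event id of each activation
    direction: str
    lag_ms: float

    def onsets(self) -> np.ndarray:
        """First activation sample of each replay event."""
        first = []
        for sid in np.unique(self.sequence_ids):
            first.append(self.event_times[self.sequence_ids == sid].min())
        return np.sort(np.asarray(first))


def make_state_patterns(
    n_channels: int,
    n_states: int,
    seed: int = 0,
    *,
    max_abs_corr: float = 0.3,
    orthogonalize: bool = False,
    max_redraws: int = 200,
    evoked_latency_ms: float = DEFAULT_EVOKED_LATENCY_MS,
    envelope_ms: float = DEFAULT_ENVELOPE_MS,
) -> PatternSet:
    """Draw unit-norm random topographies with bounded pairwise correlation."""
    if n_channels < n_states:
        raise ValueError("n_channels must be >= n_states")
    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        pats = rng.standard_normal((n_states, n_channels))
        if orthogonalize:
            q, _ = np.linalg.qr(pats.T)
            pats = q[:, :n_states].T
        pats /= np.linalg.norm(pats, axis=1, keepdims=True)
        corr = np.corrcoef(pats)
        off = corr[~np.eye(n_states, dtype=bool)]
        if np.abs(off).max() < max_abs_corr:
            return PatternSet(pats, evoked_latency_ms, envelope_ms)
    raise RuntimeError(
        f"could not satisfy |r| < {max_abs_corr} in {max_redraws} redraws"
    )


def _envelope(width_samples: int) -> np.ndarray:
    """Half-cosine bump of the given total width, peak 1 at the centre."""
    if width_samples < 1:
        return np.ones(1)
    x = np.linspace(-np.pi / 2, np.pi / 2, width_samples + 2)[1:-1]
    return np.cos(x)


def _add_pattern(data: np.ndarray, pattern: np.ndarray, center: int,
                 env: np.ndarray, amplitude: float) -> None:
    """Add ``amplitude * env * pattern`` into *data* centred at *center*."""
    half = len(env) // 2
    lo = center - half
    hi = lo + len(env)
    elo = max(0, -lo)
    ehi = len(env) - max(0, hi - data.shape[1])
    lo, hi = max(lo, 0), min(hi, data.shape[1])
    data[:, lo:hi] += amplitude * np.outer(pattern, env[elo:ehi])


def simulate_localizer(
    p: PatternSet,
    n_trials_per_state: int,
    noise_sd: float,
    seed: int = 0,
    *,
    rate: float = DEFAULT_RATE,
    tmin_ms: float = -200.0,
    tmax_ms: float = 500.0,
    amplitude: float = 1.0,
) -> EpochSet:
    """Simulate labeled localizer epochs.

    Each trial carries its state's pattern under a half-cosine envelope
    centred at the evoked latency, on top of white sensor noise.  The
    pre-onset segment is pattern-free and serves as null data for
    decoder negatives (see :func:`null_examples`).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_states, n_channels = p.patterns.shape
    times = np.arange(round(tmin_ms * rate / 1000), round(tmax_ms * rate / 1000) + 1)
    times_ms = times * 1000.0 / rate
    labels = np.repeat(np.arange(n_states), n_trials_per_state)
    rng.shuffle(labels)
    n_trials = len(labels)
    env = _envelope(max(1, round(p.envelope_ms * rate / 1000)))
    center = int(np.argmin(np.abs(times_ms - p.evoked_latency_ms)))
    trials = noise_sd * rng.standard_normal((n_trials, n_channels, len(times)))
    for t, lab in enumerate(labels):
        _add_pattern(trials[t], p.patterns[lab], center, env, amplitude)
    return EpochSet(trials=trials, labels=labels, times=times_ms, rate=rate)


def null_examples(ep: EpochSet, time_ms: float = -100.0) -> np.ndarray:
    """Pre-onset (pattern-free) slices of an epoch set, trials x channels."""
    if time_ms >= 0:
        raise ValueError("null examples must come from the pre-onset window")
    return ep.trials[:, :, ep.time_index(time_ms)]


def simulate_rest(
    p: PatternSet,
    spec: StateSpec,
    which_order: str = "rule",
    lag_ms: float = 50.0,
    direction: str = "forward",
    n_events: int = 60,
    alpha_amp: float = 1.0,
    duration_s: float = 300.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    rate: float = DEFAULT_RATE,
    amplitude: float = 1.0,
    min_gap_ms: float = 500.0,
) -> tuple[SensorRecording, GroundTruthEvents]:
    """Simulate a resting recording with injected 4-state replay events.

    Each event walks one full chain of the chosen transition matrix at a
    fixed state-to-state lag, forward or reverse, injecting the state
    patterns under the evoked envelope.  A 10 Hz sinusoid with a fixed
    random topography (shared across the whole run) and white noise are
    added.  Returns the recording and the injected ground truth.
    """
    rng = np.random.default_rng(seed)
    n_samples = round(duration_s * rate)
    lag = lag_ms * rate / 1000.0
    if abs(lag - round(lag)) > 1e-9:
        raise ValueError("lag_ms must be a multiple of the sample period")
    lag = int(round(lag))
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if which_order == "rule":
        chains = spec.chains
    elif which_order == "visual":
        chains = [list(stage) for stage in spec.stages]
    else:
        raise ValueError("which_order must be 'rule' or 'visual'")

    env = _envelope(max(1, round(p.envelope_ms * rate / 1000)))
    event_len = 3 * lag + len(env)
    min_gap = round(min_gap_ms * rate / 1000)
    slot = event_len + min_gap
    if n_events * slot > n_samples - len(env):
        raise ValueError(
            f"cannot place {n_events} non-overlapping events in {duration_s} s"
        )

    # place events: jittered onsets inside evenly sized slots -> no overlap
    onsets = []
    if n_events:
        slot_width = n_samples // n_events
        for k in range(n_events):
            jitter = rng.integers(0, max(1, slot_width - event_len - len(env)))
            onsets.append(k * slot_width + len(env) // 2 + int(jitter))

    data = noise_sd * rng.standard_normal((p.n_channels, n_samples))
    alpha_topo = rng.standard_normal(p.n_channels)
    alpha_topo /= np.linalg.norm(alpha_topo)
    t = np.arange(n_samples) / rate
    phase = rng.uniform(0, 2 * np.pi)
    data += alpha_amp * np.outer(alpha_topo, np.sin(2 * np.pi * ALPHA_HZ * t + phase))

    ev_times, ev_states, seq_ids = [], [], []
    for sid, onset in enumerate(onsets):
        chain = list(chains[rng.integers(len(chains))])
        if direction == "reverse":
            chain = chain[::-1]
        for k, state in enumerate(chain):
            center = onset + k * lag
            _add_pattern(data, p.patterns[state], center, env, amplitude)
            ev_times.append(center)
            ev_states.append(state)
            seq_ids.append(sid)

    truth = GroundTruthEvents(
        event_times=np.asarray(ev_times, dtype=int),
        event_states=np.asarray(ev_states, dtype=int),
        sequence_ids=np.asarray(seq_ids, dtype=int),
        direction=direction,
        lag_ms=lag_ms,
    )
    return SensorRecording(data=data, rate=rate), truth


def inject_bursts(
    rec: SensorRecording,
    onset_samples: np.ndarray,
    freq_hz: float,
    duration_ms: float,
    amplitude: float,
    seed: int = 0,
) -> SensorRecording:
    """Add short narrow-band oscillatory bursts at the given onsets.

    Used to validate event-locked spectral contrasts (e.g. planting
    120-150 Hz power at replay onsets); the burst topography is random
    but fixed across events.
    """
    rng = np.random.default_rng(seed)
    topo = rng.standard_normal(rec.n_channels)
    topo /= np.linalg.norm(topo)
    n = round(duration_ms * rec.rate / 1000)
    t = np.arange(n) / rec.rate
    burst = np.sin(2 * np.pi * freq_hz * t) * np.hanning(n)
    data = rec.data.copy()
    for onset in np.asarray(onset_samples, dtype=int):
        hi = min(onset + n, rec.n_samples)
        if hi <= onset:
            continue
        data[:, onset:hi] += amplitude * np.outer(topo, burst[: hi - onset])
    return SensorRecording(data=data, rate=rec.rate)
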