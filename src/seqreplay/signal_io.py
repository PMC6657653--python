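"""Minimal preprocessing (resampling, high-pass) and array I/O."""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

from .simulate import EpochSet, GroundTruthEvents, SensorRecording


def resample(rec: SensorRecording, target_rate: float) -> SensorRecording:
    """Band-limited resampling (polyphase, anti-aliased) to *target_rate*.

    Only downsampling (or identity) is allowed, mirroring a
    600 Hz -> 100 Hz decimation step.
    """
    if target_rate > rec.rate:
        raise ValueError("upsampling not supported")
    if target_rate == rec.rate:
        return SensorRecording(data=rec.data.copy(), rate=rec.rate)
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return SensorRecording(data=out, rate=target_rate)


def highpass(
    rec: SensorRecording, cutoff_hz: float, *, zero_phase: bool = False
) -> SensorRecording:
    """First-order IIR high-pass per channel (causal by default)."""
    if not 0 < cutoff_hz < rec.rate / 2:
        raise ValueError("cutoff must lie in (0, rate/2)")
    b, a = signal.butter(1, cutoff_hz, btype="highpass", fs=rec.rate)
    if zero_phase:
        out = signal.filtfilt(b, a, rec.data, axis=1)
    else:
        out = signal.lfilter(b, a, rec.data, axis=1)
    return SensorRecording(data=out, rate=rec.rate)


def save_recording(path: str | Path, rec: SensorRecording,
                   truth: GroundTruthEvents | None = None) -> None:
    """Write a recording as ``.npz`` plus a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=rec.data)
    meta: dict = {"rate": rec.rate, "n_channels": rec.n_channels}
    if truth is not None:
        meta["ground_truth"] = {
            "event_times": truth.event_times.tolist(),
            "event_states": truth.event_states.tolist(),
            "sequence_ids": truth.sequence_ids.tolist(),
            "direction": truth.direction,
            "lag_ms": truth.lag_ms,
        }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_recording(path: str | Path) -> tuple[SensorRecording, GroundTruthEvents | None]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        data = npz["data"]
    meta = json.loads(path.with_suffix(".json").read_text())
    rec = SensorRecording(data=data, rate=meta["rate"])
    truth = None
    if "ground_truth" in meta:
        gt = meta["ground_truth"]
        truth = GroundTruthEvents(
            event_times=np.asarray(gt["event_times"], dtype=int),
            event_states=np.asarray(gt["event_states"], dtype=int),
            sequence_ids=np.asarray(gt["sequence_ids"], dtype=int),
            direction=gt["direction"],
            lag_ms=gt["lag_ms"],
        )
    return rec, truth


def save_epochs(path: str | Path, ep: EpochSet) -> None:
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"), trials=ep.trials, labels=ep.labels, times=ep.times
    )
    path.with_suffix(".json").write_text(json.dumps({"rate": ep.rate}))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as npz:
        return EpochSet(
            trials=npz["trials"], labels=npz["labels"], times=npz["times"],
            rate=meta["rate"],
        )
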