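"""Post-processing chain that turns raw model traces into EEG-like records.

The model clock and amplitude are arbitrary, so four steps emulate a
clinical acquisition pipeline:

1. amplitude normalization to [0, 1];
2. spike-rate time rescaling -- an effective sampling frequency is assigned
   so the median intra-seizure spike rate lands in the clinical 1-30 Hz
   band (default target 10 Hz); this is a pure relabeling of the time axis;
3. a causal second-order Butterworth high-pass (cutoff 0.1-1 Hz, default
   0.5 Hz) emulating the AC-coupled clinical amplifier -- this is what
   truncates ictal DC shifts in real recordings;
4. additive background noise: unit-variance pink noise scaled by
   ``alpha * max(trace)`` (alpha 0 / 0.20 / 0.40 = none / moderate / high),
   emulating background brain activity and acquisition noise.

Finally the dataset is doubled by duplicating each record with the
amplitudes vertically flipped, since SEEG spike polarity is arbitrary.
Ground-truth onset/offset labels are defined on the dynamics and are never
altered by post-processing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .integrate import SimulationResult, generate_pink_noise

__all__ = [
    "SeizureRecord",
    "BackgroundNoiseConfig",
    "normalize01",
    "detect_spikes",
    "rescale_time",
    "highpass",
    "add_background_noise",
    "polarity_double",
    "postprocess",
]

RATE_BOUNDS = (1.0, 30.0)  # Hz, clinical intra-seizure spike-rate band
DEFAULT_TARGET_RATE = 10.0  # Hz
DEFAULT_CUTOFF = 0.5  # Hz, midrange of the 0.1-1 Hz clinical high-pass band


@dataclass
class BackgroundNoiseConfig:
    """Additive pink-noise amplitude as a fraction of the bursting maximum."""

    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass
class SeizureRecord:
    """A post-processed voltage trace with ground-truth labels.

    ``trace`` is in normalized units (optionally scaled by ``gain``); ``fs``
    is the effective sampling frequency assigned by the time-rescaling step.
    ``onset_sample``/``offset_sample`` are the dynamics-defined event
    indices; they are invariant under every post-processing stage.
    ``provenance`` accumulates each stage's parameters.
    """

    trace: np.ndarray
    fs: float
    onset_sample: int
    offset_sample: int
    labels: dict = field(default_factory=dict)
    noise_alpha: float = 0.0
    filter_cutoff: float | None = None
    polarity: int = 1
    seed: int = 0
    gain: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.onset_sample < self.offset_sample:
            raise ValueError("onset_sample must precede offset_sample")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.trace)) / self.fs

    def save_csv(self, stem: str | Path) -> None:
        stem = Path(stem)
        np.savetxt(
            stem.with_suffix(".csv"),
            np.column_stack([self.times, self.trace]),
            delimiter=",",
            header="t_seconds,v",
            comments="",
        )
        sidecar = {
            "fs": self.fs,
            "onset_sample": self.onset_sample,
            "offset_sample": self.offset_sample,
            "labels": self.labels,
            "noise_alpha": self.noise_alpha,
            "filter_cutoff": self.filter_cutoff,
            "polarity": self.polarity,
            "seed": self.seed,
            "gain": self.gain,
            "provenance": self.provenance,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def normalize01(trace: np.ndarray) -> np.ndarray:
    """Affine map of a trace onto [0, 1] (idempotent; constant traces are
    rejected because their scale is undefined)."""
    trace = np.asarray(trace, dtype=float)
    lo, hi = trace.min(), trace.max()
    if hi - lo <= 0:
        raise ValueError("cannot normalize a constant trace")
    return (trace - lo) / (hi - lo)


def detect_spikes(trace: np.ndarray, fs: float) -> np.ndarray:
    """Prominence-based spike detection.

    Local maxima with prominence at least 20% of the trace range, separated
    by at least ``fs/30`` samples (no two spikes closer than the period of
    the fastest clinical spike rate).  Scale-invariant by construction.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    trace = np.asarray(trace, dtype=float)
    rng = trace.max() - trace.min()
    if rng <= 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(fs / RATE_BOUNDS[1])))
    peaks, _ = signal.find_peaks(trace, prominence=0.2 * rng, distance=distance)
    return peaks


def rescale_time(
    result: SimulationResult,
    target_rate_bounds: tuple[float, float] = RATE_BOUNDS,
    target_rate: float = DEFAULT_TARGET_RATE,
    labels: dict | None = None,
    seed: int = 0,
) -> SeizureRecord:
    """Assign an effective sampling frequency so the median intra-seizure
    spike rate equals ``target_rate`` (clamped into ``target_rate_bounds``).

    The model clock is arbitrary; this step is a pure relabeling of the time
    axis and is idempotent.  The trace is normalized to [0, 1] first (the
    record invariant: normalized before filtering).  Requires at least three
    detected spikes between the labelled onset and offset.
    """
    if not result.has_labels:
        raise ValueError("result must carry onset/offset labels")
    lo, hi = target_rate_bounds
    target = min(max(target_rate, lo), hi)
    trace = normalize01(result.x)
    i0, i1 = result.onset_index, result.offset_index
    # detect in model-sample units (nominal fs of 1 per sample)
    spikes = detect_spikes(trace[i0:i1], fs=1.0)
    if len(spikes) < 3:
        raise ValueError(
            f"need >= 3 intra-seizure spikes to rescale, found {len(spikes)}"
        )
    med_gap_samples = float(np.median(np.diff(spikes)))
    # fs such that median rate = target: rate = fs / gap  =>  fs = target*gap
    fs = target * med_gap_samples
    return SeizureRecord(
        trace=trace,
        fs=fs,
        onset_sample=i0,
        offset_sample=i1,
        labels=labels or {},
        seed=seed,
        provenance={
            "rescale": {
                "target_rate_hz": target,
                "median_spike_gap_samples": med_gap_samples,
                "n_spikes": int(len(spikes)),
            }
        },
    )


def highpass(
    trace: np.ndarray, fs: float, cutoff: float = DEFAULT_CUTOFF, order: int = 2
) -> np.ndarray:
    """Causal Butterworth high-pass (single pass, like a real amplifier:
    zero-phase filtering would misrepresent how DC shifts are distorted).

    DC gain is zero and the passband gain approaches one.
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {fs / 2}), got {cutoff}")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfilt(sos, np.asarray(trace, dtype=float))


def add_background_noise(
    trace: np.ndarray, config: BackgroundNoiseConfig, seed: int
) -> np.ndarray:
    """Add unit-variance pink noise scaled by ``alpha * max(trace)``
    (deterministic per seed; ``alpha = 0`` returns the input unchanged)."""
    trace = np.asarray(trace, dtype=float)
    if config.alpha == 0:
        return trace.copy()
    pink = generate_pink_noise(len(trace), seed).samples
    return trace + pink * config.alpha * float(trace.max())


def polarity_double(records: list[SeizureRecord]) -> list[SeizureRecord]:
    """Duplicate every record with the amplitudes vertically flipped
    (reflection about the trace mid-range), removing the arbitrary SEEG
    spike polarity.  Labels and spike times are preserved; output count is
    twice the input count."""
    out = list(records)
    for rec in records:
        lo, hi = rec.trace.min(), rec.trace.max()
        flipped = replace(
            rec,
            trace=(lo + hi) - rec.trace,
            polarity=-rec.polarity,
            provenance={**rec.provenance, "flipped": True},
        )
        out.append(flipped)
    return out


def postprocess(
    result: SimulationResult,
    alpha: float = 0.0,
    cutoff: float | None = DEFAULT_CUTOFF,
    target_rate: float = DEFAULT_TARGET_RATE,
    gain: float = 1.0,
    labels: dict | None = None,
    seed: int = 0,
) -> SeizureRecord:
    """The full chain on one simulation: normalize -> rescale -> high-pass
    (skipped when ``cutoff`` is None, e.g. for classifier-grade traces) ->
    background noise -> optional output gain.  Polarity doubling operates on
    record lists and is applied separately."""
    rec = rescale_time(result, target_rate=target_rate, labels=labels, seed=seed)
    trace = rec.trace
    if cutoff is not None:
        trace = highpass(trace, rec.fs, cutoff=cutoff)
        rec.provenance["highpass"] = {"cutoff_hz": cutoff, "order": 2}
    noise_cfg = BackgroundNoiseConfig(alpha=alpha)
    trace = add_background_noise(trace, noise_cfg, seed)
    if alpha > 0:
        rec.provenance["background_noise"] = {"alpha": alpha, "seed": seed}
    if gain != 1.0:
        trace = trace * gain
        rec.provenance["gain"] = gain
    rec.trace = trace
    rec.noise_alpha = alpha
    rec.filter_cutoff = cutoff
    rec.gain = gain
    return rec
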