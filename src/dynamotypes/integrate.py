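"""Euler-Maruyama integration of the coupled fast-slow system with pink
dynamical noise, deterministic seeding, and event labeling.

The update per step is

    state_{n+1} = state_n + tstep * drift(state_n) + tstep * [sigma*xi_n, 0, 0]

where ``xi`` is unit-variance pink (1/f) noise entering only the fast
variable ``x``.  Note the stochastic increment is scaled by ``tstep`` (not
``sqrt(tstep)``) -- exactly the model's printed update rule.  As a result
the effective noise strength depends on the step size, which is why the
dynamical-noise amplitude is calibrated empirically per path
(:mod:`dynamotypes.calibration`) rather than interpreted as a diffusion
coefficient.

Onset and offset of the simulated seizure are mathematically defined: in the
hysteresis model the onset is the first sample with ``z > 0`` and the offset
the subsequent return crossing of the offset-curve parameter; in the
slow-wave and piecewise models they are the path's crossings of its onset
and offset bifurcation curves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import em_loop
from .paths import (
    BurstingPath,
    HysteresisConfig,
    PiecewiseConfig,
    SlowWaveConfig,
)

__all__ = [
    "IntegratorConfig",
    "PinkNoiseProcess",
    "SimulationResult",
    "IntegrationBlowupError",
    "generate_pink_noise",
    "integrate",
    "label_events",
]

_SLOW_KINDS = {"hysteresis": 0, "slow_wave": 1, "piecewise": 2}


class IntegrationBlowupError(RuntimeError):
    """Raised when the trajectory exceeds the state bound; names the step
    and the local path parameters."""


@dataclass(frozen=True)
class IntegratorConfig:
    """Settings of one Euler-Maruyama run.

    ``tstep`` and ``duration`` are in model time units (the model clock is
    arbitrary; the post-processing stage assigns physical seconds).  The
    default step resolves the fastest intra-burst oscillation on the default
    sphere (shortest period ~ 5 time units) by well over 50 steps per cycle.
    """

    tstep: float = 0.05
    duration: float = 4000.0
    seed: int = 0
    sigma: float = 0.0
    k_fast: float = 1.0

    def __post_init__(self) -> None:
        if self.tstep <= 0:
            raise ValueError("tstep must be positive")
        if self.duration < self.tstep:
            raise ValueError("duration must cover at least one step")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.tstep))

    def to_dict(self) -> dict:
        return {
            "tstep": self.tstep,
            "duration": self.duration,
            "seed": self.seed,
            "sigma": self.sigma,
            "k_fast": self.k_fast,
        }


@dataclass(frozen=True)
class PinkNoiseProcess:
    """A unit-variance 1/f noise realization with its generating seed."""

    samples: np.ndarray
    seed: int


def generate_pink_noise(n: int, seed: int) -> PinkNoiseProcess:
    """Unit-variance Gaussian 1/f ("pink") noise of length ``n``.

    Synthesized by spectral shaping: white Gaussian noise is filtered in the
    frequency domain by 1/sqrt(f) (power spectral density proportional to
    1/f), the zero-frequency bin zeroed, and the result normalized to unit
    sample variance.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    if n < 8:  # too short for spectral shaping; return normalized white noise
        w = white - white.mean()
        sd = w.std()
        return PinkNoiseProcess(w / sd if sd > 0 else w, seed)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    samples = np.fft.irfft(spec * scale, n=n)
    samples /= samples.std()
    return PinkNoiseProcess(samples, seed)


@dataclass
class SimulationResult:
    """Raw integrated time series plus event labels.

    Bit-identical reproducible from ``(path, config)`` -- all randomness is
    derived from ``config.seed``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    path: BurstingPath
    config: IntegratorConfig
    onset_index: int | None = None
    offset_index: int | None = None
    labels_flagged: bool = False  # True when a crossing was searched but absent

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("t, x, y, z must have equal length")
        if (
            self.onset_index is not None
            and self.offset_index is not None
            and not self.onset_index < self.offset_index
        ):
            raise ValueError("onset_index must precede offset_index")

    @property
    def has_labels(self) -> bool:
        return self.onset_index is not None and self.offset_index is not None

    def save_csv(self, stem: str | Path) -> None:
        """Column table (t, x, y, z) as CSV plus a JSON sidecar with the
        configuration, path specification and event labels."""
        stem = Path(stem)
        arr = np.column_stack([self.t, self.x, self.y, self.z])
        np.savetxt(
            stem.with_suffix(".csv"),
            arr,
            delimiter=",",
            header="t,x,y,z",
            comments="",
        )
        sidecar = {
            "config": self.config.to_dict(),
            "path": self.path.spec_dict(),
            "onset_index": self.onset_index,
            "offset_index": self.offset_index,
            "labels_flagged": self.labels_flagged,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def integrate(
    path: BurstingPath,
    slow_dynamics: HysteresisConfig | SlowWaveConfig | PiecewiseConfig | None = None,
    config: IntegratorConfig = IntegratorConfig(),
    z0: float | None = None,
    label: bool = True,
) -> SimulationResult:
    """Integrate the coupled system along a bursting path.

    ``slow_dynamics`` defaults to the configuration stored on the path.  The
    initial fast state is the resting equilibrium at the initial path
    position (deterministic).  With ``sigma = 0`` the run reduces exactly to
    a deterministic Euler scheme.
    """
    slow = slow_dynamics if slow_dynamics is not None else path.config
    if isinstance(slow, HysteresisConfig):
        kind = 0
    elif isinstance(slow, SlowWaveConfig):
        kind = 1
    elif isinstance(slow, PiecewiseConfig):
        kind = 2
    else:
        raise TypeError(f"unsupported slow dynamics {type(slow).__name__}")
    if slow is not path.config:
        path = replace_kind_config(path, slow)

    n = config.n_steps
    if config.sigma > 0:
        noise = config.sigma * generate_pink_noise(n, config.seed).samples
    else:
        noise = np.zeros(n)

    z_init = path.z_start if z0 is None else z0
    p0 = path.params_at(z_init)
    from ._kernels import stable_rest_root

    x0 = float(stable_rest_root(p0.mu1, p0.mu2, p0.nu, 0.0))
    y0 = 0.0

    ka = path.kernel_arrays()
    if kind == 2:
        t_breaks, seg_speeds = path.time_profile()
    else:
        t_breaks = np.array([math.inf])
        seg_speeds = np.array([0.0])
    c_slow = slow.c if kind == 0 else 0.0
    dstar = slow.d_star if kind == 0 else 0.0
    k_slow = slow.k if kind == 1 else 0.0

    xs, ys, zs, err = em_loop(
        x0,
        y0,
        z_init,
        n,
        config.tstep,
        config.k_fast,
        ka["arc_z0"],
        ka["arc_z1"],
        ka["C"],
        ka["U"],
        ka["V"],
        ka["r"],
        ka["closed"],
        ka["period"],
        kind,
        c_slow,
        dstar,
        k_slow,
        t_breaks,
        seg_speeds,
        noise,
    )
    if err >= 0:
        p_err = path.params_at(float(zs[-1]))
        raise IntegrationBlowupError(
            f"state bound exceeded at step {err} (t={err * config.tstep:.2f}) "
            f"with parameters mu1={p_err.mu1:.4f}, mu2={p_err.mu2:.4f}, "
            f"nu={p_err.nu:.4f}"
        )
    t = np.arange(n + 1) * config.tstep
    result = SimulationResult(t=t, x=xs, y=ys, z=zs, path=path, config=config)
    if label:
        result = label_events(result)
    return result


def replace_kind_config(path: BurstingPath, slow) -> BurstingPath:
    """Return a copy of ``path`` carrying ``slow`` as its drift config (used
    when a caller overrides the slow dynamics of a prebuilt path)."""
    import copy

    new = copy.copy(path)
    new.config = slow
    return new


def label_events(result: SimulationResult, method: str | None = None) -> SimulationResult:
    """Attach onset/offset sample indices to a simulation result.

    Hysteresis: onset at the first sample with ``z > 0`` (the path parameter
    is zero at the onset-curve crossing) and offset at the subsequent return
    of ``z`` below the offset-crossing parameter.  Slow-wave and piecewise:
    onset/offset at the first upward crossings of the respective curve
    parameters.  Missing crossings leave the indices absent and set
    ``labels_flagged``.
    """
    method = method or result.path.kind
    z = result.z
    path = result.path
    onset = offset = None
    if method == "hysteresis":
        above = np.flatnonzero(z > path.z_onset)
        if len(above):
            onset = int(above[0])
            below = np.flatnonzero(z[onset:] < path.z_offset)
            if len(below):
                offset = onset + int(below[0])
    elif method in ("slow_wave", "piecewise"):
        above = np.flatnonzero(z > path.z_onset)
        if len(above):
            onset = int(above[0])
            past = np.flatnonzero(z[onset:] > path.z_offset)
            if len(past):
                offset = onset + int(past[0])
    else:
        raise ValueError(f"unknown labeling method {method!r}")
    flagged = onset is None or offset is None
    return SimulationResult(
        t=result.t,
        x=result.x,
        y=result.y,
        z=result.z,
        path=result.path,
        config=result.config,
        onset_index=onset,
        offset_index=offset,
        labels_flagged=flagged,
    )
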