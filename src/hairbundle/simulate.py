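"""Synthetic coupled hair-bundle dynamics under efferent drive.

Each bundle is a two-variable relaxation oscillator: a fast bistable
position coordinate x (the bundle sits on one of two branches of a cubic
force balance, mirroring the channel-closed / channel-open dwelling states
that make real position histograms bimodal) and a slow adaptation force f
that drags the system around the hysteresis loop:

    tau_m dx_i/dt = -x_i^3 + a x_i - f_i + k_i (X_m - x_i)
                    + g_x s(t) + noise
         df_i/dt = eps_i (1 + g_f s(t)) * (x_i - c - g_s s(t))

x is dimensionless and scaled to nm by position_scale; eps_i sets the
cycle rate and is calibrated so a requested natural frequency in Hz is
met; X_m is the position of the overlying rigid plate (mica flake), the
spring-constant-weighted average of all attached bundles, which couples
them mechanically.

Efferent drive s(t) (a square pulse train or a constant step, in uA) acts
through three instantaneous gains:

* g_s shifts the adaptation set point (negative by default: efferent
  hyperpolarization biases the bundle toward the channel-closed state,
  lowering open probability and, with it, amplitude),
* g_f multiplies the adaptation rate, eps_eff = eps_i*(1 + g_f*s(t)),
  raising the oscillation frequency,
* g_x adds a direct force g_x*s(t) to the fast force balance. Because the
  slow adaptation variable absorbs any constant force, this term has no
  steady-state effect under step drive; under a pulse train it supplies
  the fast periodic forcing that entrains the oscillators to the drive
  frequency, which the low-pass-filtered set-point pathway alone cannot.

Integration is fixed-step Euler-Maruyama at >= 10 kHz, decimated to the
camera frame rate; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .preprocess import StimulusProtocol

__all__ = [
    "OscillatorParams",
    "CouplingConfig",
    "EfferentDrive",
    "SimOutput",
    "adaptation_rate_for_frequency",
    "default_params",
    "efferent_waveform",
    "simulate_bundles",
    "null_ensemble",
    "render_frames",
]

# Deterministic cycle frequency (Hz) of the default oscillator (a=1, c=0,
# tau_m=2 ms, noiseless) on a grid of adaptation rates, measured once by
# zero-crossing counting over 20 s runs; natural_frequency_target is mapped
# to an adaptation rate by log-log interpolation of this table. The
# dependence is sublinear because the fast branch jumps take a finite time
# (~tau_m) out of every cycle.
_EPS_GRID = np.array([5.0, 8.0, 12.0, 18.0, 27.0, 40.0, 60.0, 90.0, 135.0,
                      200.0, 300.0, 450.0, 700.0, 1100.0, 1700.0, 2600.0])
_FREQ_GRID = np.array([2.639, 3.972, 5.639, 7.889, 10.889, 14.722, 19.778,
                       26.194, 34.222, 43.750, 55.722, 70.250, 89.583,
                       114.028, 143.083, 178.056])


@dataclass(frozen=True)
class OscillatorParams:
    """Single-bundle oscillator parameters.

    stiffness_scale a sets the bistability (wells near +-sqrt(a) in
    dimensionless units); adaptation_rate eps (1/s) sets the cycle rate;
    natural_frequency_target (Hz), when given, overrides eps through the
    calibrated rate-frequency map; noise_intensity is in nm/sqrt(s);
    spike_offset c (nm) biases the adaptation set point; position_scale
    (nm) converts dimensionless positions to nm.
    """

    stiffness_scale: float = 1.0
    adaptation_rate: float = 55.0
    natural_frequency_target: Optional[float] = None
    noise_intensity: float = 250.0
    spike_offset: float = 0.0
    position_scale: float = 35.0
    fast_timescale_s: float = 0.002

    def __post_init__(self) -> None:
        if self.adaptation_rate <= 0:
            raise ValueError("adaptation_rate must be positive")
        if self.noise_intensity < 0:
            raise ValueError("noise_intensity must be >= 0")
        f = self.effective_frequency_target
        if self.natural_frequency_target is not None and not (0 < f):
            raise ValueError("natural_frequency_target must be positive")

    @property
    def effective_frequency_target(self) -> float:
        if self.natural_frequency_target is not None:
            return self.natural_frequency_target
        return float(np.exp(np.interp(np.log(self.adaptation_rate),
                                      np.log(_EPS_GRID),
                                      np.log(_FREQ_GRID))))

    @property
    def effective_adaptation_rate(self) -> float:
        if self.natural_frequency_target is not None:
            return adaptation_rate_for_frequency(self.natural_frequency_target)
        return self.adaptation_rate


def adaptation_rate_for_frequency(f_hz: float) -> float:
    """Adaptation rate eps giving the requested deterministic cycle rate
    for the default oscillator (a=1, c=0, tau_m=2 ms), by log-log
    interpolation of the calibration table (valid ~3-170 Hz)."""
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    if not (_FREQ_GRID[0] <= f_hz <= _FREQ_GRID[-1]):
        raise ValueError(f"frequency target {f_hz:g} Hz is outside the "
                         f"calibrated range [{_FREQ_GRID[0]:g}, "
                         f"{_FREQ_GRID[-1]:g}] Hz")
    return float(np.exp(np.interp(np.log(f_hz), np.log(_FREQ_GRID),
                                  np.log(_EPS_GRID))))


@dataclass(frozen=True)
class CouplingConfig:
    """Mechanical coupling of bundles to the overlying rigid plate.

    attachment marks which cells contact the plate; spring_constant k_i
    (dimensionless, >= 0) scales both each cell's pull on the plate and
    the restoring force k_i (X_m - x_i) the plate exerts back. The plate
    is massless and rigid, so its position is the k-weighted average of
    the attached bundle positions at every instant.
    """

    attachment: Tuple[bool, ...]
    spring_constant: Tuple[float, ...]
    n_cells: int

    @classmethod
    def uniform(cls, n_cells: int, k: float = 0.35,
                attached: Optional[Sequence[bool]] = None) -> "CouplingConfig":
        if attached is None:
            attached = [k > 0] * n_cells
        ks = tuple(k if a else 0.0 for a in attached)
        return cls(attachment=tuple(bool(a) for a in attached),
                   spring_constant=ks, n_cells=n_cells)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if len(self.attachment) != self.n_cells or \
                len(self.spring_constant) != self.n_cells:
            raise ValueError("attachment and spring_constant must have one "
                             "entry per cell")
        if any(k < 0 for k in self.spring_constant):
            raise ValueError("spring constants must be >= 0")
        if any(a and k == 0 for a, k in
               zip(self.attachment, self.spring_constant)):
            raise ValueError("attached cells need a positive spring constant")

    @property
    def any_attached(self) -> bool:
        return any(a for a in self.attachment)


@dataclass(frozen=True)
class EfferentDrive:
    """Efferent stimulation waveform and its coupling to the oscillators.

    kind 'pulse_train' is a square wave at `frequency` Hz with the given
    duty cycle; 'step' is a constant level; 'none' is identically zero.
    intensity is the drive amplitude in uA-equivalents. gain_setpoint g_s
    (1/uA, negative = towards the closed state), gain_frequency g_f (1/uA)
    and gain_force g_x (1/uA) convert the waveform into the set-point
    shift, adaptation-rate factor and fast force term described in the
    module docstring.
    """

    kind: str = "none"
    frequency: Optional[float] = None
    duty_cycle: float = 0.5
    intensity: float = 0.0
    gain_setpoint: float = -0.0015
    gain_frequency: float = 0.003
    gain_force: float = 0.008

    def __post_init__(self) -> None:
        if self.kind not in ("none", "pulse_train", "step"):
            raise ValueError(f"unknown drive kind {self.kind!r}")
        if self.kind == "pulse_train":
            if self.frequency is None or self.frequency <= 0:
                raise ValueError("pulse_train drive requires a positive "
                                 "frequency")
            if not (0.0 < self.duty_cycle < 1.0):
                raise ValueError("duty_cycle must lie in (0, 1)")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass
class SimOutput:
    """Simulated ensemble: traces plus ground truth.

    traces are bundle positions (nm, n_cells x n_samples at fs);
    membrane_trace is the rigid-plate position (nm; NaN-free zeros when no
    cell is attached); drive_waveform is s(t) sampled at fs;
    true_coupling marks the cells attached to the plate.
    """

    traces: np.ndarray
    membrane_trace: np.ndarray
    drive_waveform: np.ndarray
    true_coupling: np.ndarray
    seed: int
    fs: float
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.traces.shape[1]) / self.fs


def default_params(n_cells: int, seed: int,
                   freq_range_hz: Tuple[float, float] = (10.0, 30.0),
                   **overrides) -> List[OscillatorParams]:
    """Heterogeneous default ensemble: natural frequencies drawn uniformly
    from freq_range_hz (the typical spontaneous range of saccular
    bundles), other parameters at their defaults."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFE11]))
    freqs = rng.uniform(freq_range_hz[0], freq_range_hz[1], size=n_cells)
    return [OscillatorParams(natural_frequency_target=float(f), **overrides)
            for f in freqs]


def efferent_waveform(drive: EfferentDrive, t_grid: np.ndarray,
                      protocol: StimulusProtocol = StimulusProtocol(),
                      ) -> np.ndarray:
    """Drive series s(t) on a uniform time grid covering the protocol.

    Zero outside the during-window. A step holds `intensity` throughout the
    window; a pulse train is a square wave at the drive frequency with the
    configured duty cycle (low level 0, high level `intensity`), phase-
    locked to stimulus onset.
    """
    t = np.asarray(t_grid, dtype=float)
    s = np.zeros_like(t)
    if drive.kind == "none" or drive.intensity == 0.0:
        return s
    on = protocol.pre_s
    off = protocol.pre_s + protocol.during_s
    inside = (t >= on) & (t < off)
    if drive.kind == "step":
        s[inside] = drive.intensity
    else:
        phase = (t[inside] - on) * drive.frequency
        frac = phase - np.floor(phase)
        s[inside] = np.where(frac < drive.duty_cycle, drive.intensity, 0.0)
    return s


def _membrane_position(x: np.ndarray, k: np.ndarray) -> float | np.ndarray:
    ktot = k.sum()
    if ktot == 0.0:
        return 0.0
    return (k * x).sum(axis=-1) / ktot


@njit(cache=True)
def _integrate_chunk(x, f, noise, s_chunk, a, eps, scale, c, sig, tau_m, k,
                     g_s, g_f, g_x, dt, sqdt, oversample, step0, traces,
                     membrane):
    """Euler-Maruyama steps over one noise chunk, recording decimated
    samples in place. Returns the global step index after the chunk."""
    m = noise.shape[0]
    n = x.size
    ktot = 0.0
    for i in range(n):
        ktot += k[i]
    for j in range(m):
        if ktot > 0.0:
            xm = 0.0
            for i in range(n):
                xm += k[i] * x[i]
            xm /= ktot
        else:
            xm = 0.0
        s_now = s_chunk[j]
        for i in range(n):
            dx = (-x[i] ** 3 + a[i] * x[i] - f[i]
                  + k[i] * (xm - x[i]) + g_x * s_now) / tau_m[i]
            df = eps[i] * (1.0 + g_f * s_now) * (x[i] - c[i] - g_s * s_now)
            x[i] = x[i] + dx * dt + sig[i] * noise[j, i] * sqdt
            f[i] = f[i] + df * dt
        step = step0 + j + 1
        if step % oversample == 0:
            i_out = step // oversample - 1
            xm2 = 0.0
            for i in range(n):
                traces[i, i_out] = x[i] * scale[i]
                xm2 += k[i] * x[i] * scale[i]
            membrane[i_out] = xm2 / ktot if ktot > 0.0 else 0.0
    return step0 + m


def simulate_bundles(params: Sequence[OscillatorParams],
                     coupling: CouplingConfig,
                     drive: EfferentDrive,
                     fs: float,
                     duration: float,
                     seed: int,
                     protocol: Optional[StimulusProtocol] = None,
                     internal_rate_hz: float = 10_000.0) -> SimOutput:
    """Integrate the coupled ensemble and return traces at the frame rate.

    Euler-Maruyama at >= internal_rate_hz (an integer multiple of fs),
    decimated to fs by striding. The protocol defaults to 10/10/10 s when
    the duration allows, otherwise to an all-pre window (no stimulus
    epochs). Aborts with a diagnostic if any state goes non-finite.
    """
    n_cells = len(params)
    if n_cells != coupling.n_cells:
        raise ValueError("params and coupling disagree on the cell count")
    if fs < 400:
        raise ValueError("fs must be >= 400 frames/s")
    if protocol is None:
        if duration >= StimulusProtocol().total_s:
            protocol = StimulusProtocol()
        else:
            protocol = StimulusProtocol(pre_s=duration, during_s=0.0,
                                        post_s=0.0)
    oversample = max(1, int(np.ceil(internal_rate_hz / fs)))
    dt = 1.0 / (fs * oversample)
    n_out = int(round(duration * fs))
    n_steps = n_out * oversample

    a = np.array([p.stiffness_scale for p in params])
    eps = np.array([p.effective_adaptation_rate for p in params])
    scale = np.array([p.position_scale for p in params])
    c = np.array([p.spike_offset for p in params]) / scale
    sig = np.array([p.noise_intensity for p in params]) / scale
    tau_m = np.array([p.fast_timescale_s for p in params])
    k = np.array(coupling.spring_constant, dtype=float)
    attached = np.array(coupling.attachment, dtype=bool)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51D]))
    # deterministic, seed-dependent initial conditions on either branch
    x = np.where(rng.random(n_cells) < 0.5, -1.0, 1.0) * np.sqrt(a)
    f = rng.normal(0.0, 0.05, n_cells)

    t_int = (np.arange(n_steps) + 1) * dt
    s_int = efferent_waveform(drive, t_int, protocol)
    g_s = drive.gain_setpoint
    g_f = drive.gain_frequency
    g_x = drive.gain_force

    traces = np.empty((n_cells, n_out))
    membrane = np.empty(n_out)
    sqdt = np.sqrt(dt)
    chunk = 50_000
    step = 0
    while step < n_steps:
        m = min(chunk, n_steps - step)
        noise = rng.standard_normal((m, n_cells))
        step = _integrate_chunk(x, f, noise, s_int[step: step + m],
                                a, eps, scale, c, sig, tau_m, k,
                                g_s, g_f, g_x, dt, sqdt, oversample, step,
                                traces, membrane)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(f))):
            bad = int(np.nonzero(~(np.isfinite(x) & np.isfinite(f)))[0][0])
            raise FloatingPointError(
                f"simulation diverged: cell {bad} non-finite near "
                f"t={step * dt:.4f} s (check parameter magnitudes)")

    t_out = (np.arange(n_out) + 1) / fs
    s_out = efferent_waveform(drive, t_out, protocol)
    if not coupling.any_attached:
        membrane[:] = 0.0
    return SimOutput(traces=traces, membrane_trace=membrane,
                     drive_waveform=s_out, true_coupling=attached,
                     seed=int(seed), fs=float(fs), protocol=protocol)


def null_ensemble(n_pairs: int, fs: float, duration: float,
                  seed: int, **param_overrides) -> np.ndarray:
    """Mutually independent (uncoupled) traces for threshold calibration.

    Simulates the smallest ensemble whose pair count m(m-1)/2 reaches
    n_pairs with every spring constant zero, so traces share no mechanical
    path and are driven by independent noise streams. Returns the
    (m, n_samples) trace array.
    """
    if n_pairs < 100:
        raise ValueError("need >= 100 pairs for a meaningful null")
    m = int(np.ceil((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    params = default_params(m, seed, **param_overrides)
    coupling = CouplingConfig.uniform(m, k=0.0,
                                      attached=[False] * m)
    out = simulate_bundles(params, coupling, EfferentDrive(), fs=fs,
                           duration=duration, seed=seed,
                           protocol=StimulusProtocol(duration, 0.0, 0.0))
    return out.traces


def render_frames(traces_nm: np.ndarray,
                  rest_positions_px: np.ndarray,
                  axis_angle_deg: float = 0.0,
                  spot_width_px: float = 2.0,
                  nm_per_px: float = 108.3,
                  photon_noise_level: float = 0.0,
                  frame_shape: Tuple[int, int] = (64, 64),
                  peak_counts: float = 1000.0,
                  seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Render an image stack of Gaussian spots moving along a common axis.

    Each cell contributes an isotropic Gaussian spot centered at its rest
    position plus its trace (nm -> px) projected along axis_angle_deg
    (0 deg = +column direction; row = -sin, col = +cos so that angles are
    measured counterclockwise in conventional x/y). photon_noise_level > 0
    applies Poisson counting noise to intensities scaled so the spot peak
    is peak_counts / photon_noise_level (SNR at the peak roughly
    sqrt(peak)); 0 renders noiseless frames.

    Returns (stack float64 (n_frames, rows, cols), truth centers
    (n_frames, n_cells, 2) in row/col px).
    """
    traces_nm = np.atleast_2d(np.asarray(traces_nm, dtype=float))
    rest = np.atleast_2d(np.asarray(rest_positions_px, dtype=float))
    n_cells, n_frames = traces_nm.shape
    if rest.shape != (n_cells, 2):
        raise ValueError("rest_positions_px must be (n_cells, 2) row/col")
    rows, cols = frame_shape
    theta = np.deg2rad(axis_angle_deg)
    direction = np.array([-np.sin(theta), np.cos(theta)])  # row, col
    disp_px = traces_nm / nm_per_px
    centers = rest[None, :, :] + disp_px.T[:, :, None] * direction[None, None, :]

    margin = 3.0 * spot_width_px
    bad = np.nonzero((centers[..., 0] < margin) |
                     (centers[..., 0] > rows - 1 - margin) |
                     (centers[..., 1] < margin) |
                     (centers[..., 1] > cols - 1 - margin))
    if bad[0].size:
        fr, cell = int(bad[0][0]), int(bad[1][0])
        raise ValueError(f"spot of cell {cell} leaves the frame at frame "
                         f"{fr} (center {centers[fr, cell]})")

    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    stack = np.zeros((n_frames, rows, cols))
    inv2s2 = 1.0 / (2.0 * spot_width_px ** 2)
    for t in range(n_frames):
        frame = np.zeros((rows, cols))
        for i in range(n_cells):
            r0, c0 = centers[t, i]
            frame += peak_counts * np.exp(-((rr - r0) ** 2 +
                                            (cc - c0) ** 2) * inv2s2)
        stack[t] = frame
    if photon_noise_level > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed),
                                                            0xF0F0]))
        scaled = stack / photon_noise_level
        stack = rng.poisson(scaled).astype(float) * photon_noise_level
    return stack, centers
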