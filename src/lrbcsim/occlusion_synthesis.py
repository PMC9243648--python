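"""Synthetic dual-wavelength reflectometer recordings for occlusion studies.

Emulates a two-LED lock-in reflectometer: the 590 and 780 nm channels are
sinusoidal carriers (1100 and 1000 Hz) amplitude-modulated by slowly
varying intensity envelopes, sampled at 50 k-samples/s, with additive
white Gaussian noise proportional to the local envelope.  A venous
occlusion drives the envelopes: constant during baseline, falling during
cuff inflation — by about 25% at 590 nm and about 3% at 780 nm, since
hemoglobin absorbs strongly at 590 nm and weakly at 780 nm — and
recovering exponentially after release.  Monophasic scenarios ramp down
linearly; biphasic scenarios take an initial step (a fraction of the
total drop) followed by a ramp, mimicking the near-vertical initial jump
seen in a subset of occlusion tests.

Demodulation is a software lock-in: windowed in-phase/quadrature products
with the carrier references.  The default 1000-sample window at 50 kHz is
20 ms — exactly 22 cycles of 1100 Hz and 20 cycles of 1000 Hz — so the
two carriers are orthogonal over every window and inter-channel
cross-talk vanishes to numerical precision.  Output rate: 50 samples/s.

The generating envelopes are retained on the recording so estimator
recovery can be checked against exact ground truth.  An inverse-first
constructor is provided: given a target LRBC trajectory and constants,
the implied 590 nm envelope is computed by inverting the voltage-mode
estimator with the 780 nm envelope prescribed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lrbc_core import LrbcConstants

SAMPLE_RATE = 50_000
F_590 = 1100.0
F_780 = 1000.0


@dataclass(frozen=True)
class OcclusionScenario:
    """Parameters of a synthetic venous-occlusion recording.

    Durations in seconds; drops are fractional intensity decreases at the
    end of the occlusion phase relative to baseline; ``noise_sd`` is the
    white-noise standard deviation relative to the local envelope.
    """

    baseline_duration: float = 180.0
    occlusion_duration: float = 180.0
    release_duration: float = 180.0
    drop_590: float = 0.25
    drop_780: float = 0.03
    shape: str = "monophasic"
    biphasic_jump_fraction: float = 0.4
    recovery_time_constant: float = 10.0
    noise_sd: float = 0.01
    seed: int = 0
    amplitude_590: float = 1.0
    amplitude_780: float = 1.0
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        for nm in ("baseline_duration", "occlusion_duration", "release_duration"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be positive")
        for nm in ("drop_590", "drop_780"):
            if not 0.0 <= getattr(self, nm) < 1.0:
                raise ValueError(f"{nm} must be in [0, 1)")
        if not 0.0 <= self.biphasic_jump_fraction <= 1.0:
            raise ValueError("biphasic_jump_fraction must be in [0, 1]")
        if self.shape not in ("monophasic", "biphasic"):
            raise ValueError("shape must be 'monophasic' or 'biphasic'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.recovery_time_constant <= 0:
            raise ValueError("recovery_time_constant must be positive")

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + self.occlusion_duration + self.release_duration

    @property
    def inflation_time(self) -> float:
        """Start of cuff inflation (t = 0 of the occlusion clock), s."""
        return self.baseline_duration

    def envelope(self, t: np.ndarray, amplitude: float, drop: float) -> np.ndarray:
        """Intensity envelope of one channel over absolute time ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        t_occ = self.baseline_duration
        t_rel = t_occ + self.occlusion_duration
        env = np.full(t.shape, amplitude)
        occ = (t >= t_occ) & (t < t_rel)
        frac = (t[occ] - t_occ) / self.occlusion_duration
        if self.shape == "monophasic":
            env[occ] = amplitude * (1.0 - drop * frac)
        else:
            jump = self.biphasic_jump_fraction * drop
            env[occ] = amplitude * (1.0 - jump - (drop - jump) * frac)
        rel = t >= t_rel
        end_val = amplitude * (1.0 - drop)
        env[rel] = amplitude + (end_val - amplitude) * np.exp(
            -(t[rel] - t_rel) / self.recovery_time_constant)
        return env

    def phase_labels(self, t: np.ndarray) -> np.ndarray:
        """'baseline' / 'occlusion' / 'release' label per time point."""
        t = np.asarray(t, dtype=float)
        labels = np.where(t < self.baseline_duration, "baseline",
                          np.where(t < self.baseline_duration + self.occlusion_duration,
                                   "occlusion", "release"))
        return labels


@dataclass
class ReflectometryRecording:
    """Raw modulated two-channel recording plus carrier references."""

    time: np.ndarray
    channel_590: np.ndarray
    channel_780: np.ndarray
    ref_590: np.ndarray
    ref_780: np.ndarray
    sample_rate: int = SAMPLE_RATE
    f_590: float = F_590
    f_780: float = F_780
    true_envelope_590: np.ndarray | None = None
    true_envelope_780: np.ndarray | None = None
    scenario: OcclusionScenario | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for ch in (self.channel_590, self.channel_780, self.ref_590, self.ref_780):
            if len(ch) != n:
                raise ValueError("all waveforms must share one time base")


@dataclass
class DemodulatedSeries:
    """Lock-in envelope amplitudes at the demodulated rate (50 S/s default)."""

    time: np.ndarray
    ve_590: np.ndarray
    ve_780: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.ve_590) == len(self.ve_780)):
            raise ValueError("demodulated channels must share one time base")


def _assemble(time, env590, env780, sample_rate, noise_sd, seed, scenario=None):
    rng = np.random.default_rng(seed)
    ref590 = np.sin(2 * np.pi * F_590 * time)
    ref780 = np.sin(2 * np.pi * F_780 * time)
    ch590 = env590 * ref590
    ch780 = env780 * ref780
    if noise_sd > 0:
        ch590 = ch590 + rng.normal(0.0, noise_sd * env590)
        ch780 = ch780 + rng.normal(0.0, noise_sd * env780)
    return ReflectometryRecording(
        time=time, channel_590=ch590, channel_780=ch780,
        ref_590=ref590, ref_780=ref780, sample_rate=sample_rate,
        true_envelope_590=env590, true_envelope_780=env780, scenario=scenario,
    )


def generate_recording(scenario: OcclusionScenario) -> ReflectometryRecording:
    """Synthesize a modulated two-channel recording for a scenario.

    Each channel is ``envelope(t) * sin(2*pi*f*t)`` plus white Gaussian
    noise of standard deviation ``noise_sd * envelope(t)``; deterministic
    per scenario seed.
    """
    n = int(round(scenario.total_duration * scenario.sample_rate))
    time = np.arange(n) / scenario.sample_rate
    env590 = scenario.envelope(time, scenario.amplitude_590, scenario.drop_590)
    env780 = scenario.envelope(time, scenario.amplitude_780, scenario.drop_780)
    return _assemble(time, env590, env780, scenario.sample_rate,
                     scenario.noise_sd, scenario.seed, scenario)


def recording_from_envelopes(time: np.ndarray, env590: np.ndarray,
                             env780: np.ndarray, noise_sd: float = 0.0,
                             seed: int = 0,
                             sample_rate: int = SAMPLE_RATE) -> ReflectometryRecording:
    """Build a recording from arbitrary per-sample intensity envelopes."""
    return _assemble(np.asarray(time, float), np.asarray(env590, float),
                     np.asarray(env780, float), sample_rate, noise_sd, seed)


def envelopes_from_lrbc(lrbc_um: np.ndarray, env780: np.ndarray,
                        constants: LrbcConstants | None = None) -> np.ndarray:
    """Inverse-first generation: the 590 nm envelope implied by a target LRBC.

    Inverts the voltage-mode estimator sample-by-sample with the 780 nm
    envelope prescribed:  ln Ve(590) = ln v0_ratio + ln Ve(780) -
    LRBC[mm] * (PF(590)*mueff(590) - RPF*mueff(780)).  Feeding the result
    through modulation, lock-in demodulation and the estimator returns
    the target trajectory exactly (up to noise), giving recovery tests an
    exact ground truth.
    """
    if constants is None:
        constants = LrbcConstants()
    lrbc_mm = np.asarray(lrbc_um, float) / 1e3
    return np.exp(math.log(constants.v0_ratio) + np.log(np.asarray(env780, float))
                  - lrbc_mm * constants.denominator)


def lock_in_demodulate(recording: ReflectometryRecording,
                       window_length: int = 1000) -> DemodulatedSeries:
    """Software lock-in: windowed quadrature demodulation of both channels.

    Per window and channel, amplitude = 2*sqrt(<x*sin>^2 + <x*cos>^2)
    with the in-phase/quadrature references at the channel's carrier
    frequency and <.> the window mean.  The window must hold an integer
    number of samples of the recording and an integer number of periods
    of both carriers (orthogonality); the default 1000 samples at
    50 kHz satisfies both.
    """
    n = len(recording.time)
    if n % window_length != 0:
        raise ValueError("window_length must divide the recording length")
    for f in (recording.f_590, recording.f_780):
        cycles = f * window_length / recording.sample_rate
        if abs(cycles - round(cycles)) > 1e-9:
            raise ValueError(
                f"window of {window_length} samples is not an integer number of "
                f"periods of the {f} Hz carrier")
    n_win = n // window_length
    tw = recording.time[:window_length]
    out = {}
    for tag, f in (("590", recording.f_590), ("780", recording.f_780)):
        # window starts are integer carrier periods, so one reference
        # window serves for all windows
        ip = np.sin(2 * np.pi * f * tw)
        quad = np.cos(2 * np.pi * f * tw)
        x = getattr(recording, f"channel_{tag}").reshape(n_win, window_length)
        out[tag] = 2.0 * np.hypot(x @ ip / window_length, x @ quad / window_length)
    t_out = recording.time.reshape(n_win, window_length).mean(axis=1)
    return DemodulatedSeries(time=t_out, ve_590=out["590"], ve_780=out["780"],
                             rate=recording.sample_rate / window_length)
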