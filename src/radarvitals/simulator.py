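"""Synthetic radar scenes with known cardiorespiratory ground truth.

No clinical recordings ship with this package, so every downstream stage
is exercised against a parametric phantom: chest-surface displacement is
composed of a slow respiratory excursion (millimetres), a pulse-wave
component (fractions of a millimetre) and short heart-sound wavelets
(tens of micrometres, 16-80 Hz).  The motion is then mapped onto the
complex radar baseband, optionally distorted by I/Q offset, gain
imbalance and rotation, and contaminated with noise calibrated in terms
of the displacement standard deviation an ideal demodulator would see on
a static target.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .signals import (
    CHANNEL_NAMES,
    WAVELENGTH_24GHZ,
    DisplacementTrace,
    QuadratureRecord,
)

__all__ = [
    "VitalMotionConfig",
    "ChannelConfig",
    "RadarScene",
    "synth_displacement",
    "synth_quadrature",
    "synth_reference",
    "make_scene",
    "fspl_two_way_db",
]


@dataclass
class VitalMotionConfig:
    """Parameters of the simulated chest motion.

    Defaults describe a healthy resting adult: breathing in the normal
    12-25 BrPM range with a chest excursion of several millimetres, a
    heart rate near 70 BPM, and heart-sound wavelets centred inside the
    16-80 Hz observation band.

    Attributes
    ----------
    respiration_rate : float
        Mean breathing rate in BrPM; must lie in the 3-30 BrPM band the
        respiration filters pass.
    respiration_amplitude_mm : float
        Peak-to-peak chest excursion per breath in mm (typical 4-12).
    respiration_waveform : str
        ``"sinusoid"`` for analytic tests or ``"asymmetric"`` for a
        raised-cosine breath with a shorter inspiration than expiration.
    respiration_rate_jitter : float
        Fractional SD of per-breath cycle duration.
    respiration_amplitude_jitter : float
        Fractional SD of per-breath amplitude.
    apnea_intervals : sequence of (start_s, end_s)
        Respiratory motion is suppressed (with a short cosine taper)
        inside these intervals.
    body_motion_rms_um : float
        RMS of slow non-respiratory chest-surface motion (postural sway,
        vasomotion), band-limited to the respiration band.  Subjects are
        never perfectly still; 0.1-0.5 mm is typical at rest and the
        default sits in the upper part of that range.  The radar sees
        this motion but an impedance reference does not.
    heart_rate : float
        Mean heart rate in BPM.
    heart_rate_jitter : float
        Fractional SD of per-beat interval (physiological HRV ~ a few %).
    pulse_amplitude_mm : float
        Peak amplitude of the pulse-wave (sphygmogram) displacement.
        Not reported for this measurement geometry; defaults to 0.3 mm
        within the plausible 0.1-0.5 mm range and is fully configurable.
    pulse_transit_time_s, pulse_transit_jitter_s : float
        Mean delay of the surface pulse wave behind the heart sound and
        its per-beat SD.  The pulse wave is mechanically decoupled from
        the valve events, so its timing wanders a little even when the
        cardiac rhythm is steady.
    pulse_amplitude_jitter : float
        Fractional SD of per-beat pulse amplitude.
    s1_amplitude_um, s2_amplitude_um : float
        Peak amplitudes of the first/second heart-sound wavelets in µm.
    s1_s2_delay_s : float
        Delay from S1 centre to S2 centre (systolic interval).
    heartsound_center_frequency : float
        Carrier of the heart-sound wavelets in Hz, inside 16-80 Hz.
    heartsound_sigma_s : float
        Gaussian envelope SD of each wavelet in seconds.
    duration_s, sample_rate : float
        Record length and raw sampling rate (default 2000 Sa/s).
    """

    respiration_rate: float = 14.0
    respiration_amplitude_mm: float = 8.0
    respiration_waveform: str = "asymmetric"
    respiration_rate_jitter: float = 0.0
    respiration_amplitude_jitter: float = 0.0
    apnea_intervals: Sequence[Tuple[float, float]] = ()
    body_motion_rms_um: float = 400.0
    heart_rate: float = 70.0
    heart_rate_jitter: float = 0.0
    pulse_amplitude_mm: float = 0.3
    pulse_transit_time_s: float = 0.15
    pulse_transit_jitter_s: float = 0.010
    pulse_amplitude_jitter: float = 0.2
    s1_amplitude_um: float = 50.0
    s2_amplitude_um: float = 30.0
    s1_s2_delay_s: float = 0.30
    heartsound_center_frequency: float = 40.0
    heartsound_sigma_s: float = 0.012
    duration_s: float = 60.0
    sample_rate: float = 2000.0

    def validate(self) -> None:
        if not (3.0 <= self.respiration_rate <= 30.0):
            raise ValueError("respiration_rate must lie in [3, 30] BrPM")
        if not (0.0 < self.respiration_amplitude_mm <= 20.0):
            raise ValueError("respiration_amplitude_mm must lie in (0, 20] mm")
        if not (16.0 <= self.heartsound_center_frequency <= 80.0):
            raise ValueError("heartsound_center_frequency must lie in [16, 80] Hz")
        if self.sample_rate < 2 * 120.0:
            raise ValueError("sample_rate must be at least twice the 120 Hz analog band")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.respiration_waveform not in ("sinusoid", "asymmetric"):
            raise ValueError("respiration_waveform must be 'sinusoid' or 'asymmetric'")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        iv = sorted((float(a), float(b)) for a, b in self.apnea_intervals)
        for (a, b) in iv:
            if b <= a:
                raise ValueError(f"apnea interval ({a}, {b}) has non-positive length")
        for (_, b0), (a1, _) in zip(iv[:-1], iv[1:]):
            if a1 < b0:
                raise ValueError("apnea intervals overlap")


@dataclass
class ChannelConfig:
    """Radar channel model: carrier, I/Q distortions and noise level.

    ``noise_displacement_std_um`` calibrates the additive baseband noise
    so that ideal arctangent demodulation of a *static* target yields a
    displacement standard deviation of exactly this many micrometres
    (default 1.07 µm, the measured bench precision of the system class
    this simulator emulates).
    """

    wavelength: float = WAVELENGTH_24GHZ
    iq_offset: complex = 0.0 + 0.0j
    iq_gain_ratio: float = 1.0
    iq_rotation: float = 0.0
    amplitude: float = 1.0
    noise_displacement_std_um: float = 1.07
    common_mode_offsets: Tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    nonlinearity: float = 0.0  # optional periodic-in-phase gain ripple, default off

    def validate(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.iq_gain_ratio <= 0:
            raise ValueError("iq_gain_ratio must be positive")
        if self.noise_displacement_std_um < 0:
            raise ValueError("noise_displacement_std_um must be non-negative")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class RadarScene:
    """A complete synthetic recording with ground truth and references."""

    quadrature: QuadratureRecord
    truth: DisplacementTrace
    ecg_rpeaks: np.ndarray
    reference_respiration: DisplacementTrace
    seed: int


def _beat_times(cfg: VitalMotionConfig, rng: np.random.Generator) -> np.ndarray:
    """Beat (S1 centre) times covering the record, with per-beat jitter."""
    mean_ibi = 60.0 / cfg.heart_rate
    times: List[float] = []
    # first beat shortly after the start so edge beats stay in-record
    t = 0.5 * mean_ibi
    while t < cfg.duration_s:
        times.append(t)
        eps = float(np.clip(rng.standard_normal(), -3.0, 3.0)) if cfg.heart_rate_jitter else 0.0
        t += mean_ibi * (1.0 + cfg.heart_rate_jitter * eps)
    return np.asarray(times)


def _breath_cycles(cfg: VitalMotionConfig, rng: np.random.Generator) -> np.ndarray:
    """Breath cycle start times (first cycle starts at t=0)."""
    mean_T = 60.0 / cfg.respiration_rate
    starts = [0.0]
    while starts[-1] < cfg.duration_s:
        eps = float(np.clip(rng.standard_normal(), -3.0, 3.0)) if cfg.respiration_rate_jitter else 0.0
        starts.append(starts[-1] + mean_T * (1.0 + cfg.respiration_rate_jitter * eps))
    return np.asarray(starts)


def _respiration_component(
    cfg: VitalMotionConfig, t: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Respiratory displacement in µm and the breath-cycle start times."""
    starts = _breath_cycles(cfg, rng)
    amp_um = cfg.respiration_amplitude_mm * 1000.0
    x = np.zeros_like(t)
    insp_frac = 0.4  # inspiration is the shorter, active phase
    for k in range(len(starts) - 1):
        t0, t1 = starts[k], starts[k + 1]
        T = t1 - t0
        sel = (t >= t0) & (t < t1)
        tau = t[sel] - t0
        if cfg.respiration_waveform == "sinusoid":
            shape = 0.5 - 0.5 * np.cos(2 * np.pi * tau / T)
        else:
            ti = insp_frac * T
            shape = np.where(
                tau < ti,
                0.5 - 0.5 * np.cos(np.pi * tau / ti),
                0.5 + 0.5 * np.cos(np.pi * (tau - ti) / (T - ti)),
            )
        a = amp_um
        if cfg.respiration_amplitude_jitter:
            a *= 1.0 + cfg.respiration_amplitude_jitter * float(
                np.clip(rng.standard_normal(), -3.0, 3.0)
            )
        x[sel] = a * shape
    # suppress breathing inside apnea intervals with a short cosine taper
    taper = 0.25
    for (a0, b0) in cfg.apnea_intervals:
        gate = np.ones_like(t)
        gate[(t >= a0) & (t <= b0)] = 0.0
        ramp_in = (t > a0 - taper) & (t < a0)
        gate[ramp_in] = 0.5 + 0.5 * np.cos(np.pi * (t[ramp_in] - (a0 - taper)) / taper)
        ramp_out = (t > b0) & (t < b0 + taper)
        gate[ramp_out] = 0.5 - 0.5 * np.cos(np.pi * (t[ramp_out] - b0) / taper)
        x *= gate
    return x, starts


def _gauss_wavelet(t: np.ndarray, center: float, amp_um: float, f0: float, sigma: float) -> np.ndarray:
    tau = t - center
    return amp_um * np.exp(-0.5 * (tau / sigma) ** 2) * np.cos(2 * np.pi * f0 * tau)


def synth_displacement(cfg: VitalMotionConfig, seed: int = 0) -> DisplacementTrace:
    """Generate the ground-truth chest displacement for a scene.

    The trace is the sum of the respiratory excursion, a pulse-wave bump
    trailing each beat, and one S1 and one S2 heart-sound wavelet per
    cardiac cycle (S2 delayed by ``s1_s2_delay_s``).  Component arrays,
    beat times and breath-cycle starts are stored in ``meta`` so tests
    and references can use them as ground truth.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_s * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate

    resp, breath_starts = _respiration_component(cfg, t, rng)
    # non-respiratory body motion: seen by the radar, absent from the
    # impedance reference, present even during apnea
    sway = np.zeros_like(t)
    if cfg.body_motion_rms_um > 0:
        from scipy import signal as sps

        sos = sps.butter(2, [0.05, 0.5], btype="bandpass", fs=cfg.sample_rate, output="sos")
        sway = sps.sosfilt(sos, rng.standard_normal(n))
        sd = sway.std()
        sway = cfg.body_motion_rms_um * sway / sd if sd > 0 else sway

    beats = _beat_times(cfg, rng)
    pulse = np.zeros_like(t)
    heart = np.zeros_like(t)
    pulse_amp_um = cfg.pulse_amplitude_mm * 1000.0
    for tb in beats:
        # pulse wave: smooth bump trailing the beat by the transit time,
        # ~80 ms wide, with per-beat timing and amplitude variability
        transit = cfg.pulse_transit_time_s
        amp = pulse_amp_um
        if cfg.pulse_transit_jitter_s:
            transit += cfg.pulse_transit_jitter_s * float(
                np.clip(rng.standard_normal(), -3.0, 3.0)
            )
        if cfg.pulse_amplitude_jitter:
            amp *= 1.0 + cfg.pulse_amplitude_jitter * float(
                np.clip(rng.standard_normal(), -3.0, 3.0)
            )
        pulse += amp * np.exp(-0.5 * ((t - tb - transit) / 0.08) ** 2)
        heart += _gauss_wavelet(
            t, tb, cfg.s1_amplitude_um, cfg.heartsound_center_frequency, cfg.heartsound_sigma_s
        )
        heart += _gauss_wavelet(
            t,
            tb + cfg.s1_s2_delay_s,
            cfg.s2_amplitude_um,
            cfg.heartsound_center_frequency,
            cfg.heartsound_sigma_s,
        )

    total = resp + sway + pulse + heart
    return DisplacementTrace(
        displacement_um=total,
        sample_rate=cfg.sample_rate,
        wavelength_used=None,
        meta={
            "respiration_um": resp,
            "sway_um": sway,
            "pulse_um": pulse,
            "heartsound_um": heart,
            "beat_times": beats,
            "s1_centers": beats.copy(),
            "s2_centers": beats + cfg.s1_s2_delay_s,
            "breath_cycle_starts": breath_starts,
            "config": cfg,
            "seed": seed,
        },
    )


def synth_quadrature(
    truth: DisplacementTrace, ch: ChannelConfig, seed: int = 0
) -> QuadratureRecord:
    """Map a displacement trace onto distorted, noisy detector voltages.

    The ideal baseband sample is ``A * exp(j * 4π d(t) / λ)``.  The unit
    circle is distorted into an ellipse by the quadrature gain ratio and
    rotation and shifted by the complex offset (antenna cross-talk).
    Complex white noise is added with a per-quadrature SD of
    ``A * 4π σ_d / λ`` so that an ideal demodulator applied to a static
    target reproduces ``noise_displacement_std_um``.
    """
    ch.validate()
    if truth.n == 0:
        raise ValueError("truth displacement is empty")
    rng = np.random.default_rng(seed)
    d_m = truth.displacement_um * 1e-6
    phi = 4.0 * np.pi * d_m / ch.wavelength
    z = ch.amplitude * np.exp(1j * phi)
    if ch.nonlinearity:
        z *= 1.0 + ch.nonlinearity * np.cos(2.0 * phi)
    # ellipse distortion: gain imbalance on Q, then rotation, then offset
    z = z.real + 1j * ch.iq_gain_ratio * z.imag
    z = z * np.exp(1j * ch.iq_rotation)
    z = z + ch.iq_offset
    if ch.noise_displacement_std_um > 0:
        sigma_phi = 4.0 * np.pi * (ch.noise_displacement_std_um * 1e-6) / ch.wavelength
        s = ch.amplitude * sigma_phi
        z = z + s * (rng.standard_normal(z.size) + 1j * rng.standard_normal(z.size))

    off = ch.common_mode_offsets
    channels = {
        "B3": off[0] + 0.5 * z.imag,
        "B4": off[1] - 0.5 * z.imag,
        "B5": off[2] + 0.5 * z.real,
        "B6": off[3] - 0.5 * z.real,
    }
    return QuadratureRecord(
        sample_rate=truth.sample_rate,
        iq=z,
        channels=channels,
        wavelength=ch.wavelength,
        meta={"seed": seed, "channel_config": ch},
    )


def synth_reference(
    truth: DisplacementTrace,
    lag_s: float = 0.147,
    seed: int = 0,
    rpeak_delay_s: float = 0.040,
    rpeak_jitter_s: float = 0.0,
    reference_rate: float = 100.0,
    scale: float = 0.8,
    noise_frac: float = 0.02,
) -> Tuple[np.ndarray, DisplacementTrace]:
    """Emulate the gold-standard annotations for a synthetic scene.

    R-peak times precede each S1 wavelet centre by the electromechanical
    delay ``rpeak_delay_s`` (default 40 ms).  The reference respiration
    waveform is the truth respiration component sampled at
    ``reference_rate``, delayed by ``lag_s`` (positive = reference lags
    the radar), rescaled (it stands for a different physical quantity,
    transthoracic impedance) and lightly noised.
    """
    if abs(lag_s) >= truth.duration:
        raise ValueError("|lag_s| must be smaller than the record duration")
    if "s1_centers" not in truth.meta:
        raise ValueError("truth trace lacks simulator ground-truth metadata")
    rng = np.random.default_rng(seed)

    s1 = np.asarray(truth.meta["s1_centers"])
    rpeaks = s1 - rpeak_delay_s
    if rpeak_jitter_s:
        rpeaks = rpeaks + rpeak_jitter_s * rng.standard_normal(rpeaks.size)
    rpeaks = np.sort(rpeaks[rpeaks >= 0.0])

    resp = np.asarray(truth.meta["respiration_um"], dtype=float)
    t_src = truth.times
    n_ref = int(round(truth.duration * reference_rate))
    t_ref = np.arange(n_ref) / reference_rate
    shifted = np.interp(t_ref - lag_s, t_src, resp)
    ref = scale * (shifted - shifted.mean())
    if noise_frac:
        sd = ref.std()
        if sd > 0:
            ref = ref + noise_frac * sd * rng.standard_normal(ref.size)
    ref_trace = DisplacementTrace(
        displacement_um=ref,
        sample_rate=reference_rate,
        meta={"lag_s": lag_s, "scale": scale, "units": "a.u.", "seed": seed},
    )
    return rpeaks, ref_trace


def make_scene(
    motion: Optional[VitalMotionConfig] = None,
    channel: Optional[ChannelConfig] = None,
    seed: int = 0,
    reference_lag_s: float = 0.147,
) -> RadarScene:
    """Convenience constructor tying the three generators together."""
    motion = motion or VitalMotionConfig()
    channel = channel or ChannelConfig()
    ss = np.random.SeedSequence(seed)
    s_motion, s_chan, s_ref = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    truth = synth_displacement(motion, seed=s_motion)
    quad = synth_quadrature(truth, channel, seed=s_chan)
    rpeaks, ref = synth_reference(truth, lag_s=reference_lag_s, seed=s_ref)
    return RadarScene(
        quadrature=quad,
        truth=truth,
        ecg_rpeaks=rpeaks,
        reference_respiration=ref,
        seed=seed,
    )


def fspl_two_way_db(distance_m: float, frequency_hz: float) -> float:
    """Two-way free-space attenuation for an ideally reflective target.

    Under the mirror-image model a perfectly reflective plate at range
    ``d`` behaves like a transmitter at range ``2 d``, so the round-trip
    loss is the one-way free-space path loss evaluated at twice the
    distance:  ``20 log10(4π (2 d) f / c)`` in dB.
    """
    from scipy.constants import c

    if distance_m <= 0:
        raise ValueError("distance_m must be positive")
    if frequency_hz <= 0:
        raise ValueError("frequency_hz must be positive")
    return 20.0 * np.log10(4.0 * np.pi * (2.0 * distance_m) * frequency_hz / c)
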