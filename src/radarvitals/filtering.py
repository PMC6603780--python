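"""Band-splitting of the displacement signal.

The reconstructed chest displacement superimposes phenomena living in
well-separated bands:

* respiration: lowpass at 0.5 Hz (apnea stays visible) and bandpass
  0.05-0.5 Hz (3-30 BrPM) for rate estimation, both on a 100 Sa/s
  decimated copy,
* heart sounds: bandpass 16-80 Hz at the raw rate,
* sphygmogram (pulse wave): bandpass, default 0.75-5 Hz.  No reference
  band exists for this quantity in the measurement literature we follow;
  the default is a package choice and fully configurable.

All filters are fourth-order Butterworth designs stored as second-order
sections.  Offline application is zero-phase (forward-backward) by
default so that beat and breath timing is not skewed by group delay; a
causal mode exists for streaming parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from .signals import DisplacementTrace

__all__ = [
    "FilterSpec",
    "BandConfig",
    "BandSignals",
    "design_butterworth",
    "apply_filter",
    "decimate_to",
    "extract_bands",
]


@dataclass
class FilterSpec:
    """Butterworth filter specification.

    ``kind`` is ``"lowpass"`` or ``"bandpass"``; ``cutoffs`` holds one
    or two corner frequencies in Hz; ``application`` selects zero-phase
    (``filtfilt``) or causal application.
    """

    kind: str
    cutoffs: Tuple[float, ...]
    order: int = 4
    application: str = "zero-phase"

    def validate(self, sample_rate: float) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise ValueError("kind must be 'lowpass' or 'bandpass'")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.application not in ("zero-phase", "causal"):
            raise ValueError("application must be 'zero-phase' or 'causal'")
        nyq = sample_rate / 2.0
        cuts = tuple(self.cutoffs)
        if self.kind == "lowpass" and len(cuts) != 1:
            raise ValueError("lowpass needs exactly one cutoff")
        if self.kind == "bandpass":
            if len(cuts) != 2:
                raise ValueError("bandpass needs exactly two cutoffs")
            if not (0 < cuts[0] < cuts[1]):
                raise ValueError("cutoffs must satisfy 0 < low < high")
        if any(c <= 0 or c >= nyq for c in cuts):
            raise ValueError(f"cutoffs {cuts} must lie strictly inside (0, {nyq}) Hz")


def design_butterworth(spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Return second-order-section coefficients for the spec.

    SOS form keeps the 0.05 Hz corner numerically stable even at
    unfavourable cutoff/rate ratios.
    """
    spec.validate(sample_rate)
    btype = "lowpass" if spec.kind == "lowpass" else "bandpass"
    wn = spec.cutoffs[0] if spec.kind == "lowpass" else list(spec.cutoffs)
    return sps.butter(spec.order, wn, btype=btype, fs=sample_rate, output="sos")


def apply_filter(
    sos: np.ndarray,
    x: np.ndarray,
    zero_phase: bool = True,
    padlen: Optional[int] = None,
) -> np.ndarray:
    """Apply an SOS filter forward-backward (default) or causally.

    ``padlen`` controls the forward-backward edge padding; the scipy
    default is far too short for corners like 0.05 Hz, whose impulse
    response spans tens of seconds, so band extraction passes a pad of
    a few corner time constants.
    """
    if zero_phase:
        if padlen is not None:
            padlen = min(padlen, x.size - 1)
        return sps.sosfiltfilt(sos, x, padlen=padlen)
    return sps.sosfilt(sos, x)


def decimate_to(trace: DisplacementTrace, target_rate: float) -> DisplacementTrace:
    """Anti-aliased rational-rate resampling of a displacement trace."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == trace.sample_rate:
        return trace
    frac = Fraction(target_rate / trace.sample_rate).limit_denominator(10000)
    # linear-extension padding: zero padding would turn the record's DC
    # offset into an edge step that rings through the slow filters
    y = sps.resample_poly(
        trace.displacement_um, frac.numerator, frac.denominator, padtype="line"
    )
    return DisplacementTrace(
        displacement_um=y,
        sample_rate=trace.sample_rate * frac.numerator / frac.denominator,
        wavelength_used=trace.wavelength_used,
        meta={**trace.meta, "decimated_from": trace.sample_rate},
    )


@dataclass
class BandConfig:
    """Cutoffs and rates of the four analysis bands."""

    respiration_lowpass_hz: float = 0.5
    respiration_band_hz: Tuple[float, float] = (0.05, 0.5)
    heartsound_band_hz: Tuple[float, float] = (16.0, 80.0)
    sphygmogram_band_hz: Tuple[float, float] = (0.75, 5.0)
    order: int = 4
    respiration_rate: float = 100.0
    zero_phase: bool = True


@dataclass
class BandSignals:
    """The four band-limited views of one displacement record."""

    respiration_lp: DisplacementTrace
    respiration_bp: DisplacementTrace
    heartsound: DisplacementTrace
    sphygmogram: DisplacementTrace
    edge_warning: bool = False


def extract_bands(d: DisplacementTrace, config: Optional[BandConfig] = None) -> BandSignals:
    """Split a raw-rate displacement trace into the four bands.

    The respiration and sphygmogram paths are decimated to
    ``config.respiration_rate`` (default 100 Sa/s) before filtering; the
    heart-sound band stays at the raw rate, which must support it
    (>= 160 Sa/s).  Records shorter than about three time constants of
    the slowest (0.05 Hz) corner are flagged with ``edge_warning``
    because edge transients dominate.
    """
    cfg = config or BandConfig()
    if d.sample_rate < 2 * cfg.heartsound_band_hz[1]:
        raise ValueError(
            f"raw rate {d.sample_rate} Sa/s cannot support the "
            f"{cfg.heartsound_band_hz} Hz heart-sound band"
        )
    zp = cfg.zero_phase
    low = decimate_to(d, cfg.respiration_rate)
    # a bandpass removes DC in steady state anyway; removing it up front
    # keeps the record's (arbitrary) displacement origin from exciting
    # the slow corners' edge transients
    low_ac = low.displacement_um - low.displacement_um.mean()
    raw_ac = d.displacement_um - d.displacement_um.mean()

    lp_sos = design_butterworth(
        FilterSpec("lowpass", (cfg.respiration_lowpass_hz,), cfg.order), low.sample_rate
    )
    bp_sos = design_butterworth(
        FilterSpec("bandpass", cfg.respiration_band_hz, cfg.order), low.sample_rate
    )
    hs_sos = design_butterworth(
        FilterSpec("bandpass", cfg.heartsound_band_hz, cfg.order), d.sample_rate
    )
    sp_sos = design_butterworth(
        FilterSpec("bandpass", cfg.sphygmogram_band_hz, cfg.order), low.sample_rate
    )

    def mk(x: np.ndarray, rate: float, band: str, cutoffs) -> DisplacementTrace:
        return DisplacementTrace(
            displacement_um=x,
            sample_rate=rate,
            wavelength_used=d.wavelength_used,
            meta={"band": band, "cutoffs_hz": tuple(np.atleast_1d(cutoffs))},
        )

    def pad(rate: float, low_cutoff: float) -> int:
        # a few periods of the lowest corner, so its transient settles
        return int(3.0 * rate / low_cutoff)

    out = BandSignals(
        respiration_lp=mk(
            apply_filter(lp_sos, low.displacement_um, zp,
                         padlen=pad(low.sample_rate, cfg.respiration_lowpass_hz)),
            low.sample_rate,
            "respiration_lp",
            cfg.respiration_lowpass_hz,
        ),
        respiration_bp=mk(
            apply_filter(bp_sos, low_ac, zp,
                         padlen=pad(low.sample_rate, cfg.respiration_band_hz[0])),
            low.sample_rate,
            "respiration_bp",
            cfg.respiration_band_hz,
        ),
        heartsound=mk(
            apply_filter(hs_sos, raw_ac, zp,
                         padlen=pad(d.sample_rate, cfg.heartsound_band_hz[0])),
            d.sample_rate,
            "heartsound",
            cfg.heartsound_band_hz,
        ),
        sphygmogram=mk(
            apply_filter(sp_sos, low_ac, zp,
                         padlen=pad(low.sample_rate, cfg.sphygmogram_band_hz[0])),
            low.sample_rate,
            "sphygmogram",
            cfg.sphygmogram_band_hz,
        ),
        edge_warning=d.duration < 3.0 / (2.0 * np.pi * cfg.respiration_band_hz[0]),
    )
    return out
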