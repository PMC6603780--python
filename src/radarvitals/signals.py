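"""Core in-memory containers shared by every pipeline stage.

The radar front end delivers four detector voltages B3..B6.  Their
differences form the complex baseband sample

    Z(t) = [B5(t) - B6(t)] + j [B3(t) - B4(t)],

whose argument tracks the round-trip phase of the 24 GHz carrier.  All
containers carry an explicit sample rate so that stages operating at
different rates (raw 2000 Sa/s, decimated 100 Sa/s respiration path,
50 Hz heart-sound feature frames) cannot be mixed up silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT

#: Free-space wavelength of the 24 GHz carrier in metres.
WAVELENGTH_24GHZ = SPEED_OF_LIGHT / 24e9

#: Detector channel names in the order they are written to disk.
CHANNEL_NAMES = ("B3", "B4", "B5", "B6")


def channels_to_iq(channels: dict) -> np.ndarray:
    """Combine the four detector voltages into the complex baseband Z.

    Real part is B5 - B6, imaginary part is B3 - B4; per-channel
    common-mode offsets cancel in the differences.
    """
    missing = [k for k in CHANNEL_NAMES if k not in channels]
    if missing:
        raise ValueError(f"missing detector channels: {missing}")
    b3, b4, b5, b6 = (np.asarray(channels[k], dtype=float) for k in CHANNEL_NAMES)
    return (b5 - b6) + 1j * (b3 - b4)


@dataclass
class QuadratureRecord:
    """Raw radar record: complex baseband samples and/or detector voltages.

    Parameters
    ----------
    sample_rate
        Sampling rate in Sa/s.
    iq
        Complex baseband samples Z (arbitrary units).  Derived from
        ``channels`` when omitted.
    channels
        Optional dict of the four detector voltages ``B3..B6`` in volts.
    wavelength
        Carrier wavelength in metres (defaults to c / 24 GHz).
    """

    sample_rate: float
    iq: Optional[np.ndarray] = None
    channels: Optional[dict] = None
    wavelength: float = WAVELENGTH_24GHZ
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.iq is None:
            if self.channels is None:
                raise ValueError("need either iq samples or detector channels")
            self.iq = channels_to_iq(self.channels)
        else:
            self.iq = np.asarray(self.iq, dtype=complex)
        if self.iq.ndim != 1 or self.iq.size == 0:
            raise ValueError("iq must be a non-empty 1-D sequence")

    @property
    def n(self) -> int:
        return self.iq.size

    @property
    def duration(self) -> float:
        return self.n / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.sample_rate


@dataclass
class PhaseTrace:
    """Unwrapped baseband phase in radians."""

    phase: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.phase.size) / self.sample_rate


@dataclass
class DisplacementTrace:
    """Relative chest displacement in micrometres.

    The radar measures *relative* distance only; by convention the first
    sample defines the origin of a reconstructed trace.  ``meta`` carries
    stage provenance (band cutoffs, simulator ground truth, ...).
    """

    displacement_um: np.ndarray
    sample_rate: float
    wavelength_used: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.displacement_um)):
            raise ValueError("displacement contains non-finite values")

    @property
    def n(self) -> int:
        return self.displacement_um.size

    @property
    def duration(self) -> float:
        return self.n / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.sample_rate

    @property
    def displacement_mm(self) -> np.ndarray:
        return self.displacement_um / 1000.0
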