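"""Core NMR domain types and axis conventions.

All other modules share the conventions fixed here:

* times in seconds, frequencies in Hz (signed offset from the carrier),
  decay rates in s**-1; ppm appears only at API boundaries;
* ppm = carrier_ppm + f / SF with f in Hz and SF (spectrometer frequency)
  in MHz, so positive Hz offsets are downfield (higher ppm);
* ppm windows are half-open intervals [lo, hi) so that adjacent segments
  partition the axis without double counting.

A Lorentzian line in the frequency domain corresponds to an exponentially
damped sinusoid in the time domain,

    s(t) = a * exp(i*phi) * exp((i*2*pi*f - lam) * t),

with full width at half maximum ``lam / pi`` Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "AcquisitionParams",
    "FIDRecord",
    "LorentzianComponent",
    "PpmWindow",
    "Provenance",
    "ppm_to_hz",
    "hz_to_ppm",
    "reference_axis",
    "time_axis",
]


class Provenance(str, Enum):
    """Origin of a stored FID: a raw acquisition or a filtered segment."""

    RAW = "raw"
    SEGMENT = "segment"


@dataclass(frozen=True)
class AcquisitionParams:
    """Spectrometer and axis metadata fixing the time and ppm grids.

    Parameters
    ----------
    spectrometer_freq : float
        Proton Larmor frequency in MHz (e.g. 500 for a 500 MHz magnet).
    sweep_width : float
        Spectral width in Hz. The complex dwell time is ``1 / sweep_width``.
    n_points : int
        Number of complex time-domain points.
    carrier_ppm : float
        ppm position of zero frequency offset (transmitter/carrier).
    temperature_K : float
        Sample temperature in kelvin; metadata only.
    """

    spectrometer_freq: float
    sweep_width: float
    n_points: int
    carrier_ppm: float = 4.7
    temperature_K: float = 298.2

    def __post_init__(self) -> None:
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be > 0 MHz")
        if self.sweep_width <= 0:
            raise ValueError("sweep_width must be > 0 Hz")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def dwell_time(self) -> float:
        """Complex dwell time in seconds."""
        return 1.0 / self.sweep_width

    @property
    def ppm_span(self) -> float:
        """Width of the spectral window in ppm."""
        return self.sweep_width / self.spectrometer_freq


@dataclass(frozen=True)
class PpmWindow:
    """Half-open chemical-shift interval [lo, hi) in ppm."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"require lo < hi, got [{self.lo}, {self.hi})")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, ppm: float) -> bool:
        """Membership in the half-open interval: hi itself is excluded."""
        return self.lo <= ppm < self.hi

    def overlaps(self, other: "PpmWindow") -> bool:
        return self.lo < other.hi and other.lo < self.hi


@dataclass(frozen=True)
class LorentzianComponent:
    """One exponentially damped sinusoid (one Lorentzian line).

    ``amplitude`` is the modulus of the complex amplitude at the true
    excitation origin t = 0, the quantity proportional to concentration.
    """

    amplitude: float
    phase: float
    frequency: float  # Hz offset from carrier, signed
    decay: float  # s**-1, > 0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.decay <= 0:
            raise ValueError("decay must be > 0 s^-1")

    @property
    def fwhm_hz(self) -> float:
        """Lorentzian full width at half maximum in Hz."""
        return self.decay / np.pi

    @property
    def complex_amplitude(self) -> complex:
        return self.amplitude * np.exp(1j * self.phase)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Time signal a*exp(i*phi)*exp((i*2*pi*f - lam)*t) on axis ``t``."""
        return self.complex_amplitude * np.exp(
            (2j * np.pi * self.frequency - self.decay) * np.asarray(t)
        )


@dataclass
class FIDRecord:
    """A complex free induction decay plus provenance.

    ``t_start`` is the absolute time of the first stored sample relative to
    the excitation origin; it is 0 for raw FIDs and positive for filtered
    segments whose initial points were discarded.
    """

    samples: np.ndarray
    params: AcquisitionParams
    t_start: float = 0.0
    sample_id: str = ""
    provenance: Provenance = Provenance.RAW
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.ascontiguousarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if len(self.samples) != self.params.n_points:
            raise ValueError(
                f"length of samples ({len(self.samples)}) != "
                f"params.n_points ({self.params.n_points})"
            )
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")
        self.provenance = Provenance(self.provenance)
        if self.provenance is Provenance.RAW and self.t_start != 0:
            raise ValueError("raw FIDs must have t_start == 0")

    def __len__(self) -> int:
        return len(self.samples)


def ppm_to_hz(ppm: float, params: AcquisitionParams) -> float:
    """Chemical shift (ppm) to signed frequency offset (Hz) from the carrier."""
    return (ppm - params.carrier_ppm) * params.spectrometer_freq


def hz_to_ppm(f: float, params: AcquisitionParams) -> float:
    """Exact inverse of :func:`ppm_to_hz`."""
    return params.carrier_ppm + f / params.spectrometer_freq


def reference_axis(
    params: AcquisitionParams, observed_ppm: float, target_ppm: float
) -> AcquisitionParams:
    """Recalibrate the ppm axis so a reference line lands on its known shift.

    Shifts ``carrier_ppm`` by ``target_ppm - observed_ppm``. Frequencies in
    Hz are untouched; only the ppm labelling of the axis moves. The standard
    serum reference is the alpha-glucose alpha-H doublet at 5.233 ppm.
    """
    return replace(params, carrier_ppm=params.carrier_ppm + (target_ppm - observed_ppm))


def time_axis(fid: FIDRecord) -> np.ndarray:
    """Absolute sample times t_n = t_start + n * dwell, in seconds."""
    dt = fid.params.dwell_time
    return fid.t_start + dt * np.arange(fid.params.n_points)
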