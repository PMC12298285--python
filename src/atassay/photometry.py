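"""Double-pass reflection–transmission photometry.

The assay chip measures color in a sessile droplet sandwiched between a
transparent top plate and a reflective bottom electrode.  A 405 nm beam
enters from above, crosses the liquid layer, is reflected by the electrode
(reflectance ``r``), crosses the liquid a second time and reaches a
photon-counting PMT.  Absorption on each traversal follows the
Beer–Lambert law, so the detected intensity is

    I_out = I_in * exp(-alpha * l) * r

with ``alpha`` the solution absorption coefficient and ``l`` the *total*
optical path (twice the chamber gap).  Absorbance is the decadic log ratio
against the incident (t = 0) intensity,

    A(t) = -log10( I(t) / I0 )

and because the PMT reports photon counts proportional to intensity
(``N = I * A_det / (h * f)``), the absorbance *change* between two times
reduces to a pure count ratio,

    dA = log10( N(t0) / N(t1) )

in which the reflectance, detector area and photon energy all cancel.
The assay observable is dA per minute over the 0–60 s reaction window.

Everything here is stateless scalar/array math; trace-level QC and
endpoint selection live in :mod:`atassay.traces`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError, InvalidConfigError, SaturationError, WindowError

#: CODATA Planck constant, J s.
PLANCK_H = 6.62607015e-34
#: Speed of light in vacuum, m/s.
LIGHT_SPEED_C = 299_792_458.0


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and constants of the optical detection path.

    Parameters
    ----------
    wavelength_nm
        Center wavelength of the bandpass-filtered source (405 nm LED line).
    bandwidth_nm
        Half-peak width of the filter; informational only — the math uses
        the monochromatic approximation at ``wavelength_nm``.
    path_length_mm
        Liquid thickness per traversal (the chamber gap).  The total
        optical path is twice this because the beam crosses the droplet
        before and after reflection.
    reflectance_r
        Bottom-electrode reflectance in (0, 1].  Cancels out of dA.
    detector_area_mm2
        Effective collection area used to convert intensity to photon rate.
    lamp_voltage_V, saturation_voltage_V
        Source supply voltage and the threshold above which the PMT count
        saturates; traces acquired above threshold are rejected.
    """

    wavelength_nm: float = 405.0
    bandwidth_nm: float = 10.0
    path_length_mm: float = 0.3
    reflectance_r: float = 1.0
    detector_area_mm2: float = 1.0
    planck_h: float = PLANCK_H
    light_speed_c: float = LIGHT_SPEED_C
    lamp_voltage_V: float = 2.44
    saturation_voltage_V: float = 2.45

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise InvalidConfigError("wavelength_nm must be positive")
        if not 0 < self.reflectance_r <= 1:
            raise InvalidConfigError("reflectance_r must lie in (0, 1]")
        if not self.path_length_mm > 0:
            raise InvalidConfigError("path_length_mm must be positive")
        if not self.detector_area_mm2 > 0:
            raise InvalidConfigError("detector_area_mm2 must be positive")
        if not self.saturation_voltage_V > 0:
            raise InvalidConfigError("saturation_voltage_V must be positive")

    @property
    def total_path_mm(self) -> float:
        """Total optical path: incident plus reflected traversal."""
        return 2.0 * self.path_length_mm

    @property
    def frequency_hz(self) -> float:
        """Optical frequency f = c / lambda."""
        return self.light_speed_c / (self.wavelength_nm * 1e-9)


@dataclass(frozen=True)
class LightSample:
    """A snapshot of the optical signal in one of three equivalent units.

    ``power = intensity * detector_area`` and ``photon_rate = power / (h f)``
    when the corresponding fields are populated.
    """

    intensity: Optional[float] = None      # W / mm^2
    power: Optional[float] = None          # W
    photon_rate: Optional[float] = None    # photons / s

    def __post_init__(self) -> None:
        for name in ("intensity", "power", "photon_rate"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class AbsorbanceSample:
    """Absorbance at a single time point, optionally with the absorption
    coefficient it derives from."""

    time_s: float
    absorbance: float
    alpha_per_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise DomainError("time_s must be nonnegative")
        if not math.isfinite(self.absorbance):
            raise DomainError("absorbance must be finite")


@dataclass(frozen=True)
class RateResult:
    """Absorbance change over a window and its per-minute rate."""

    delta_A: float
    t0_s: float = 0.0
    t1_s: float = 60.0
    rate_per_min: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.t1_s > self.t0_s:
            raise WindowError(f"window [{self.t0_s}, {self.t1_s}] s is not increasing")


def photon_energy(config: OpticalConfig) -> float:
    """Energy of one photon at the configured wavelength, h*f in joules."""
    return config.planck_h * config.frequency_hz


def intensity_to_photon_rate(sample: LightSample, config: OpticalConfig) -> float:
    """Convert intensity to a photon arrival rate, N = I * A / (h f)."""
    if sample.intensity is None:
        raise DomainError("LightSample.intensity is not set")
    return sample.intensity * config.detector_area_mm2 / photon_energy(config)


def reflected_intensity(
    i_in: float, alpha_per_mm: float, config: OpticalConfig
) -> float:
    """Intensity after the double pass: I_in * exp(-alpha*l) * r.

    ``alpha_per_mm`` is the solution absorption coefficient; the path is
    ``config.total_path_mm`` (both traversals).
    """
    if i_in < 0:
        raise DomainError("incident intensity must be nonnegative")
    if alpha_per_mm < 0:
        raise DomainError("absorption coefficient must be nonnegative")
    return i_in * math.exp(-alpha_per_mm * config.total_path_mm) * config.reflectance_r


def absorbance(i_t: float, i0: float) -> float:
    """Decadic absorbance A = -log10(I(t)/I0).  Both intensities must be > 0."""
    if i_t <= 0 or i0 <= 0:
        raise DomainError(f"intensities must be positive for log, got {i_t}, {i0}")
    return -math.log10(i_t / i0)


def delta_absorbance(
    n_t0: float, n_t1: float, *, saturated: bool = False
) -> float:
    """Absorbance change from two photon counts, log10(N(t0)/N(t1)).

    The detector constants (h, f, collection area) and the electrode
    reflectance divide out of the count ratio, so no optical configuration
    is needed here.  Counts flagged as acquired in saturation are refused —
    the ratio of clipped counts is meaningless.
    """
    if saturated:
        raise SaturationError("counts were acquired above the saturation voltage")
    if n_t0 <= 0 or n_t1 <= 0:
        raise DomainError(f"photon counts must be positive, got {n_t0}, {n_t1}")
    return math.log10(n_t0 / n_t1)


def delta_absorbance_rate(
    n_t0: float,
    n_t1: float,
    t0_s: float = 0.0,
    t1_s: float = 60.0,
    *,
    saturated: bool = False,
) -> RateResult:
    """dA between two counts, rescaled to a one-minute rate."""
    if not t1_s > t0_s:
        raise WindowError(f"t1_s ({t1_s}) must exceed t0_s ({t0_s})")
    d_a = delta_absorbance(n_t0, n_t1, saturated=saturated)
    rate = d_a * 60.0 / (t1_s - t0_s)
    return RateResult(delta_A=d_a, t0_s=t0_s, t1_s=t1_s, rate_per_min=rate)


def absorbance_to_transmittance(a: np.ndarray | float) -> np.ndarray | float:
    """Fractional transmitted intensity 10**(-A); used by the simulator."""
    return np.power(10.0, -np.asarray(a, dtype=float))
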