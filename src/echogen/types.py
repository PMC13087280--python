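"""Core domain containers shared across the pipeline.

Conventions used throughout the package:

* frequencies in MHz, speed of sound in m/s, depths and lateral extents in mm
  (converted to cm only inside attenuation arithmetic),
* attenuation coefficients are one-way, in dB/MHz/cm; round-trip compensation
  carries an explicit factor of 2,
* RF frames are 2-D arrays indexed ``[axial sample, scan line]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PulseModel",
    "GridSpec",
    "AcousticRegion",
    "PhantomScene",
    "RFFrame",
    "BModeImage",
    "NormalizationParams",
]


@dataclass(frozen=True)
class PulseModel:
    """Gaussian transmit/receive pulse of a linear-array system.

    ``fractional_bandwidth`` is the -6 dB (amplitude) full width divided by
    the center frequency.
    """

    center_frequency_mhz: float = 10.0
    fractional_bandwidth: float = 0.6
    sampling_rate_mhz: float = 40.0
    speed_of_sound_mps: float = 1540.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fractional_bandwidth <= 1.0):
            raise ValueError("fractional_bandwidth must be in (0, 1]")
        if self.center_frequency_mhz >= self.sampling_rate_mhz / 2.0:
            raise ValueError("center frequency must be below Nyquist")
        if self.center_frequency_mhz <= 0 or self.speed_of_sound_mps <= 0:
            raise ValueError("frequencies and speed of sound must be positive")

    @property
    def sigma_f_mhz(self) -> float:
        """Std of the Gaussian amplitude spectrum implied by the -6 dB width."""
        bw = self.fractional_bandwidth * self.center_frequency_mhz
        # -6 dB amplitude: exp(-(bw/2)^2 / (2 sigma^2)) = 10^(-6/20)
        return bw / (2.0 * np.sqrt(2.0 * np.log(10.0 ** 0.3)))

    def amplitude_spectrum(self, f_mhz: np.ndarray) -> np.ndarray:
        return np.exp(-((f_mhz - self.center_frequency_mhz) ** 2)
                      / (2.0 * self.sigma_f_mhz ** 2))


@dataclass(frozen=True)
class AcousticRegion:
    """Homogeneous sub-resolution scatterer population.

    ``geometry`` is ``None`` for the background, or an axis-aligned ellipse
    ``(center_axial_mm, center_lateral_mm, semi_axial_mm, semi_lateral_mm)``.
    """

    a_eff_um: float
    density_per_mm2: float
    amplitude_variance: float = 1.0
    attenuation_db_mhz_cm: float = 1.0
    geometry: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if self.a_eff_um <= 0:
            raise ValueError("effective radius must be positive")
        if self.density_per_mm2 < 0:
            raise ValueError("number density must be non-negative")
        if self.attenuation_db_mhz_cm < 0:
            raise ValueError("attenuation must be non-negative")

    @property
    def is_background(self) -> bool:
        return self.geometry is None


@dataclass(frozen=True)
class PhantomScene:
    """Ordered stack of acoustic regions; later regions override earlier ones
    inside their geometry. Exactly one background region, listed first."""

    regions: tuple[AcousticRegion, ...]
    intervening_layer_depth_mm: float = 0.0
    class_label: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        n_bg = sum(r.is_background for r in self.regions)
        if n_bg != 1 or not self.regions[0].is_background:
            raise ValueError("scene needs exactly one background region, first")
        if self.class_label not in (None, "benign", "malignant"):
            raise ValueError("class_label must be benign or malignant")

    @property
    def background(self) -> AcousticRegion:
        return self.regions[0]


@dataclass(frozen=True)
class GridSpec:
    """Field-of-view / sampling grid of an RF frame."""

    n_axial: int = 512
    n_lines: int = 128
    lateral_pitch_mm: float = 0.3125

    def __post_init__(self) -> None:
        if self.n_axial < 1 or self.n_lines < 1:
            raise ValueError("field of view must be non-empty")
        if self.lateral_pitch_mm <= 0:
            raise ValueError("lateral pitch must be positive")

    def axial_pitch_mm(self, pulse: PulseModel) -> float:
        # one sample corresponds to c/(2 fs) of depth (round trip)
        return pulse.speed_of_sound_mps / (2.0 * pulse.sampling_rate_mhz * 1e6) * 1e3

    def depth_mm(self, pulse: PulseModel) -> float:
        return self.n_axial * self.axial_pitch_mm(pulse)

    def width_mm(self) -> float:
        return self.n_lines * self.lateral_pitch_mm


@dataclass
class RFFrame:
    """Raw echo matrix plus acquisition geometry."""

    samples: np.ndarray  # [n_axial, n_lines], float
    sampling_rate_mhz: float
    speed_of_sound_mps: float
    lateral_pitch_mm: float
    provenance: str = "original"  # original | synthetic | reference
    calibration: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("RF samples must be a 2-D [axial, line] matrix")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")
        if self.provenance not in ("original", "synthetic", "reference"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_pitch_mm(self) -> float:
        return self.speed_of_sound_mps / (2.0 * self.sampling_rate_mhz * 1e6) * 1e3


@dataclass
class BModeImage:
    """Log-compressed envelope raster mapped onto RF-frame coordinates."""

    pixels: np.ndarray  # values in [0, 1]
    dynamic_range_db: float = 60.0
    extent_mm: Optional[tuple[float, float]] = None  # (depth, width)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("B-mode image must be 2-D")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1.0 + 1e-9:
            raise ValueError("B-mode pixels must lie in [0, 1]")


@dataclass(frozen=True)
class NormalizationParams:
    """Global min-max normalization constants, fitted on the training split."""

    rf_min: float
    rf_max: float
    bmode_min: float = 0.0
    bmode_max: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.rf_max > self.rf_min and self.bmode_max > self.bmode_min):
            raise ValueError("normalization range must be non-degenerate")

    def to_json(self) -> str:
        return json.dumps({
            "rf_min": self.rf_min, "rf_max": self.rf_max,
            "bmode_min": self.bmode_min, "bmode_max": self.bmode_max,
            "source": self.source,
        })

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        return cls(**json.loads(text))
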