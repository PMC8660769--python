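"""Three-phase demodulation and calibration to diffuse reflectance.

For frames I_k = A + B cos(phi + (k-1) * 120deg) the AC amplitude B is
recovered per pixel from phase differences,

    I_ac = sqrt(2)/3 * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)

which is exact for ideal sinusoids and rejects any offset common to the
three frames (ambient light).  The DC amplitude A is the three-frame mean.
Calibration against a phantom of known optical properties removes the
instrument response:

    Rd_sample(fx) = I_sample(fx) / I_phantom(fx) * Rd_phantom_model(fx)

where the phantom's model Rd comes from the Monte Carlo forward model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DiffuseReflectanceMap",
    "FrameSequence",
    "demodulate_ac",
    "demodulate_dc",
    "dark_correct",
    "calibrate",
]


@dataclass
class FrameSequence:
    """The five raw camera frames of one wavelength at one spatial frequency."""

    planar: np.ndarray
    dark: np.ndarray
    phase1: np.ndarray
    phase2: np.ndarray
    phase3: np.ndarray
    wavelength: float = 0.0
    fx: float = 0.0

    def __post_init__(self) -> None:
        shapes = {f.shape for f in (self.planar, self.dark, self.phase1, self.phase2, self.phase3)}
        if len(shapes) != 1:
            raise ValueError(f"all frames must share one shape, got {shapes}")

    @property
    def frames(self):
        return [self.planar, self.dark, self.phase1, self.phase2, self.phase3]


@dataclass
class DiffuseReflectanceMap:
    """Calibrated diffuse reflectance; ``valid`` flags in-range pixels."""

    rd: np.ndarray
    fx: float
    wavelength: float = 0.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.rd) & (self.rd >= 0.0) & (self.rd <= 1.0)


def _check_shapes(*imgs):
    shapes = {np.asarray(i).shape for i in imgs}
    if len(shapes) != 1:
        raise ValueError(f"images must share one shape, got {shapes}")


def demodulate_ac(i1, i2, i3) -> np.ndarray:
    """AC amplitude image from the three phase frames (exact for sinusoids)."""
    i1, i2, i3 = (np.asarray(i, dtype=np.float64) for i in (i1, i2, i3))
    _check_shapes(i1, i2, i3)
    return (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )


def demodulate_dc(i1, i2, i3) -> np.ndarray:
    """DC (offset) image: the mean of the three phase frames."""
    i1, i2, i3 = (np.asarray(i, dtype=np.float64) for i in (i1, i2, i3))
    _check_shapes(i1, i2, i3)
    return (i1 + i2 + i3) / 3.0


def dark_correct(frame, dark) -> np.ndarray:
    """Subtract the dark frame, clipping at zero (clipped pixels logged)."""
    frame = np.asarray(frame, dtype=np.float64)
    dark = np.asarray(dark, dtype=np.float64)
    _check_shapes(frame, dark)
    diff = frame - dark
    n_clipped = int(np.count_nonzero(diff < 0))
    if n_clipped:
        logger.warning("dark_correct clipped %d negative pixels to 0", n_clipped)
    return np.clip(diff, 0.0, None)


def calibrate(
    i_sample,
    i_phantom,
    rd_phantom_model,
    fx: float = 0.0,
    wavelength: float = 0.0,
    rel_floor: float = 1e-6,
) -> DiffuseReflectanceMap:
    """Ratio calibration of a demodulated sample image against the phantom.

    ``rd_phantom_model`` is the phantom's model diffuse reflectance at the
    same fx (scalar, or an image for a spatially varying model).  Phantom
    pixels below ``rel_floor`` times the phantom's mean intensity are not
    divided; they come back NaN and flagged invalid.
    """
    i_sample = np.asarray(i_sample, dtype=np.float64)
    i_phantom = np.asarray(i_phantom, dtype=np.float64)
    _check_shapes(i_sample, i_phantom)
    floor = rel_floor * float(np.abs(i_phantom).mean())
    bad = ~(np.abs(i_phantom) > floor)
    rd = np.full(i_sample.shape, np.nan)
    np.divide(i_sample, i_phantom, out=rd, where=~bad)
    rd = rd * rd_phantom_model
    valid = np.isfinite(rd) & (rd >= 0.0) & (rd <= 1.0)
    if bad.any():
        logger.warning("calibrate: %d near-zero phantom pixels flagged invalid", int(bad.sum()))
    return DiffuseReflectanceMap(rd=rd, fx=fx, wavelength=wavelength, valid=valid)
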