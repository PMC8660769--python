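"""Illumination pattern generation and error-diffusion halftoning.

Each wavelength is measured with a five-pattern sequence: planar
illumination, a dark frame, and three sinusoids phase-shifted by 0, 120 and
240 degrees.  Binary-native projectors display 1-bit frames two orders of
magnitude faster than 8-bit grayscale, so the continuous-tone sinusoids are
converted to binary halftones by Floyd-Steinberg error diffusion; the turbid
medium's low-pass response restores an effectively sinusoidal illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "PatternSpec",
    "PatternImage",
    "sinusoid_pattern",
    "halftone_error_diffusion",
    "pattern_sequence",
]

VALID_KINDS = ("planar", "dark", "sinusoid")
PHASES = (0.0, 120.0, 240.0)


@dataclass(frozen=True)
class PatternSpec:
    """Specification of one projected pattern.

    ``pixel_pitch`` is the physical size (mm) of one projected pixel at the
    sample plane; the sinusoid argument is ``2 pi fx (col * pixel_pitch)``.
    """

    shape: tuple
    fx: float = 0.0
    pixel_pitch: float = 1.0
    phase: float = 0.0
    kind: str = "sinusoid"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if not (self.pixel_pitch > 0):
            raise ValueError("pixel_pitch must be > 0")
        if self.fx < 0:
            raise ValueError("fx must be >= 0")
        if self.fx * self.pixel_pitch >= 0.5:
            raise ValueError(
                f"Nyquist violation: fx * pixel_pitch = {self.fx * self.pixel_pitch:.3f} >= 0.5"
            )


@dataclass
class PatternImage:
    """A 2-D illumination pattern: relative radiance in [0,1].

    ``bit_depth`` is 8 for continuous-tone (256-level) patterns and 1 for
    binary halftones ({0, 1} only).
    """

    values: np.ndarray
    bit_depth: int = 8
    spec: PatternSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.bit_depth == 1:
            if not np.all((self.values == 0.0) | (self.values == 1.0)):
                raise ValueError("1-bit pattern must contain only {0, 1}")
        elif self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("pattern values must lie in [0, 1]")


def sinusoid_pattern(spec: PatternSpec) -> PatternImage:
    """Continuous-tone pattern for a spec, quantized to 8-bit levels.

    Sinusoid: ``0.5 * (1 + cos(2 pi fx x + phase))`` with x the column
    coordinate in mm; planar is all ones, dark all zeros.
    """
    rows, cols = spec.shape
    if spec.kind == "planar":
        return PatternImage(np.ones((rows, cols)), bit_depth=8, spec=spec)
    if spec.kind == "dark":
        return PatternImage(np.zeros((rows, cols)), bit_depth=8, spec=spec)
    x = np.arange(cols) * spec.pixel_pitch
    row = 0.5 * (1.0 + np.cos(2.0 * np.pi * spec.fx * x + np.deg2rad(spec.phase)))
    vals = np.broadcast_to(row, (rows, cols))
    vals = np.round(vals * 255.0) / 255.0  # 8-bit quantization
    return PatternImage(np.ascontiguousarray(vals), bit_depth=8, spec=spec)


@njit(cache=False)
def _floyd_steinberg_serpentine(img):  # pragma: no cover - jitted
    rows, cols = img.shape
    work = img.copy()
    out = np.zeros((rows, cols))
    for r in range(rows):
        l2r = r % 2 == 0
        rng = range(cols) if l2r else range(cols - 1, -1, -1)
        step = 1 if l2r else -1
        for c in rng:
            old = work[r, c]
            new = 1.0 if old >= 0.5 else 0.0
            out[r, c] = new
            err = old - new
            # 7/16 ahead, 3/16 behind-below, 5/16 below, 1/16 ahead-below
            if 0 <= c + step < cols:
                work[r, c + step] += err * 7.0 / 16.0
            if r + 1 < rows:
                if 0 <= c - step < cols:
                    work[r + 1, c - step] += err * 3.0 / 16.0
                work[r + 1, c] += err * 5.0 / 16.0
                if 0 <= c + step < cols:
                    work[r + 1, c + step] += err * 1.0 / 16.0
    return out


def halftone_error_diffusion(pattern: PatternImage) -> PatternImage:
    """Convert a continuous pattern to 1-bit by Floyd-Steinberg diffusion.

    Serpentine scan (alternating row direction) with the classic
    7/16, 3/16, 5/16, 1/16 error kernel and threshold 0.5.  Deterministic:
    the same input always yields the same binary image.
    """
    vals = np.asarray(pattern.values, dtype=np.float64)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("halftone input must lie in [0, 1]")
    binary = _floyd_steinberg_serpentine(vals)
    return PatternImage(binary, bit_depth=1, spec=pattern.spec)


def pattern_sequence(
    wavelengths,
    fx: float,
    shape,
    pixel_pitch: float,
    halftone: bool = False,
) -> list:
    """Five-pattern sequence per wavelength: planar, dark, three phases.

    Returns a flat list ordered wavelength-major; with ``halftone`` every
    non-dark pattern is converted to binary (the dark frame is all-zero in
    both modes, and an all-ones planar halftones to all ones).
    """
    wavelengths = list(np.atleast_1d(wavelengths))
    seq: list[PatternImage] = []
    for _wl in wavelengths:
        frames = [
            sinusoid_pattern(PatternSpec(shape=shape, pixel_pitch=pixel_pitch, kind="planar")),
            sinusoid_pattern(PatternSpec(shape=shape, pixel_pitch=pixel_pitch, kind="dark")),
        ]
        for phase in PHASES:
            frames.append(
                sinusoid_pattern(
                    PatternSpec(
                        shape=shape,
                        fx=fx,
                        pixel_pitch=pixel_pitch,
                        phase=phase,
                        kind="sinusoid",
                    )
                )
            )
        if halftone:
            frames = [
                halftone_error_diffusion(p) if p.spec.kind != "dark" else
                PatternImage(p.values.copy(), bit_depth=1, spec=p.spec)
                for p in frames
            ]
        seq.extend(frames)
    return seq


def sequence_manifest(wavelengths, fx: float, halftone: bool) -> dict:
    """JSON-serializable manifest describing a pattern sequence's order."""
    wavelengths = [float(w) for w in np.atleast_1d(wavelengths)]
    frames = []
    for wl in wavelengths:
        for kind, phase in (
            ("planar", None),
            ("dark", None),
            ("sinusoid", 0.0),
            ("sinusoid", 120.0),
            ("sinusoid", 240.0),
        ):
            frames.append({"wavelength_nm": wl, "kind": kind, "phase_deg": phase, "fx_per_mm": fx})
    return {"halftone": bool(halftone), "frames": frames}
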