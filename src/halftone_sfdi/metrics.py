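"""Evaluation statistics: percent difference, repeatability, resolution.

Conventions: percent difference is ``100 * (test - reference) / reference``
with an explicitly named reference; the repeatability noise level is the
coefficient of variation of repeated measurements; spatial resolution is
the FWHM of the line spread function obtained by differentiating an edge
spread function.  Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComparisonStat",
    "ResolutionEstimate",
    "percent_difference",
    "noise_level",
    "esf_to_fwhm",
]


@dataclass
class ComparisonStat:
    """Mean +/- SD of signed and absolute percent differences.

    ``n`` counts the elements compared; ``n_excluded`` those dropped for a
    zero reference.  SDs are sample (n-1) standard deviations.
    """

    mean_pd: float
    sd_pd: float
    mean_abs_pd: float
    sd_abs_pd: float
    n: int
    reference_label: str
    n_excluded: int = 0


@dataclass
class ResolutionEstimate:
    """ESF, its derivative (LSF), and the FWHM of the LSF main lobe (mm)."""

    positions: np.ndarray
    esf: np.ndarray
    lsf: np.ndarray
    fwhm: float


def _sd(x):
    x = np.asarray(x, dtype=np.float64)
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def percent_difference(test, reference, reference_label: str = "reference",
                       mask=None) -> ComparisonStat:
    """Element-wise percent difference of ``test`` against ``reference``.

    Zero-reference elements are excluded and counted; an optional boolean
    ``mask`` restricts the comparison (True = include), used to drop
    invalid-inversion pixels from map-level aggregates.
    """
    test = np.asarray(test, dtype=np.float64).ravel()
    reference = np.asarray(reference, dtype=np.float64).ravel()
    if test.shape != reference.shape:
        raise ValueError("test and reference must have the same number of elements")
    keep = np.isfinite(test) & np.isfinite(reference)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool).ravel()
    nonzero = reference != 0
    n_excluded = int(np.count_nonzero(keep & ~nonzero))
    keep &= nonzero
    if not keep.any():
        raise ValueError("no comparable elements (all excluded)")
    pd_vals = 100.0 * (test[keep] - reference[keep]) / reference[keep]
    return ComparisonStat(
        mean_pd=float(pd_vals.mean()),
        sd_pd=_sd(pd_vals),
        mean_abs_pd=float(np.abs(pd_vals).mean()),
        sd_abs_pd=_sd(np.abs(pd_vals)),
        n=int(pd_vals.size),
        reference_label=reference_label,
        n_excluded=n_excluded,
    )


def noise_level(repeats) -> float:
    """Repeatability as percent coefficient of variation: 100 * SD / mean.

    ``repeats`` are repeated measurements of the same quantity (e.g., 10
    repeated extractions of a phantom's absorption).  Sample SD; scale
    invariant by construction.
    """
    repeats = np.asarray(repeats, dtype=np.float64).ravel()
    if repeats.size < 2:
        raise ValueError("need at least two repeats")
    mean = repeats.mean()
    if mean == 0:
        raise ValueError("mean of repeats is zero; CV undefined")
    return float(100.0 * np.std(repeats, ddof=1) / abs(mean))


def esf_to_fwhm(profile, positions) -> ResolutionEstimate:
    """Resolution from an edge profile: normalize, differentiate, FWHM.

    The edge spread function is min-max normalized, differentiated by
    central differences to the line spread function, and the full width at
    half maximum of the LSF's main lobe is located by linear interpolation
    of the half-maximum crossings.  Profiles whose LSF has no clear single
    main lobe (secondary lobes above half maximum) are rejected with advice
    to smooth first.
    """
    profile = np.asarray(profile, dtype=np.float64).ravel()
    positions = np.asarray(positions, dtype=np.float64).ravel()
    if profile.size != positions.size:
        raise ValueError("profile and positions must have equal length")
    if profile.size < 5:
        raise ValueError("profile too short for derivative estimation")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    span = profile.max() - profile.min()
    if span == 0:
        raise ValueError("flat profile has no edge")
    esf = (profile - profile.min()) / span
    lsf = np.gradient(esf, positions)
    lsf = np.abs(lsf)  # edge polarity is irrelevant
    peak = int(np.argmax(lsf))
    half = lsf[peak] / 2.0
    above = lsf >= half
    # main lobe: contiguous run of samples above half max around the peak
    left = peak
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak
    while right < lsf.size - 1 and above[right + 1]:
        right += 1
    if above[:left].any() or above[right + 1:].any():
        raise ValueError(
            "LSF has secondary lobes above half maximum; smooth the profile first"
        )
    if left == 0 or right == lsf.size - 1:
        raise ValueError("LSF main lobe is clipped by the profile ends")
    # linear interpolation of the two half-maximum crossings
    x_l = positions[left - 1] + (half - lsf[left - 1]) / (lsf[left] - lsf[left - 1]) * (
        positions[left] - positions[left - 1]
    )
    x_r = positions[right] + (half - lsf[right]) / (lsf[right + 1] - lsf[right]) * (
        positions[right + 1] - positions[right]
    )
    fwhm = float(x_r - x_l)
    if not (fwhm > 0):
        raise ValueError("degenerate FWHM; profile may be too noisy")
    return ResolutionEstimate(positions=positions, esf=esf, lsf=lsf, fwhm=fwhm)
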