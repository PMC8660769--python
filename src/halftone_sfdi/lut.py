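"""Forward lookup table (mua, musp) -> (Rd(f1), Rd(f2)) and its inversion.

SFDI extracts optical properties by direct mapping: the diffuse reflectance
measured at two spatial frequencies (conventionally 0 and 0.1 /mm) uniquely
determines an (absorption, reduced scattering) pair over the tissue-relevant
range.  The forward grid is evaluated from a white Monte Carlo photon table;
the inverse map interpolates linearly over the triangulated forward image in
Rd-space, so per-pixel inversion is a vectorized interpolator call rather
than an iterative fit.  Pixels whose Rd pair falls outside the attainable
region (the convex hull of the forward image) are flagged invalid, never
extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.special import j0 as _bessel_j0

from .mc import WMCTable

__all__ = ["LUT", "OpticalPropertyMap", "build_lut", "invert_rd", "default_grids"]

# property ranges of the 16-phantom validation array; default grids pad them
PHANTOM_MUA_RANGE = (0.005, 0.04)
PHANTOM_MUSP_RANGE = (0.3, 2.0)


def default_grids(n_mua: int = 100, n_musp: int = 100):
    """Default LUT grids: log-spaced mua (spans an order of magnitude) and
    linear musp, padded beyond the phantom validation ranges."""
    mua = np.geomspace(0.003, 0.05, n_mua)
    musp = np.linspace(0.2, 2.8, n_musp)
    return mua, musp


@dataclass
class OpticalPropertyMap:
    """Per-pixel inversion result. Invalid pixels are NaN with mask False."""

    mua: np.ndarray
    musp: np.ndarray
    valid: np.ndarray


@dataclass
class LUT:
    """Forward grid of diffuse reflectance pairs plus its inverse mapping.

    ``rd_dc[j, k]`` and ``rd_ac[j, k]`` hold Rd at the two frequencies of
    ``f_pair`` for ``mua_grid[j]``, ``musp_grid[k]``.
    """

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    f_pair: tuple
    rd_dc: np.ndarray
    rd_ac: np.ndarray
    provenance: dict = field(default_factory=dict)
    _inverse: LinearNDInterpolator | None = field(default=None, repr=False, compare=False)

    def _inverse_interpolator(self) -> LinearNDInterpolator:
        if self._inverse is None:
            pts = np.column_stack([self.rd_dc.ravel(), self.rd_ac.ravel()])
            mua_j, musp_k = np.meshgrid(self.mua_grid, self.musp_grid, indexing="ij")
            vals = np.column_stack([mua_j.ravel(), musp_k.ravel()])
            self._inverse = LinearNDInterpolator(pts, vals)
        return self._inverse

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mua_grid", data=self.mua_grid)
            f.create_dataset("musp_grid", data=self.musp_grid)
            f.create_dataset("rd_dc", data=self.rd_dc)
            f.create_dataset("rd_ac", data=self.rd_ac)
            f.attrs["f_pair"] = np.asarray(self.f_pair, dtype=float)
            for k, v in self.provenance.items():
                f.attrs[f"prov_{k}"] = v

    @classmethod
    def load(cls, path) -> "LUT":
        with h5py.File(path, "r") as f:
            prov = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("prov_")}
            return cls(
                mua_grid=f["mua_grid"][:],
                musp_grid=f["musp_grid"][:],
                f_pair=tuple(float(v) for v in f.attrs["f_pair"]),
                rd_dc=f["rd_dc"][:],
                rd_ac=f["rd_ac"][:],
                provenance=prov,
            )

    def to_csv(self, path) -> None:
        mua_j, musp_k = np.meshgrid(self.mua_grid, self.musp_grid, indexing="ij")
        pd.DataFrame(
            {
                "mua": mua_j.ravel(),
                "musp": musp_k.ravel(),
                "rd_dc": self.rd_dc.ravel(),
                "rd_ac": self.rd_ac.ravel(),
            }
        ).to_csv(path, index=False)


def build_lut(table: WMCTable, mua_grid, musp_grid, f_pair=(0.0, 0.1)) -> LUT:
    """Dense forward evaluation of Rd at every grid node.

    Node values are bit-identical to direct `rd_frequency` calls; the
    per-musp similarity scaling and Bessel kernels are merely hoisted out of
    the mua loop (the arithmetic per node is the same expression in the same
    order).  Grids must be strictly increasing.
    """
    mua_grid = np.asarray(mua_grid, dtype=np.float64)
    musp_grid = np.asarray(musp_grid, dtype=np.float64)
    if mua_grid.ndim != 1 or musp_grid.ndim != 1:
        raise ValueError("grids must be 1-D")
    if np.any(np.diff(mua_grid) <= 0) or np.any(np.diff(musp_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    f1, f2 = float(f_pair[0]), float(f_pair[1])
    provenance = {
        "seed": table.config.seed,
        "n_photons": table.config.n_photons,
        "g": table.config.g,
        "n_rel": table.config.n_rel,
        "musp_ref": table.config.musp_ref,
    }
    # similarity scaling over musp assumes fixed g; flag grid excursions far
    # beyond the reference scattering in the provenance rather than failing
    ratio = musp_grid / table.config.musp_ref
    if ratio.max() > 20 or ratio.min() < 0.05:
        warnings.warn("musp grid extends far from musp_ref; similarity scaling may degrade")
        provenance["scaling_warning"] = True

    n = table.config.n_photons
    rd_dc = np.empty((mua_grid.size, musp_grid.size))
    rd_ac = np.empty_like(rd_dc)
    for k, musp in enumerate(musp_grid):
        scale = table.config.musp_ref / musp
        r_scaled = table.exit_radius * scale
        l_scaled = table.path_length * scale
        j0_1 = _bessel_j0(2.0 * np.pi * f1 * r_scaled)
        j0_2 = _bessel_j0(2.0 * np.pi * f2 * r_scaled)
        for j, mua in enumerate(mua_grid):
            weights = table.exit_weight * np.exp(-mua * l_scaled)
            rd_dc[j, k] = np.dot(weights, j0_1) / n
            rd_ac[j, k] = np.dot(weights, j0_2) / n
    return LUT(
        mua_grid=mua_grid,
        musp_grid=musp_grid,
        f_pair=(f1, f2),
        rd_dc=rd_dc,
        rd_ac=rd_ac,
        provenance=provenance,
    )


def invert_rd(lut: LUT, rd_dc_map, rd_ac_map) -> OpticalPropertyMap:
    """Pixel-by-pixel inversion of (Rd_dc, Rd_ac) maps to optical properties.

    Linear interpolation over the triangulated forward image; pixels outside
    the attainable Rd region come back NaN and are flagged in ``valid``.
    """
    rd_dc_map = np.asarray(rd_dc_map, dtype=np.float64)
    rd_ac_map = np.asarray(rd_ac_map, dtype=np.float64)
    if rd_dc_map.shape != rd_ac_map.shape:
        raise ValueError(
            f"rd_dc and rd_ac shapes differ: {rd_dc_map.shape} vs {rd_ac_map.shape}"
        )
    interp = lut._inverse_interpolator()
    pts = np.column_stack([rd_dc_map.ravel(), rd_ac_map.ravel()])
    finite = np.all(np.isfinite(pts), axis=1)
    out = np.full((pts.shape[0], 2), np.nan)
    if finite.any():
        out[finite] = interp(pts[finite])
    mua = out[:, 0].reshape(rd_dc_map.shape)
    musp = out[:, 1].reshape(rd_dc_map.shape)
    valid = np.isfinite(mua) & np.isfinite(musp)
    if not valid.any():
        warnings.warn("all pixels fell outside the attainable Rd region")
    return OpticalPropertyMap(mua=mua, musp=musp, valid=valid)
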