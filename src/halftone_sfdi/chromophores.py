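"""Beer's-law chromophore unmixing from multi-wavelength absorption maps.

Per pixel, absorption is a linear mixture of chromophore contributions,
``mua(lambda) = sum_c eps_c(lambda) * conc_c``.  With as many wavelengths as
chromophores the system is solved exactly; with more it is solved by
ordinary least squares.  Negative concentrations are reported as-is and
flagged, never silently clipped.  Derived hemodynamic indices: total
hemoglobin THb = HbO2 + HHb and saturation StO2 = HbO2 / THb.

A packaged extinction resource (`load_hemoglobin_extinction`) carries
oxy-/deoxy-hemoglobin coefficients at 470-850 nm in mm^-1 per uM,
converted from the standard tabulated molar extinction compilation
(e_mm_uM = e_cm_M * ln(10) * 1e-7); users may substitute their own table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExtinctionTable",
    "ChromophoreMap",
    "unmix",
    "derived_indices",
    "load_hemoglobin_extinction",
    "single_chromophore_table",
]


@dataclass
class ExtinctionTable:
    """Extinction coefficients: rows = wavelengths (nm), cols = chromophores.

    ``epsilon`` is in mm^-1 per uM for hemoglobins (or mm^-1 per arbitrary
    concentration unit for dyes).
    """

    wavelengths: np.ndarray
    chromophores: list
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.atleast_1d(np.asarray(self.wavelengths, dtype=np.float64))
        self.epsilon = np.atleast_2d(np.asarray(self.epsilon, dtype=np.float64))
        if self.epsilon.shape != (self.wavelengths.size, len(self.chromophores)):
            raise ValueError("epsilon must be (n_wavelengths, n_chromophores)")

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        """Read a long-format CSV with columns wavelength_nm, chromophore, epsilon."""
        df = pd.read_csv(path)
        wide = df.pivot_table(index="wavelength_nm", columns="chromophore", values="epsilon")
        return cls(
            wavelengths=wide.index.to_numpy(float),
            chromophores=list(wide.columns),
            epsilon=wide.to_numpy(float),
        )

    def to_csv(self, path) -> None:
        rows = [
            {"wavelength_nm": wl, "chromophore": c, "epsilon": self.epsilon[i, j]}
            for i, wl in enumerate(self.wavelengths)
            for j, c in enumerate(self.chromophores)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def subset(self, wavelengths, chromophores=None) -> "ExtinctionTable":
        """Rows at the requested wavelengths (exact match), optional column subset."""
        wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=np.float64))
        idx = []
        for wl in wavelengths:
            hits = np.nonzero(np.isclose(self.wavelengths, wl, atol=1e-6))[0]
            if hits.size == 0:
                raise ValueError(f"wavelength {wl} nm not in extinction table")
            idx.append(hits[0])
        chroms = list(chromophores) if chromophores is not None else list(self.chromophores)
        cidx = [self.chromophores.index(c) for c in chroms]
        return ExtinctionTable(
            wavelengths=self.wavelengths[idx],
            chromophores=chroms,
            epsilon=self.epsilon[np.ix_(idx, cidx)],
        )


@dataclass
class ChromophoreMap:
    """Unmixed concentration maps (rows, cols, n_chromophores), in uM for
    hemoglobins.  ``negative`` flags pixels with any negative concentration;
    ``thb``/``sto2`` are set when both HbO2 and HHb are present."""

    conc: np.ndarray
    chromophores: list
    negative: np.ndarray
    thb: np.ndarray | None = None
    sto2: np.ndarray | None = None


def load_hemoglobin_extinction() -> ExtinctionTable:
    """Packaged oxy-/deoxy-hemoglobin extinction table, 470-850 nm."""
    with resources.files("halftone_sfdi").joinpath("data/hemoglobin_extinction.csv").open() as f:
        return ExtinctionTable.from_csv(f)


def single_chromophore_table(name: str, wavelengths, epsilon=1.0) -> ExtinctionTable:
    """One-dye table (e.g., nigrosin) with per-wavelength coefficients; a
    scalar ``epsilon`` gives concentrations in mua-proportional units."""
    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=np.float64))
    eps = np.broadcast_to(np.asarray(epsilon, dtype=np.float64), wavelengths.shape)
    return ExtinctionTable(wavelengths=wavelengths, chromophores=[name], epsilon=eps[:, None])


def unmix(mua_maps, table: ExtinctionTable, chromophores=None, wavelengths=None) -> ChromophoreMap:
    """Solve eps @ c = mua per pixel across wavelengths.

    ``mua_maps`` is an array (n_wavelengths, rows, cols) ordered like
    ``wavelengths`` (default: the table's rows).  Square systems are solved
    exactly, overdetermined ones by least squares; a rank-deficient
    extinction matrix is an error.  Pixels with non-finite mua come back NaN.
    """
    mua_maps = np.asarray(mua_maps, dtype=np.float64)
    if mua_maps.ndim == 2:
        mua_maps = mua_maps[None]
    if wavelengths is not None or chromophores is not None:
        table = table.subset(
            wavelengths if wavelengths is not None else table.wavelengths, chromophores
        )
    eps = table.epsilon
    n_wl, n_c = eps.shape
    if mua_maps.shape[0] != n_wl:
        raise ValueError(
            f"got {mua_maps.shape[0]} mua maps for {n_wl} table wavelengths"
        )
    if n_wl < n_c:
        raise ValueError("need at least as many wavelengths as chromophores")
    if np.linalg.matrix_rank(eps) < n_c:
        raise ValueError("extinction matrix is rank deficient; cannot unmix")
    rows, cols = mua_maps.shape[1:]
    flat = mua_maps.reshape(n_wl, -1)
    finite = np.all(np.isfinite(flat), axis=0)
    conc = np.full((n_c, flat.shape[1]), np.nan)
    if finite.any():
        if n_wl == n_c:
            conc[:, finite] = np.linalg.solve(eps, flat[:, finite])
        else:
            conc[:, finite], *_ = np.linalg.lstsq(eps, flat[:, finite], rcond=None)
    conc = np.moveaxis(conc.reshape(n_c, rows, cols), 0, -1)
    negative = np.any(conc < 0, axis=-1)
    out = ChromophoreMap(conc=conc, chromophores=list(table.chromophores), negative=negative)
    names = [c.lower() for c in table.chromophores]
    if "hbo2" in names and "hhb" in names:
        thb, sto2 = derived_indices(
            conc[..., names.index("hbo2")], conc[..., names.index("hhb")]
        )
        out.thb, out.sto2 = thb, sto2
    return out


def derived_indices(c_hbo2, c_hhb):
    """THb = HbO2 + HHb and StO2 = HbO2/THb (NaN-flagged where THb <= 0)."""
    c_hbo2 = np.asarray(c_hbo2, dtype=np.float64)
    c_hhb = np.asarray(c_hhb, dtype=np.float64)
    thb = c_hbo2 + c_hhb
    sto2 = np.full(np.shape(thb), np.nan)
    np.divide(c_hbo2, thb, out=sto2, where=thb > 0)
    return thb, sto2
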