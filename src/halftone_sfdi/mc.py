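"""White Monte Carlo photon transport in a semi-infinite turbid medium.

The forward model behind SFDI inversion is the spatial-frequency-resolved
diffuse reflectance Rd(fx; mua, musp) of a homogeneous half-space.  A single
"white" simulation is run with zero absorption at a reference reduced
scattering ``musp_ref``; per-photon exit radius and total path length are
recorded.  Any (mua, musp) with the same anisotropy is then served by
similarity scaling — radii and path lengths scale by ``musp_ref / musp`` and
absorption enters as the Beer-Lambert factor ``exp(-mua * L)`` — so one photon
table supports an entire lookup-table grid.

Rd at spatial frequency fx is the zeroth-order Hankel transform of the
spatially resolved reflectance, evaluated per photon (no radial binning):

    Rd(fx) = (1/N) * sum_i  w_i * exp(-mua * L_i') * J0(2 pi fx r_i')

A diffusion-approximation closed form (`rd_diffusion`) is provided as an
independent oracle; it is never used in the measurement chain itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from numba import njit
from scipy.special import j0 as _bessel_j0

__all__ = [
    "OpticalProperties",
    "TransportConfig",
    "WMCTable",
    "simulate_white_mc",
    "rd_frequency",
    "rd_diffusion",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering coefficients, both in 1/mm."""

    mua: float
    musp: float

    def __post_init__(self) -> None:
        if not (self.mua >= 0):
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if not (self.musp > 0):
            raise ValueError(f"musp must be > 0, got {self.musp}")


@dataclass(frozen=True)
class TransportConfig:
    """Settings for the white Monte Carlo simulation.

    Parameters
    ----------
    g : scattering anisotropy of the Henyey-Greenstein phase function.
    n_rel : refractive index of the medium relative to the ambient above it.
    n_photons : number of photons launched.
    seed : PRNG seed; identical configs give bit-identical tables.
    musp_ref : reduced scattering at which the white simulation is run, 1/mm.
        Similarity scaling maps the table to any other musp at the same g.
    max_path_mm : cap on the total path travelled per photon (in the
        reference medium's units).  Without absorption the return-path
        distribution in a half-space is heavy-tailed (Levy first passage),
        so a truncation is required for finite runtime; capped photons are
        recorded at their current radius with the capped path, which keeps
        energy conservation exact while the downstream Beer-Lambert factor
        exp(-mua * L) renders their misplacement negligible for any
        absorption of practical interest (see the truncation-bias note in
        the package docs).
    max_steps : additional safety cap on scattering events per photon.
    """

    g: float = 0.9
    n_rel: float = 1.4
    n_photons: int = 1_000_000
    seed: int = 0
    musp_ref: float = 1.0
    max_path_mm: float = 5000.0
    max_steps: int = 10_000_000

    def __post_init__(self) -> None:
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"anisotropy g must be in (-1, 1), got {self.g}")
        if not (self.n_rel >= 1.0):
            raise ValueError(f"n_rel must be >= 1, got {self.n_rel}")
        if not (self.n_photons >= 1):
            raise ValueError(f"n_photons must be >= 1, got {self.n_photons}")
        if not (self.musp_ref > 0):
            raise ValueError(f"musp_ref must be > 0, got {self.musp_ref}")
        if not (self.max_path_mm > 0):
            raise ValueError(f"max_path_mm must be > 0, got {self.max_path_mm}")


@dataclass
class WMCTable:
    """Per-photon exit records of a white Monte Carlo run.

    ``exit_radius`` is the distance from the pencil-beam axis at which the
    photon left the medium (mm), ``path_length`` the total distance travelled
    inside the medium (mm), and ``exit_weight`` the residual photon weight
    (unity here: boundary reflection is decided probabilistically, so photons
    exit whole).  ``n_truncated`` counts photons recorded at the path cap
    rather than at a true boundary crossing.
    """

    exit_radius: np.ndarray
    path_length: np.ndarray
    exit_weight: np.ndarray
    config: TransportConfig
    n_truncated: int = 0

    def __post_init__(self) -> None:
        self.exit_radius = np.asarray(self.exit_radius, dtype=np.float64)
        self.path_length = np.asarray(self.path_length, dtype=np.float64)
        self.exit_weight = np.asarray(self.exit_weight, dtype=np.float64)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("radius", data=self.exit_radius)
            f.create_dataset("pathlength", data=self.path_length)
            f.create_dataset("weight", data=self.exit_weight)
            f.attrs["g"] = self.config.g
            f.attrs["n_rel"] = self.config.n_rel
            f.attrs["n_photons"] = self.config.n_photons
            f.attrs["seed"] = self.config.seed
            f.attrs["musp_ref"] = self.config.musp_ref
            f.attrs["max_path_mm"] = self.config.max_path_mm
            f.attrs["max_steps"] = self.config.max_steps
            f.attrs["n_truncated"] = self.n_truncated

    @classmethod
    def load(cls, path) -> "WMCTable":
        with h5py.File(path, "r") as f:
            config = TransportConfig(
                g=float(f.attrs["g"]),
                n_rel=float(f.attrs["n_rel"]),
                n_photons=int(f.attrs["n_photons"]),
                seed=int(f.attrs["seed"]),
                musp_ref=float(f.attrs["musp_ref"]),
                max_path_mm=float(f.attrs["max_path_mm"]),
                max_steps=int(f.attrs["max_steps"]),
            )
            return cls(
                exit_radius=f["radius"][:],
                path_length=f["pathlength"][:],
                exit_weight=f["weight"][:],
                config=config,
                n_truncated=int(f.attrs["n_truncated"]),
            )


@njit(cache=False)
def _mc_kernel(n_photons, g, n_rel, musp_ref, seed, max_path, max_steps, z_switch):  # pragma: no cover - jitted
    np.random.seed(seed)
    mus_hg = musp_ref / (1.0 - g) if g != 0.0 else musp_ref
    mus_iso = musp_ref
    out_r = np.empty(n_photons, dtype=np.float64)
    out_l = np.empty(n_photons, dtype=np.float64)
    out_w = np.empty(n_photons, dtype=np.float64)
    n_exit = 0
    n_trunc = 0
    # critical-angle cosine for total internal reflection (medium -> ambient)
    if n_rel > 1.0:
        cos_crit = np.sqrt(1.0 - 1.0 / (n_rel * n_rel))
    else:
        cos_crit = 0.0
    eps = 1e-12
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        path = 0.0
        steps = 0
        alive = True
        deep = False  # zone flag, toggled only at switch-plane crossings
        tau = -np.log(np.random.random())  # optical depth to next scattering
        while alive:
            # below z_switch the walk is accelerated by first-order
            # similarity: isotropic scattering at musp_ref instead of
            # Henyey-Greenstein at musp_ref/(1-g); same transport
            # coefficient, ~1/(1-g) fewer steps per unit path.  Optical
            # depth is converted rigorously at the switch plane.
            mu = mus_iso if deep else mus_hg
            s = tau / mu
            # distance to the top boundary along the current direction
            d_bound = (-z / uz) if uz < -eps else 1e30
            # distance to the similarity switch plane (toward it only)
            if (not deep and uz > eps) or (deep and uz < -eps):
                d_switch = (z_switch - z) / uz
                if d_switch < 0.0:
                    d_switch = 0.0
            else:
                d_switch = 1e30
            if s <= d_bound and s <= d_switch:
                # scattering event
                x += ux * s
                y += uy * s
                z += uz * s
                path += s
                if path >= max_path:
                    # heavy-tailed return paths: record at the cap
                    # (conserves energy; exp(-mua*L) suppresses the
                    # contribution for any absorption of interest)
                    out_r[n_exit] = np.sqrt(x * x + y * y)
                    out_l[n_exit] = path
                    out_w[n_exit] = 1.0
                    n_exit += 1
                    n_trunc += 1
                    break
                u = np.random.random()
                if deep or g == 0.0:
                    cost = 2.0 * u - 1.0
                else:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
                sint = np.sqrt(1.0 - cost * cost)
                phi = 2.0 * np.pi * np.random.random()
                cosp = np.cos(phi)
                sinp = np.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz >= 0.0 else -cost
                else:
                    denom = np.sqrt(1.0 - uz * uz)
                    ux_n = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                    uy_n = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                    uz_n = -sint * cosp * denom + uz * cost
                    ux, uy, uz = ux_n, uy_n, uz_n
                tau = -np.log(np.random.random())
                steps += 1
                if steps >= max_steps:
                    out_r[n_exit] = np.sqrt(x * x + y * y)
                    out_l[n_exit] = path
                    out_w[n_exit] = 1.0
                    n_exit += 1
                    n_trunc += 1
                    break
            elif d_bound <= d_switch:
                # top boundary: Fresnel reflect or exit
                x += ux * d_bound
                y += uy * d_bound
                path += d_bound
                tau -= d_bound * mu
                z = 0.0
                cos_i = -uz
                if n_rel == 1.0:
                    refl = 0.0
                elif cos_i < cos_crit:
                    refl = 1.0
                else:
                    sin_i = np.sqrt(1.0 - cos_i * cos_i)
                    sin_t = n_rel * sin_i
                    cos_t = np.sqrt(1.0 - sin_t * sin_t)
                    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
                    rp = (cos_i - n_rel * cos_t) / (cos_i + n_rel * cos_t)
                    refl = 0.5 * (rs * rs + rp * rp)
                if np.random.random() < refl:
                    uz = -uz
                else:
                    out_r[n_exit] = np.sqrt(x * x + y * y)
                    out_l[n_exit] = path
                    out_w[n_exit] = 1.0
                    n_exit += 1
                    alive = False
            else:
                # crossed the similarity switch plane: convert remaining
                # optical depth at the new scattering rate next iteration
                x += ux * d_switch
                y += uy * d_switch
                z += uz * d_switch
                path += d_switch
                tau -= d_switch * mu
                if tau < eps:
                    tau = eps
                deep = not deep
    return out_r[:n_exit], out_l[:n_exit], out_w[:n_exit], n_trunc


def simulate_white_mc(config: TransportConfig) -> WMCTable:
    """Run the white (zero-absorption) Monte Carlo simulation.

    A pencil beam enters normally at the origin of a semi-infinite medium
    with reduced scattering ``config.musp_ref`` and Henyey-Greenstein
    anisotropy ``config.g``.  The top boundary applies unpolarized Fresnel
    reflection for relative index ``config.n_rel``; whether a boundary hit
    reflects or transmits is decided probabilistically, so each remitted
    photon produces exactly one record with unit weight.  Deterministic for a
    given config (single-threaded, seeded).
    """
    if not isinstance(config, TransportConfig):
        raise TypeError("config must be a TransportConfig")
    # similarity-acceleration switch depth: 15 transport mean free paths,
    # comfortably inside the diffusive regime
    z_switch = 15.0 / config.musp_ref
    r, l, w, n_trunc = _mc_kernel(
        config.n_photons,
        float(config.g),
        float(config.n_rel),
        float(config.musp_ref),
        int(config.seed),
        float(config.max_path_mm),
        int(config.max_steps),
        z_switch,
    )
    return WMCTable(exit_radius=r, path_length=l, exit_weight=w, config=config, n_truncated=n_trunc)


def rd_frequency(table: WMCTable, props: OpticalProperties, fx) -> float | np.ndarray:
    """Diffuse reflectance Rd(fx) for arbitrary (mua, musp) from a white table.

    Similarity scaling: radii and path lengths are multiplied by
    ``musp_ref / musp``; absorption is applied as ``exp(-mua * L')``; the
    Hankel kernel ``J0(2 pi fx r')`` is evaluated per photon.  ``fx`` may be
    a scalar or an array of spatial frequencies (1/mm).
    """
    if not isinstance(props, OpticalProperties):
        props = OpticalProperties(*props)
    fx_arr = np.atleast_1d(np.asarray(fx, dtype=np.float64))
    if np.any(fx_arr < 0):
        raise ValueError("spatial frequency fx must be >= 0")
    scale = table.config.musp_ref / props.musp
    r_scaled = table.exit_radius * scale
    l_scaled = table.path_length * scale
    weights = table.exit_weight * np.exp(-props.mua * l_scaled)
    n = table.config.n_photons
    out = np.empty(fx_arr.shape, dtype=np.float64)
    for i, f in enumerate(fx_arr):
        out[i] = np.dot(weights, _bessel_j0(2.0 * np.pi * f * r_scaled)) / n
    if np.isscalar(fx) or np.ndim(fx) == 0:
        return float(out[0])
    return out


def rd_diffusion(props: OpticalProperties, fx, n_rel: float = 1.4) -> float | np.ndarray:
    """Semi-infinite diffusion-approximation Rd(fx), the closed-form oracle.

    Standard SFDI diffusion solution for a spatially modulated planar source
    on a half-space with extrapolated-boundary constant A obtained from the
    effective reflection coefficient of the relative index:

        mutr   = mua + musp,    a' = musp / mutr
        mueff  = sqrt(3 mua mutr)
        mueff' = sqrt(mueff^2 + (2 pi fx)^2)
        Reff   = 0.0636 n + 0.668 + 0.710/n - 1.440/n^2
        A      = (1 - Reff) / (2 (1 + Reff))
        Rd     = 3 A a' / ((mueff'/mutr + 1) (mueff'/mutr + 3A))

    Valid in the transport-dominated regime (musp >> mua).
    """
    if not isinstance(props, OpticalProperties):
        props = OpticalProperties(*props)
    fx_arr = np.asarray(fx, dtype=np.float64)
    if np.any(fx_arr < 0):
        raise ValueError("spatial frequency fx must be >= 0")
    mutr = props.mua + props.musp
    a_prime = props.musp / mutr
    mueff = np.sqrt(3.0 * props.mua * mutr)
    mueff_p = np.sqrt(mueff**2 + (2.0 * np.pi * fx_arr) ** 2)
    n = n_rel
    reff = 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2
    a_const = (1.0 - reff) / (2.0 * (1.0 + reff))
    rd = 3.0 * a_const * a_prime / ((mueff_p / mutr + 1.0) * (mueff_p / mutr + 3.0 * a_const))
    if np.ndim(fx) == 0:
        return float(rd)
    return rd
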