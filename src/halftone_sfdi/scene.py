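"""Virtual turbid-medium measurement generator.

Renders the raw camera frames an SFDI instrument would record for a scene of
per-pixel optical properties under a given illumination pattern, so every
downstream stage (demodulation, calibration, LUT inversion, unmixing) can be
exercised without hardware.

Rendering model: the pattern is decomposed by 2-D FFT and every spatial
frequency component is attenuated by the medium's diffuse reflectance
Rd(|f|).  Scenes are piecewise-constant in properties; each homogeneous
region is rendered as if the whole field had its properties, and the
regions are composited.  This matches the pixelwise-homogeneous assumption
of LUT inversion itself; behavior within a transport length of a property
boundary is approximate.  Camera signal is ``gain * radiance`` with
optional shot (Poisson) and Gaussian read noise, all seeded.

Scene factories emulate the validation experiments: a 4x4 phantom array
spanning mua 0.005-0.04 /mm and musp 0.3-2 /mm, a vessel-on-tissue stripe
with optional periodic physiological modulation, and a dynamic flow field
in which an injected absorbing/scattering blob advects across the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .demod import FrameSequence
from .mc import OpticalProperties, WMCTable, rd_frequency
from .patterns import PatternImage, pattern_sequence

__all__ = [
    "Scene",
    "NoiseModel",
    "make_phantom_array_scene",
    "make_vessel_scene",
    "make_flow_scene",
    "phantom_tile_slices",
    "render_frame",
    "render_sequence",
    "render_time_series",
]

# regions cap: rendering is per unique property pair, so scenes must be
# piecewise constant; a scene with per-pixel-unique properties is rejected
MAX_REGIONS = 64

# node ratio of the geometric spatial-frequency grid on which Rd(|f|) is
# evaluated exactly before cubic-spline interpolation onto the FFT grid
_CURVE_RATIO = 1.2


@dataclass
class Scene:
    """Per-pixel optical properties per wavelength on a square-pixel grid.

    ``mua`` and ``musp`` have shape (rows, cols, n_wavelengths) in 1/mm;
    ``pixel_pitch`` is mm per pixel.  ``time_course`` optionally holds one
    Scene per raw camera frame for dynamic experiments.
    """

    mua: np.ndarray
    musp: np.ndarray
    wavelengths: np.ndarray
    pixel_pitch: float
    time_course: list | None = None

    def __post_init__(self) -> None:
        self.mua = np.atleast_3d(np.asarray(self.mua, dtype=np.float64))
        self.musp = np.atleast_3d(np.asarray(self.musp, dtype=np.float64))
        self.wavelengths = np.atleast_1d(np.asarray(self.wavelengths, dtype=np.float64))
        if self.mua.shape != self.musp.shape:
            raise ValueError("mua and musp must share a shape")
        if self.mua.shape[2] != self.wavelengths.size:
            raise ValueError("third axis must match number of wavelengths")
        if not (self.pixel_pitch > 0):
            raise ValueError("pixel_pitch must be > 0")

    @property
    def shape(self):
        return self.mua.shape[:2]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mua", data=self.mua)
            f.create_dataset("musp", data=self.musp)
            f.create_dataset("wavelengths", data=self.wavelengths)
            f.attrs["pixel_pitch"] = self.pixel_pitch

    @classmethod
    def load(cls, path) -> "Scene":
        with h5py.File(path, "r") as f:
            return cls(
                mua=f["mua"][:],
                musp=f["musp"][:],
                wavelengths=f["wavelengths"][:],
                pixel_pitch=float(f.attrs["pixel_pitch"]),
            )


@dataclass(frozen=True)
class NoiseModel:
    """Camera model: counts = gain * reflectance, shot + read noise.

    Defaults give a planar-frame shot-noise SNR above 200 for mid-range
    reflectance (counts ~ gain * Rd(0) ~ 5e4 .. 1e5).
    """

    read_noise_sd: float = 10.0
    shot_noise: bool = True
    gain: float = 2.0e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.gain < 0:
            raise ValueError("noise parameters must be non-negative")


def phantom_tile_slices(shape, n_rows: int = 4, n_cols: int = 4):
    """Row/col slices of each tile of the phantom-array scene, row-major."""
    rows, cols = shape
    r_edges = np.linspace(0, rows, n_rows + 1).astype(int)
    c_edges = np.linspace(0, cols, n_cols + 1).astype(int)
    return [
        (slice(r_edges[i], r_edges[i + 1]), slice(c_edges[j], c_edges[j + 1]))
        for i in range(n_rows)
        for j in range(n_cols)
    ]


def make_phantom_array_scene(
    n_rows: int = 4,
    n_cols: int = 4,
    mua_range=(0.005, 0.04),
    musp_range=(0.3, 2.0),
    shape=(400, 400),
    wavelengths=(650.0, 700.0, 750.0, 800.0, 850.0),
    pixel_pitch: float = 0.05,
    scatter_power: float = 0.6,
) -> Scene:
    """Tiled phantom-array scene spanning the requested property ranges.

    Absorption varies across columns and reduced scattering down rows, both
    linearly including the range endpoints, giving ``n_rows * n_cols``
    distinct property pairs at the first (reference) wavelength.  Reduced
    scattering follows a power law ``(lambda/lambda_ref)^-scatter_power``
    across wavelengths, as for TiO2-in-silicone phantoms; absorption is kept
    spectrally flat (the dye spectrum is not modeled).
    """
    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=np.float64))
    mua_vals = np.linspace(*mua_range, n_cols)
    musp_vals = np.linspace(*musp_range, n_rows)
    rows, cols = shape
    mua2d = np.empty(shape)
    musp2d = np.empty(shape)
    tiles = phantom_tile_slices(shape, n_rows, n_cols)
    for t, (rs, cs) in enumerate(tiles):
        i, j = divmod(t, n_cols)
        mua2d[rs, cs] = mua_vals[j]
        musp2d[rs, cs] = musp_vals[i]
    spectral = (wavelengths / wavelengths[0]) ** (-scatter_power)
    mua = np.repeat(mua2d[:, :, None], wavelengths.size, axis=2)
    musp = musp2d[:, :, None] * spectral[None, None, :]
    return Scene(mua=mua, musp=musp, wavelengths=wavelengths, pixel_pitch=pixel_pitch)


def make_vessel_scene(
    background_props: OpticalProperties,
    vessel_props: OpticalProperties,
    vessel_width: float,
    shape=(200, 200),
    wavelengths=(685.0,),
    pixel_pitch: float = 0.05,
    modulation_rate: float | None = None,
    modulation_amplitude: float = 0.1,
    frame_rate: float = 15.0,
    n_frames: int = 0,
) -> Scene:
    """Straight absorbing stripe (a vessel) on a homogeneous background.

    The vertical stripe of width ``vessel_width`` (mm) is centered in the
    field.  With ``modulation_rate`` (Hz) set and ``n_frames > 0``, a
    time_course is attached in which the vessel absorption is modulated
    sinusoidally by the fractional ``modulation_amplitude`` at that rate,
    emulating a periodic physiological signal sampled at ``frame_rate``.
    """
    rows, cols = shape
    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=np.float64))
    half_px = 0.5 * vessel_width / pixel_pitch
    center = (cols - 1) / 2.0
    stripe = np.abs(np.arange(cols) - center) < half_px

    def build(vessel_mua):
        mua2d = np.full(shape, background_props.mua)
        musp2d = np.full(shape, background_props.musp)
        mua2d[:, stripe] = vessel_mua
        musp2d[:, stripe] = vessel_props.musp
        mua = np.repeat(mua2d[:, :, None], wavelengths.size, axis=2)
        musp = np.repeat(musp2d[:, :, None], wavelengths.size, axis=2)
        return Scene(mua=mua, musp=musp, wavelengths=wavelengths, pixel_pitch=pixel_pitch)

    scene = build(vessel_props.mua)
    if modulation_rate is not None and n_frames > 0:
        t = np.arange(n_frames) / frame_rate
        series = vessel_props.mua * (
            1.0 + modulation_amplitude * np.sin(2.0 * np.pi * modulation_rate * t)
        )
        scene.time_course = [build(v) for v in series]
    return scene


def make_flow_scene(
    shape=(100, 140),
    n_frames: int = 50,
    background_props: OpticalProperties = OpticalProperties(0.005, 0.5),
    blob_props: OpticalProperties = OpticalProperties(0.03, 1.5),
    blob_radius: float = 0.8,
    wavelengths=(470.0, 625.0),
    pixel_pitch: float = 0.025,
    speed: float = 0.06,
) -> Scene:
    """Dynamic flow-field scene: an injected blob advecting across the well.

    A disk of elevated absorption and scattering (the injected dye/lipid
    bolus) moves ``speed`` mm per frame across a homogeneous liquid-phantom
    background, and its radius grows slowly as it disperses.  One Scene per
    raw camera frame is stored in ``time_course``.
    """
    rows, cols = shape
    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=np.float64))
    yy, xx = np.mgrid[0:rows, 0:cols]
    frames = []
    for k in range(n_frames):
        cx = (0.15 * cols + k * speed / pixel_pitch) % cols
        cy = rows / 2.0 + 0.15 * rows * np.sin(2.0 * np.pi * k / max(n_frames, 1))
        radius_px = (blob_radius + 0.004 * k) / pixel_pitch
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 < radius_px**2
        mua2d = np.full(shape, background_props.mua)
        musp2d = np.full(shape, background_props.musp)
        mua2d[disk] = blob_props.mua
        musp2d[disk] = blob_props.musp
        mua = np.repeat(mua2d[:, :, None], wavelengths.size, axis=2)
        musp = np.repeat(musp2d[:, :, None], wavelengths.size, axis=2)
        frames.append(
            Scene(mua=mua, musp=musp, wavelengths=wavelengths, pixel_pitch=pixel_pitch)
        )
    scene = replace(frames[0])
    scene.time_course = frames
    return scene


def _rd_curve(table: WMCTable, props: OpticalProperties, f_max: float) -> CubicSpline:
    """Cubic-spline model of Rd(f) for one homogeneous medium, cached on the
    photon table. Nodes are geometric (dense at low f where Rd bends)."""
    cache = getattr(table, "_rd_curve_cache", None)
    if cache is None:
        cache = {}
        table._rd_curve_cache = cache
    key = (float(props.mua), float(props.musp), round(float(f_max), 9))
    if key not in cache:
        f_lo = 1e-2
        n_nodes = int(np.ceil(np.log(f_max / f_lo) / np.log(_CURVE_RATIO))) + 1
        nodes = np.concatenate(([0.0], np.geomspace(f_lo, f_max, n_nodes)))
        rd = rd_frequency(table, props, nodes)
        cache[key] = CubicSpline(nodes, rd)
    return cache[key]


def _region_labels(mua2d, musp2d):
    pairs = np.stack([mua2d.ravel(), musp2d.ravel()], axis=1)
    uniq, labels = np.unique(pairs, axis=0, return_inverse=True)
    return uniq, labels.reshape(mua2d.shape)


def render_frame(
    scene: Scene,
    pattern: PatternImage,
    table: WMCTable,
    noise: NoiseModel | None = None,
    wavelength_index: int = 0,
    rng: np.random.Generator | None = None,
    psf_sigma_mm: float | None = None,
) -> np.ndarray:
    """Render one raw camera frame (float counts) for a scene and pattern.

    The pattern spectrum is attenuated by Rd(|f|) of each homogeneous
    region and the per-region renders are composited.  ``psf_sigma_mm``
    optionally applies a Gaussian instrument blur to the radiance (off by
    default).  With a NoiseModel, shot and read noise are drawn from ``rng``
    (or a generator seeded with ``noise.seed``).
    """
    if pattern.values.shape != scene.shape:
        raise ValueError(
            f"pattern shape {pattern.values.shape} != scene shape {scene.shape}"
        )
    mua2d = scene.mua[:, :, wavelength_index]
    musp2d = scene.musp[:, :, wavelength_index]
    uniq, labels = _region_labels(mua2d, musp2d)
    if uniq.shape[0] > MAX_REGIONS:
        raise ValueError(
            f"scene has {uniq.shape[0]} distinct property regions (max {MAX_REGIONS}); "
            "rendering assumes piecewise-constant scenes"
        )
    ratio = uniq[:, 1] / table.config.musp_ref
    bad = (uniq[:, 0] < 0) | (uniq[:, 1] <= 0) | (ratio > 50) | (ratio < 0.02)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"region {i} (mua={uniq[i, 0]:.4g}, musp={uniq[i, 1]:.4g}) is outside "
            "the forward model's validity"
        )
    rows, cols = scene.shape
    d = scene.pixel_pitch
    fr = np.fft.fftfreq(rows, d=d)
    fc = np.fft.fftfreq(cols, d=d)
    f_abs = np.sqrt(fr[:, None] ** 2 + fc[None, :] ** 2)
    f_max = float(f_abs.max()) * 1.0001
    spectrum = np.fft.fft2(pattern.values)
    radiance = np.empty((rows, cols))
    for i, (mua, musp) in enumerate(uniq):
        curve = _rd_curve(table, OpticalProperties(mua, musp), f_max)
        h = np.clip(curve(f_abs), 0.0, None)
        region = np.fft.ifft2(spectrum * h).real
        mask = labels == i
        radiance[mask] = region[mask]
    np.clip(radiance, 0.0, None, out=radiance)
    if psf_sigma_mm is not None:
        radiance = gaussian_filter(radiance, sigma=psf_sigma_mm / d)
    if noise is None:
        return radiance
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    signal = noise.gain * radiance
    if noise.shot_noise:
        signal = rng.poisson(signal).astype(np.float64)
    if noise.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, noise.read_noise_sd, size=signal.shape)
    return signal


def render_sequence(
    scene: Scene,
    patterns: list,
    table: WMCTable,
    noise: NoiseModel | None = None,
    wavelength_index: int = 0,
    wavelength: float | None = None,
    fx: float = 0.0,
    rng: np.random.Generator | None = None,
) -> FrameSequence:
    """Render a 5-pattern sequence [planar, dark, 3 phases] to a FrameSequence.

    Noise realizations are independent across frames but reproducible: a
    fresh generator is seeded from ``noise.seed`` unless ``rng`` is given.
    """
    if len(patterns) != 5:
        raise ValueError(f"expected 5 patterns (planar, dark, 3 phases), got {len(patterns)}")
    if noise is not None and rng is None:
        rng = np.random.default_rng(noise.seed)
    frames = [
        render_frame(scene, p, table, noise=noise, wavelength_index=wavelength_index, rng=rng)
        for p in patterns
    ]
    if wavelength is None:
        wavelength = float(scene.wavelengths[wavelength_index])
    return FrameSequence(
        planar=frames[0],
        dark=frames[1],
        phase1=frames[2],
        phase2=frames[3],
        phase3=frames[4],
        wavelength=wavelength,
        fx=fx,
    )


def render_time_series(
    scene: Scene,
    fx: float,
    table: WMCTable,
    noise: NoiseModel | None = None,
    halftone: bool = False,
) -> list:
    """Render a dynamic scene's time_course into per-time FrameSequences.

    The time_course holds one Scene per raw camera frame (the flow advances
    between every projected pattern, emulating continuous acquisition); each
    consecutive block of 5 frames x n_wavelengths forms one time point.
    Returns a list over time points of {wavelength: FrameSequence}.
    """
    if scene.time_course is None:
        raise ValueError("scene has no time_course; use render_sequence for static scenes")
    n_wl = scene.wavelengths.size
    per_point = 5 * n_wl
    n_points = len(scene.time_course) // per_point
    pats = pattern_sequence(
        [0.0], fx, scene.shape, scene.pixel_pitch, halftone=halftone
    )  # identical pattern set for every wavelength
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    out = []
    k = 0
    for _t in range(n_points):
        point = {}
        for w in range(n_wl):
            frames = []
            for p in pats:
                frames.append(
                    render_frame(
                        scene.time_course[k], p, table,
                        noise=noise, wavelength_index=w, rng=rng,
                    )
                )
                k += 1
            point[float(scene.wavelengths[w])] = FrameSequence(
                planar=frames[0], dark=frames[1],
                phase1=frames[2], phase2=frames[3], phase3=frames[4],
                wavelength=float(scene.wavelengths[w]), fx=fx,
            )
        out.append(point)
    return out
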