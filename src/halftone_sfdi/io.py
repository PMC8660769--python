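"""Shared readers/writers and the end-to-end processing pipeline.

Interchange formats: multi-page TIFF for frame stacks and maps (page order
is fragile, so a JSON manifest always travels with a stack), HDF5 for photon
tables / LUTs / scenes, CSV for small tables.  `run_pipeline` chains
demodulation -> calibration -> LUT inversion -> (optional) chromophore
unmixing and writes every intermediate plus a provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .chromophores import ExtinctionTable, unmix
from .demod import FrameSequence, calibrate, dark_correct, demodulate_ac
from .lut import LUT, OpticalPropertyMap, invert_rd
from .mc import OpticalProperties, WMCTable, rd_frequency

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_frames", "write_frames", "write_maps", "run_pipeline"]

FRAME_KINDS = ["planar", "dark", "phase0", "phase120", "phase240"]


@dataclass
class RunConfig:
    """File paths and parameters for one pipeline run."""

    frames: str
    manifest: str
    phantom_frames: str
    phantom_manifest: str
    table: str
    lut: str
    phantom_props: str  # CSV: wavelength_nm, mua, musp
    out_dir: str
    extinction: str | None = None  # CSV; enables unmixing when >= 2 wavelengths
    chromophores: list | None = None
    dark_subtract_all: bool = False
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def write_frames(path, manifest_path, sequences: dict) -> None:
    """Write {wavelength: FrameSequence} as a multi-page TIFF + JSON manifest.

    Page order is wavelength-major with frames [planar, dark, phase0,
    phase120, phase240] per wavelength, and is recorded in the manifest.
    """
    wavelengths = sorted(sequences)
    pages = []
    entries = []
    for wl in wavelengths:
        seq = sequences[wl]
        for kind, frame in zip(FRAME_KINDS, seq.frames):
            pages.append(np.asarray(frame, dtype=np.float32))
            entries.append({"wavelength_nm": float(wl), "kind": kind, "fx_per_mm": float(seq.fx)})
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    Path(manifest_path).write_text(json.dumps({"frames": entries}, indent=1))


def read_frames(path, manifest_path) -> dict:
    """Read a frame stack back into {wavelength: FrameSequence}.

    Fails fast when a wavelength is missing one of the five frame kinds,
    naming the missing pattern.
    """
    manifest = json.loads(Path(manifest_path).read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    entries = manifest["frames"]
    if len(entries) != pages.shape[0]:
        raise ValueError(
            f"manifest lists {len(entries)} frames but stack has {pages.shape[0]} pages"
        )
    grouped: dict = {}
    for entry, page in zip(entries, pages):
        wl = float(entry["wavelength_nm"])
        grouped.setdefault(wl, {})[entry["kind"]] = (
            np.asarray(page, dtype=np.float64),
            float(entry.get("fx_per_mm", 0.0)),
        )
    out = {}
    for wl, frames in grouped.items():
        missing = [k for k in FRAME_KINDS if k not in frames]
        if missing:
            raise ValueError(f"wavelength {wl} nm is missing frame(s): {', '.join(missing)}")
        fx = frames["phase0"][1]
        out[wl] = FrameSequence(
            planar=frames["planar"][0],
            dark=frames["dark"][0],
            phase1=frames["phase0"][0],
            phase2=frames["phase120"][0],
            phase3=frames["phase240"][0],
            wavelength=wl,
            fx=fx,
        )
    return out


def write_maps(maps: dict, path) -> None:
    """Write named float maps as a multi-page 32-bit TIFF + channel manifest."""
    names = list(maps)
    stack = np.stack([np.asarray(maps[n], dtype=np.float32) for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    Path(str(path) + ".json").write_text(json.dumps({"channels": names}, indent=1))


def process_sequence(
    sample: FrameSequence,
    phantom: FrameSequence,
    phantom_props: OpticalProperties,
    table: WMCTable,
    lut: LUT,
    dark_subtract_all: bool = False,
):
    """Demodulate + calibrate one wavelength's sequences and invert to properties.

    DC comes from the dark-corrected planar frame; AC from three-phase
    demodulation (a common dark offset cancels there, but can optionally be
    subtracted from all frames).  Returns (rd_dc_map, rd_ac_map, props_map).
    """
    f_dc, f_ac = lut.f_pair
    if dark_subtract_all:
        s_phases = [dark_correct(f, sample.dark) for f in (sample.phase1, sample.phase2, sample.phase3)]
        p_phases = [dark_correct(f, phantom.dark) for f in (phantom.phase1, phantom.phase2, phantom.phase3)]
    else:
        s_phases = [sample.phase1, sample.phase2, sample.phase3]
        p_phases = [phantom.phase1, phantom.phase2, phantom.phase3]
    rd_model_dc = rd_frequency(table, phantom_props, f_dc)
    rd_model_ac = rd_frequency(table, phantom_props, f_ac)
    rd_dc = calibrate(
        dark_correct(sample.planar, sample.dark),
        dark_correct(phantom.planar, phantom.dark),
        rd_model_dc,
        fx=f_dc,
        wavelength=sample.wavelength,
    )
    rd_ac = calibrate(
        demodulate_ac(*s_phases),
        demodulate_ac(*p_phases),
        rd_model_ac,
        fx=f_ac,
        wavelength=sample.wavelength,
    )
    props = invert_rd(lut, rd_dc.rd, rd_ac.rd)
    return rd_dc, rd_ac, props


def run_pipeline(config: RunConfig):
    """File-driven pipeline: frames -> Rd maps -> property maps -> chromophores.

    Writes per-wavelength Rd and property maps, optional chromophore maps,
    and a provenance JSON (config hash, seed, version) into ``out_dir``.
    Returns ({wavelength: OpticalPropertyMap}, ChromophoreMap | None).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("frames", "manifest", "phantom_frames", "phantom_manifest", "table", "lut", "phantom_props"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"stage 'inputs': {name} file not found: {p}")
    samples = read_frames(config.frames, config.manifest)
    phantoms = read_frames(config.phantom_frames, config.phantom_manifest)
    table = WMCTable.load(config.table)
    lut = LUT.load(config.lut)
    props_df = pd.read_csv(config.phantom_props).set_index("wavelength_nm")

    prop_maps: dict = {}
    mua_stack = []
    wavelengths = sorted(samples)
    for wl in wavelengths:
        if wl not in phantoms:
            raise ValueError(f"stage 'calibrate': no phantom frames for {wl} nm")
        try:
            row = props_df.loc[wl]
        except KeyError:
            raise ValueError(f"stage 'calibrate': no phantom properties for {wl} nm") from None
        phantom_props = OpticalProperties(float(row["mua"]), float(row["musp"]))
        rd_dc, rd_ac, props = process_sequence(
            samples[wl], phantoms[wl], phantom_props, table, lut,
            dark_subtract_all=config.dark_subtract_all,
        )
        prop_maps[wl] = props
        mua_stack.append(props.mua)
        write_maps(
            {"rd_dc": rd_dc.rd, "rd_ac": rd_ac.rd, "mua": props.mua, "musp": props.musp,
             "valid": props.valid.astype(np.float32)},
            out_dir / f"maps_{wl:g}nm.tif",
        )

    chrom = None
    if config.extinction is not None and len(wavelengths) >= 2:
        ext = ExtinctionTable.from_csv(config.extinction)
        chrom = unmix(
            np.stack(mua_stack), ext,
            chromophores=config.chromophores, wavelengths=wavelengths,
        )
        channels = {c: chrom.conc[..., i] for i, c in enumerate(chrom.chromophores)}
        if chrom.thb is not None:
            channels["THb"] = chrom.thb
            channels["StO2"] = chrom.sto2
        write_maps(channels, out_dir / "chromophores.tif")

    provenance = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "wavelengths_nm": [float(w) for w in wavelengths],
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return prop_maps, chrom
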