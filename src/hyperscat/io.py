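"""Configuration parsing and output writers.

Configs are flat TOML key/value files with units spelled out in the key
names (radius_nm, wavelength_nm, distance_mm, ...).  Unknown keys are
rejected with a diagnostic.  1D output is three-column ASCII
(q [nm^-1], I, sigma_I placeholder 0) with a # header echoing every
parameter; 2D output is a 32-bit float TIFF plus a plain-text matrix and
a key=value sidecar that re-parses to an equivalent configuration.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import tifffile

from .distributions import OrientationDistribution, SizeDistribution
from .errors import ConfigError
from .formfactors import ShapeSpec
from .lattice import PeakShape, UnitCell
from .pattern import (
    Curve1D,
    DetectorGeometry,
    GISASFilm,
    IntensityParams,
    LatticeModel,
    Pattern2D,
)

__all__ = [
    "KNOWN_KEYS",
    "load_config",
    "apply_overrides",
    "build_run",
    "config_from_pattern",
    "write_curve1d",
    "read_curve1d",
    "write_pattern2d",
    "read_sidecar",
]

MODES = ("curve1d", "pattern2d", "gisas", "validate", "benchmark")

#: key -> (type, validator description)
KNOWN_KEYS = {
    "mode": str,
    "preset": str,
    "shape_kind": str,
    "radius_nm": float,
    "length_nm": float,
    "thickness_nm": float,
    "diameter_nm": float,
    "semi_axis_a_nm": float,
    "semi_axis_b_nm": float,
    "semi_axis_c_nm": float,
    "edge_a_nm": float,
    "edge_b_nm": float,
    "edge_c_nm": float,
    "sigma": float,
    "sigma_length": float,
    "orientation_kind": str,
    "orientation_width_rad": float,
    "lattice_type": str,
    "cell_a_nm": float,
    "cell_b_nm": float,
    "cell_c_nm": float,
    "cell_alpha_deg": float,
    "cell_beta_deg": float,
    "cell_gamma_deg": float,
    "uvw": str,
    "lattice_orientation": str,
    "peak_kind": str,
    "peak_sigma_q": float,
    "peak_eta": float,
    "debye_waller_sigma_nm": float,
    "nx": int,
    "ny": int,
    "pixel_size_mm": float,
    "wavelength_nm": float,
    "distance_mm": float,
    "beam_center_x": float,
    "beam_center_y": float,
    "qmap_mode": str,
    "contrast": float,
    "number_density_nm3": float,
    "include_lattice": bool,
    "alpha_i_deg": float,
    "film_delta": float,
    "film_beta": float,
    "q_min_nm1": float,
    "q_max_nm1": float,
    "n_points": int,
    "seed": int,
    "tolerance": float,
}


def _validate(cfg: dict) -> dict:
    out = {}
    for key, value in cfg.items():
        if key not in KNOWN_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
        want = KNOWN_KEYS[key]
        try:
            if want is bool and isinstance(value, str):
                value = value.lower() in ("1", "true", "yes")
            out[key] = want(value)
        except (TypeError, ValueError):
            raise ConfigError(
                f"key {key!r} expects {want.__name__}, got {value!r}"
            ) from None
    mode = out.get("mode")
    if mode is not None and mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")
    return out


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return _validate(tomllib.load(fh))


def apply_overrides(cfg: dict, pairs) -> dict:
    """Apply --set key=value overrides (strings parsed by key type)."""
    cfg = dict(cfg)
    for pair in pairs:
        if "=" not in pair:
            raise ConfigError(f"--set expects key=value, got {pair!r}")
        key, _, value = pair.partition("=")
        cfg.update(_validate({key.strip(): value.strip()}))
    return cfg


def _shape_from_config(cfg: dict):
    kind = cfg.get("shape_kind", "sphere")
    sigma = cfg.get("sigma", 0.1)
    sig_l = cfg.get("sigma_length", sigma)
    if kind == "sphere":
        sizes = (cfg.get("radius_nm", 3.0),)
        dists = [SizeDistribution(sizes[0], sigma)]
    elif kind == "cylinder":
        sizes = (cfg.get("radius_nm", 2.0), cfg.get("length_nm", 16.0))
        dists = [SizeDistribution(sizes[0], sigma), SizeDistribution(sizes[1] / 2, sig_l)]
    elif kind == "disk_lamella":
        t = cfg.get("thickness_nm", 2.0)
        if "diameter_nm" in cfg:
            sizes = (t, cfg["diameter_nm"])
            dists = [SizeDistribution(sizes[1] / 2, sigma), SizeDistribution(t / 2, sig_l)]
        else:
            sizes = (t,)
            dists = [SizeDistribution(t / 2, sigma)]
    elif kind == "biaxial_ellipsoid":
        sizes = (cfg.get("semi_axis_a_nm", 2.0), cfg.get("semi_axis_c_nm", 6.0))
        dists = [SizeDistribution(1.0, sigma)]
    elif kind == "triaxial_ellipsoid":
        sizes = (
            cfg.get("semi_axis_a_nm", 2.0),
            cfg.get("semi_axis_b_nm", 4.0),
            cfg.get("semi_axis_c_nm", 6.0),
        )
        dists = [SizeDistribution(1.0, sigma)]
    elif kind == "cube_parallelepiped":
        if "edge_b_nm" in cfg or "edge_c_nm" in cfg:
            sizes = (cfg.get("edge_a_nm", 4.0), cfg.get("edge_b_nm", 4.0),
                     cfg.get("edge_c_nm", 4.0))
        else:
            sizes = (cfg.get("edge_a_nm", 4.0),)
        dists = [SizeDistribution(sizes[0] / 2, sigma)]
    else:
        raise ConfigError(f"unknown shape_kind {kind!r}")
    return ShapeSpec(kind, sizes), dists


def build_run(cfg: dict) -> dict:
    """Turn a flat config into the model-level inputs of a run."""
    shape, dists = _shape_from_config(cfg)
    out = {"shape": shape, "dists": dists}
    if "orientation_kind" in cfg:
        out["odist"] = OrientationDistribution(
            cfg["orientation_kind"], cfg.get("orientation_width_rad", 0.0)
        )
    if "lattice_type" in cfg:
        uvw = tuple(int(v) for v in cfg.get("uvw", "0,0,1").split(","))
        cell = UnitCell(
            cfg.get("cell_a_nm", 35.0),
            cfg.get("cell_b_nm", cfg.get("cell_a_nm", 35.0)),
            cfg.get("cell_c_nm", cfg.get("cell_a_nm", 35.0)),
            cfg.get("cell_alpha_deg", 90.0),
            cfg.get("cell_beta_deg", 90.0),
            cfg.get("cell_gamma_deg", 90.0),
            cfg["lattice_type"],
            uvw,
        )
        peak = PeakShape(
            cfg.get("peak_kind", "pseudo_voigt"),
            cfg.get("peak_sigma_q", 0.02),
            cfg.get("peak_eta", 0.0),
            cfg.get("debye_waller_sigma_nm", 0.0),
        )
        out["lattice"] = LatticeModel(cell, peak, cfg.get("lattice_orientation", "aligned"))
    bc = None
    if "beam_center_x" in cfg or "beam_center_y" in cfg:
        bc = (cfg.get("beam_center_x", cfg.get("nx", 256) / 2),
              cfg.get("beam_center_y", cfg.get("ny", 256) / 2))
    out["detector"] = DetectorGeometry(
        cfg.get("nx", 256),
        cfg.get("ny", 256),
        cfg.get("pixel_size_mm", 1.0),
        cfg.get("wavelength_nm", 0.1),
        cfg.get("distance_mm", 4000.0),
        beam_center=bc,
        mode=cfg.get("qmap_mode", "small_angle"),
    )
    out["params"] = IntensityParams(
        cfg.get("contrast", 1.0),
        cfg.get("number_density_nm3", 1.0),
        cfg.get("include_lattice", True),
    )
    if "alpha_i_deg" in cfg:
        out["film"] = GISASFilm(
            cfg["alpha_i_deg"], cfg.get("film_delta", 0.0), cfg.get("film_beta", 0.0)
        )
    out["q_grid"] = (
        cfg.get("q_min_nm1", 0.02),
        cfg.get("q_max_nm1", 10.0),
        cfg.get("n_points", 500),
    )
    return out


def _flatten_meta(meta: dict) -> dict:
    """Flat key=value echo of run inputs for headers and sidecars."""
    out = {}
    shape = meta.get("shape")
    if shape is not None:
        out["shape_kind"] = shape.kind
        for i, s in enumerate(shape.sizes):
            out[f"size_{i}_nm"] = s
    det = meta.get("detector")
    if det is not None:
        out.update(
            nx=det.nx, ny=det.ny, pixel_size_mm=det.pixel_size,
            wavelength_nm=det.wavelength, distance_mm=det.distance,
            beam_center_x=det.beam_center[0], beam_center_y=det.beam_center[1],
            qmap_mode=det.mode,
        )
    params = meta.get("params")
    if params is not None:
        out.update(
            contrast=params.contrast,
            number_density_nm3=params.number_density,
            include_lattice=params.include_lattice,
        )
    lat = meta.get("lattice")
    if lat is not None:
        out.update(
            lattice_type=lat.cell.lattice_type,
            cell_a_nm=lat.cell.a, cell_b_nm=lat.cell.b, cell_c_nm=lat.cell.c,
            cell_alpha_deg=lat.cell.alpha, cell_beta_deg=lat.cell.beta,
            cell_gamma_deg=lat.cell.gamma,
            uvw=",".join(str(v) for v in lat.cell.uvw),
            lattice_orientation=lat.orientation,
            peak_kind=lat.peak.kind, peak_sigma_q=lat.peak.sigma_q,
            peak_eta=lat.peak.eta, debye_waller_sigma_nm=lat.peak.debye_waller_sigma,
        )
    film = meta.get("film")
    if film is not None:
        out.update(alpha_i_deg=film.alpha_i, film_delta=film.delta, film_beta=film.beta)
    return out


def write_curve1d(curve: Curve1D, path) -> None:
    path = Path(path)
    header = ["q_nm^-1 I sigma_I"]
    for k, v in _flatten_meta(curve.meta).items():
        header.append(f"{k} = {v}")
    data = np.column_stack([curve.q, curve.I, np.zeros_like(curve.q)])
    np.savetxt(path, data, header="\n".join(header))


def read_curve1d(path) -> Curve1D:
    data = np.loadtxt(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
    return Curve1D(data[:, 0], data[:, 1], meta)


def write_pattern2d(p: Pattern2D, stem) -> dict:
    """Write <stem>.tif (float32), <stem>.txt (matrix) and <stem>.meta.txt
    (key=value sidecar); returns the paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tif = stem.with_suffix(".tif")
    txt = stem.with_suffix(".txt")
    meta_path = stem.with_name(stem.name + ".meta.txt")
    tifffile.imwrite(tif, p.I.astype(np.float32))
    np.savetxt(txt, p.I)
    with open(meta_path, "w") as fh:
        for k, v in _flatten_meta(p.meta).items():
            fh.write(f"{k} = {v}\n")
    return {"tiff": tif, "matrix": txt, "sidecar": meta_path}


def read_sidecar(path) -> dict:
    """Re-parse a sidecar into a validated config-like dict (round-trip)."""
    raw = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or "=" not in line:
                continue
            k, _, v = line.partition("=")
            k = k.strip()
            if k in KNOWN_KEYS:
                raw[k] = v.strip()
    return _validate(raw)


def config_from_pattern(p: Pattern2D) -> dict:
    return {k: v for k, v in _flatten_meta(p.meta).items() if k in KNOWN_KEYS}
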