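"""Reading and writing recordings, configs and reconstruction results.

Recordings travel as HDF5 containers (``/voltage`` of shape
``(T, ny, nx)``, ``/time_s``, geometry/medium metadata as attributes) or
as a directory of per-frame CSV matrices with a YAML sidecar.  One YAML
config describes grid, layered medium and reconstruction parameters:

.. code-block:: yaml

    grid: {nx: 10, ny: 10, pitch_mm: 0.4}
    layers:
      - {x_from_mm: 0.0, x_to_mm: 3.6, sigma_S_per_m: 0.3, eps_rel: 1.0e5, mu_rel: 1.0}
    reconstruction: {z_mm: 0.1, kc: 7.85, alpha: 0.25, pad_factor: 2, upsample_factor: 3}
    superresolution: {factor: 3, band_limit_frac: 1.0, max_iter: 500, tol: 1.0e-8}
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .geometry import ArrayGeometry, MediumModel, TissueLayer
from .reconstruct import ReconstructionParams, ReconstructionResult
from .simulate import Recording

__all__ = [
    "load_config",
    "build_geometry",
    "build_medium",
    "build_params",
    "medium_to_dict",
    "medium_from_dict",
    "save_recording",
    "load_recording",
    "load_csv_recording",
    "save_result",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def build_geometry(cfg: dict) -> ArrayGeometry:
    g = cfg.get("grid", {})
    return ArrayGeometry(int(g.get("nx", 10)), int(g.get("ny", 10)), float(g.get("pitch_mm", 0.4)))


def medium_to_dict(medium: MediumModel) -> dict:
    return {
        "layers": [
            {
                "x_from_mm": l.x_from_mm,
                "x_to_mm": l.x_to_mm,
                "sigma_S_per_m": l.sigma,
                "eps_rel": l.eps_rel,
                "mu_rel": l.mu_rel,
            }
            for l in medium.layers
        ],
        "anisotropy_ratio": medium.anisotropy_ratio,
    }


def medium_from_dict(d: dict) -> MediumModel:
    layers = [
        TissueLayer(
            float(l["x_from_mm"]), float(l["x_to_mm"]),
            float(l["sigma_S_per_m"]), float(l["eps_rel"]),
            float(l.get("mu_rel", 1.0)),
        )
        for l in d["layers"]
    ]
    return MediumModel(layers, anisotropy_ratio=float(d.get("anisotropy_ratio", 1.0)))


def build_medium(cfg: dict) -> MediumModel:
    if "layers" not in cfg or not cfg["layers"]:
        return MediumModel.uniform()
    return medium_from_dict(
        {"layers": cfg["layers"], "anisotropy_ratio": cfg.get("anisotropy_ratio", 1.0)}
    )


def build_params(cfg: dict) -> ReconstructionParams:
    r = cfg.get("reconstruction", {})
    s = cfg.get("superresolution", {})
    kwargs: dict = {}
    if "z_mm" in r:
        kwargs["z_mm"] = float(r["z_mm"])
    if "kc" in r and r["kc"] is not None:
        kwargs["kc"] = float(r["kc"])
    if "kc_frac_nyquist" in r:
        kwargs["kc_frac_nyquist"] = float(r["kc_frac_nyquist"])
    if "alpha" in r:
        kwargs["alpha"] = float(r["alpha"])
    if "pad_factor" in r:
        kwargs["pad_factor"] = int(r["pad_factor"])
    if "upsample_factor" in r:
        kwargs["upsample_factor"] = int(r["upsample_factor"])
    elif "factor" in s:
        kwargs["upsample_factor"] = int(s["factor"])
    if "omega" in r:
        kwargs["omega"] = float(r["omega"])
    if "max_iter" in s:
        kwargs["pg_max_iter"] = int(s["max_iter"])
    if "tol" in s:
        kwargs["pg_tol"] = float(s["tol"])
    if "poynting_conjugate" in r:
        kwargs["poynting_conjugate"] = bool(r["poynting_conjugate"])
    return ReconstructionParams(**kwargs)


def _config_digest(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=float).encode()).hexdigest()[:16]


def save_recording(path: str | Path, recording: Recording, with_truth: bool = True) -> None:
    """Write a recording (and optionally its ground truth) to HDF5."""
    g = recording.geometry
    meta = {
        "grid": {"nx": g.n_x, "ny": g.n_y, "pitch_mm": g.pitch_mm},
        **medium_to_dict(recording.medium),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=recording.voltage)
        f.create_dataset("time_s", data=recording.time_s)
        f.attrs["config_yaml"] = yaml.safe_dump(meta)
        f.attrs["config_digest"] = _config_digest(meta)
        if with_truth and recording.truth:
            t = f.create_group("truth")
            t.create_dataset("noiseless", data=recording.truth["noiseless"])
            t.attrs["noise_sd"] = recording.truth["noise_sd"]
            t.attrs["depths_mm"] = json.dumps(recording.truth["depths_mm"])
            t.attrs["centres_mm"] = json.dumps(
                [list(c) for c in recording.truth["centres_mm"]]
            )


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        voltage = f["voltage"][()]
        time_s = f["time_s"][()]
        meta = yaml.safe_load(f.attrs["config_yaml"])
        truth: dict = {}
        if "truth" in f:
            t = f["truth"]
            truth = {
                "noiseless": t["noiseless"][()],
                "noise_sd": float(t.attrs["noise_sd"]),
                "depths_mm": json.loads(t.attrs["depths_mm"]),
                "centres_mm": [tuple(c) for c in json.loads(t.attrs["centres_mm"])],
            }
    geometry = build_geometry(meta)
    medium = build_medium(meta)
    if voltage.shape[1:] != geometry.shape:
        raise ValueError(
            f"voltage shape {voltage.shape} does not match the {geometry.shape} grid"
        )
    return Recording(voltage=voltage, time_s=time_s, geometry=geometry, medium=medium, truth=truth)


def load_csv_recording(directory: str | Path, sidecar: str | Path | None = None) -> Recording:
    """Read per-frame CSV matrices (sorted by name) plus a YAML sidecar.

    The sidecar (default ``<directory>/config.yaml``) must provide the
    grid block and a ``sample_rate_hz`` entry; layers are optional.
    """
    directory = Path(directory)
    sidecar = Path(sidecar) if sidecar else directory / "config.yaml"
    cfg = load_config(sidecar)
    geometry = build_geometry(cfg)
    medium = build_medium(cfg)
    fs = float(cfg.get("sample_rate_hz", 0))
    if fs <= 0:
        raise ValueError("sidecar must state a positive sample_rate_hz")
    frames = sorted(directory.glob("*.csv"))
    if not frames:
        raise FileNotFoundError(f"no CSV frames found in {directory}")
    movie = np.stack([np.loadtxt(p, delimiter=",") for p in frames])
    if movie.shape[1:] != geometry.shape:
        raise ValueError(
            f"CSV frames of shape {movie.shape[1:]} do not match the {geometry.shape} grid"
        )
    time_s = np.arange(movie.shape[0]) / fs
    return Recording(voltage=movie, time_s=time_s, geometry=geometry, medium=medium)


def save_result(path: str | Path, result: ReconstructionResult) -> None:
    """Write field estimates to HDF5 (complex vectors component-major)."""
    with h5py.File(path, "w") as f:
        for name, frame in (("Ez", result.E), ("Hz", result.H), ("Sz", result.S)):
            f.create_dataset(name, data=np.stack(frame.components))
        f.create_dataset("ESD", data=np.real(result.esd.values))
        f.create_dataset("D", data=np.real(result.dissipation.values))
        p = result.params
        f.attrs["params_json"] = json.dumps(
            {
                "z_mm": p.z_mm,
                "kc": p.resolve_kc(
                    ArrayGeometry(
                        result.E.geometry.n_x, result.E.geometry.n_y,
                        result.E.geometry.pitch_mm,
                    )
                ),
                "alpha": p.alpha,
                "pad_factor": p.pad_factor,
                "upsample_factor": p.upsample_factor,
                "omega": p.omega,
                "poynting_conjugate": p.poynting_conjugate,
            }
        )
        f.attrs["provenance"] = result.provenance
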