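"""File formats: parameter files, profile/track CSVs, TIFF movies + sidecars.

Conventions: distances in µm and times in s inside the package; velocities
cross the I/O boundary in µm/min (the bench convention) and are converted on
read/write.  Every CSV header and JSON key carries its unit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ablation import ImageStack
from .lifetimes import LifetimeFit, LifetimeSample
from .model import ModelParams, RadialProfile

__all__ = [
    "read_params",
    "write_params",
    "read_profile",
    "write_profile",
    "read_stack",
    "write_stack",
    "read_lifetimes",
    "write_lifetimes",
    "write_lifetime_report",
    "write_manifest",
    "um_per_min_to_um_per_s",
    "um_per_s_to_um_per_min",
]


def um_per_min_to_um_per_s(v: float) -> float:
    return v / 60.0


def um_per_s_to_um_per_min(v: float) -> float:
    return v * 60.0


# -- parameters -------------------------------------------------------------

def write_params(params: ModelParams, path: str | Path) -> None:
    data = {
        "ell_um": params.ell,
        "ell_u_um": None if params.uniform_activation else params.ell_u,
        "alpha": params.alpha,
        "rho0": params.rho0,
        "theta_per_s": params.theta,
    }
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def read_params(path: str | Path) -> ModelParams:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    ell_u = data.get("ell_u_um")
    kwargs = {}
    if ell_u is None or ell_u == "inf":
        ell_u = float("inf")
        kwargs["beta0"] = float(data["beta0_per_um"])
    return ModelParams(
        ell=float(data["ell_um"]),
        ell_u=float(ell_u),
        alpha=float(data["alpha"]),
        rho0=float(data["rho0"]),
        theta=float(data.get("theta_per_s", 0.05)),
        **kwargs,
    )


# -- radial profiles --------------------------------------------------------

def write_profile(profile: RadialProfile, path: str | Path) -> None:
    df = pd.DataFrame({"x_um": profile.x, "value": profile.values})
    if profile.sd is not None:
        df["sd"] = profile.sd
    if profile.n is not None:
        df["n"] = profile.n
    df.to_csv(path, index=False)


def read_profile(path: str | Path, kind: str = "density") -> RadialProfile:
    df = pd.read_csv(path)
    return RadialProfile(
        x=df["x_um"].to_numpy(),
        values=df["value"].to_numpy(),
        kind=kind,  # type: ignore[arg-type]
        sd=df["sd"].to_numpy() if "sd" in df else None,
        n=df["n"].to_numpy() if "n" in df else None,
    )


# -- movies -----------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Multi-frame TIFF plus a JSON metadata sidecar (<path>.json)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "center_row": stack.center[0],
        "center_col": stack.center[1],
        "cut_frame": stack.cut_time_index,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return ImageStack(
        frames=frames,
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_s"]),
        center=(float(meta["center_row"]), float(meta["center_col"])),
        cut_time_index=int(meta["cut_frame"]),
    )


# -- lifetimes --------------------------------------------------------------

def write_lifetimes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_lifetimes(path: str | Path) -> LifetimeSample:
    df = pd.read_csv(path)
    durations = (df["t_end_s"] - df["t_start_s"]).to_numpy(dtype=float)
    censored = df["censored"].to_numpy(dtype=bool) if "censored" in df else None
    return LifetimeSample(durations=durations, censored=censored)


def write_lifetime_report(fit: LifetimeFit, path: str | Path) -> None:
    report = {
        "tau_s": fit.tau,
        "tau_se_s": fit.tau_se,
        "mean_lifetime_s": fit.mean_lifetime,
        "theta_per_s": fit.theta,
        "t_min_s": fit.t_min,
        "n_used": fit.n_used,
        "ks_statistic": fit.ks_statistic,
        "ks_pvalue": fit.ks_pvalue,
        "model_mismatch": fit.model_mismatch,
        "t_min_sensitivity_tau_s": fit.t_min_sensitivity,
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


# -- run manifests ----------------------------------------------------------

def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    subcommand: str,
    inputs: list[str | Path],
    parameters: dict,
    seed: int | None,
) -> None:
    """JSON run manifest: inputs with content hashes, parameters, seed."""
    manifest = {
        "subcommand": subcommand,
        "inputs": {
            str(p): _hash_file(Path(p)) for p in inputs if Path(p).is_file()
        },
        "parameters": parameters,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
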