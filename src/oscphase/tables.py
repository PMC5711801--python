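"""Delimited-text table formats, posterior persistence and run manifests.

All tables are CSV with a header; angles are stored in degrees, times in
seconds, positions in mm.  Posterior draws go into a chunked HDF5 container.
Every pipeline stage writes a manifest recording the configuration, seed,
package versions and SHA-256 digests of its inputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import Diagnostics, McmcSettings, PosteriorSamples

TRAJECTORY_COLUMNS = ["participant", "trial", "t", "hand", "x", "missing"]
METADATA_COLUMNS = [
    "trial", "participant", "session", "instruction", "mirror", "posture_raw",
    "excluded",
]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def write_trajectories(traj: pd.DataFrame, path) -> None:
    _require_columns(traj, TRAJECTORY_COLUMNS, path)
    traj.to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed table ({e})") from None
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    df["missing"] = df["missing"].astype(bool)
    # sampling must be uniform within every trial x hand series
    for (_, trial, hand), g in df.groupby(["participant", "trial", "hand"]):
        t = g["t"].to_numpy()
        if len(t) >= 3:
            dt = np.diff(t)
            if np.any(dt <= 0) or np.any(np.abs(dt - np.median(dt)) > 0.5 * np.median(dt)):
                raise ValueError(
                    f"{path}: non-uniform sampling in trial {trial} hand {hand}"
                )
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    _require_columns(meta, METADATA_COLUMNS, path)
    meta.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, METADATA_COLUMNS, path)
    df["excluded"] = df["excluded"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, required=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, required, path)
    return df


def write_posterior(post: PosteriorSamples, diag: Diagnostics | None, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("beta", data=post.beta, chunks=True, compression="gzip")
        f.create_dataset(
            "participant_intercepts",
            data=post.participant_intercepts,
            chunks=True,
            compression="gzip",
        )
        f.attrs["effect_names"] = list(post.effect_names)
        f.attrs["participant_ids"] = [str(p) for p in post.participant_ids]
        for k in ("chains", "burn_in", "draws", "thin"):
            f.attrs[k] = getattr(post.settings, k)
        if diag is not None:
            f.create_dataset("ess", data=diag.ess.to_numpy())
            f.create_dataset("shrink_factor", data=diag.shrink_factor.to_numpy())


def read_posterior(path) -> PosteriorSamples:
    with h5py.File(path, "r") as f:
        settings = McmcSettings(
            chains=int(f.attrs["chains"]),
            burn_in=int(f.attrs["burn_in"]),
            draws=int(f.attrs["draws"]),
            thin=int(f.attrs["thin"]),
        )
        return PosteriorSamples(
            beta=f["beta"][...],
            participant_intercepts=f["participant_intercepts"][...],
            effect_names=tuple(f.attrs["effect_names"]),
            participant_ids=tuple(f.attrs["participant_ids"]),
            settings=settings,
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, stage: str, config: dict, seed, inputs=()) -> Path:
    """Record what produced the outputs in ``out_dir``."""
    import oscphase

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "versions": {
            "oscphase": oscphase.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
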