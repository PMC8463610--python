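"""Persistence: HDF5 snapshots, CSV series, JSON manifests.

Snapshot schema (HDF5): datasets ``/omega`` (N x N float64) and
``/mean_u`` (2 float64); attributes ``t, lambda, alpha, beta, L, N, dt,
seed, code_version``.  CSV files are comma-separated with a header row.
A run manifest records the configuration, seeds and SHA-256 checksums of
every output file, enough to re-run bit-identically on one platform.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .model import ModelParams
from .solver import EnergySeries, FieldSnapshot, state_from_vorticity
from .vortexfield import MeltField, PolarityCounts, VortexSet

__all__ = [
    "SchemaError",
    "write_snapshot",
    "read_snapshot",
    "snapshot_state",
    "write_energy_csv",
    "read_energy_csv",
    "write_vortex_csv",
    "read_vortex_csv",
    "write_polarity_csv",
    "write_melt_field",
    "RunManifest",
]


class SchemaError(ValueError):
    """A persisted file is missing a required dataset or attribute."""


_SNAPSHOT_ATTRS = ("t", "lambda", "alpha", "beta", "L", "N", "dt")


def write_snapshot(snapshot: FieldSnapshot, path) -> Path:
    path = Path(path)
    p = snapshot.params
    with h5py.File(path, "w") as f:
        f.create_dataset("omega", data=snapshot.omega, dtype="float64")
        mean_u = snapshot.u.reshape(-1, 2).mean(axis=0)
        f.create_dataset("mean_u", data=mean_u, dtype="float64")
        f.attrs.update(
            {
                "t": snapshot.t,
                "lambda": p.lambda_adv,
                "alpha": p.alpha,
                "beta": p.beta,
                "L": p.L,
                "N": p.N,
                "dt": p.dt,
                "seed": -1 if snapshot.seed is None else snapshot.seed,
                "code_version": __version__,
            }
        )
    return path


def read_snapshot(path) -> FieldSnapshot:
    from .solver import velocity_from_vorticity

    with h5py.File(path, "r") as f:
        for name in ("omega", "mean_u"):
            if name not in f:
                raise SchemaError(f"snapshot file missing dataset /{name}")
        for name in _SNAPSHOT_ATTRS:
            if name not in f.attrs:
                raise SchemaError(f"snapshot file missing attribute {name!r}")
        omega = f["omega"][...]
        mean_u = f["mean_u"][...]
        a = dict(f.attrs)
    params = ModelParams(
        lambda_adv=float(a["lambda"]),
        alpha=float(a["alpha"]),
        beta=float(a["beta"]),
        L=float(a["L"]),
        N=int(a["N"]),
        dt=float(a["dt"]),
    )
    seed = int(a.get("seed", -1))
    state = state_from_vorticity(omega, params, mean_u=mean_u, t=float(a["t"]))
    # keep the stored omega bit-identical; only u is reconstructed
    return FieldSnapshot(
        omega=omega,
        u=velocity_from_vorticity(state, params),
        t=float(a["t"]),
        params=params,
        seed=None if seed < 0 else seed,
    )


def snapshot_state(path):
    """Read a snapshot file back into (SpectralState, ModelParams, seed)."""
    snap = read_snapshot(path)
    state = state_from_vorticity(
        snap.omega, snap.params,
        mean_u=snap.u.reshape(-1, 2).mean(axis=0), t=snap.t,
    )
    return state, snap.params, snap.seed


def write_energy_csv(series: EnergySeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({"t": series.times, "energy": series.values}).to_csv(
        path, index=False
    )
    return path


def read_energy_csv(path) -> EnergySeries:
    df = pd.read_csv(path)
    for col in ("t", "energy"):
        if col not in df.columns:
            raise SchemaError(f"energy CSV missing column {col!r}")
    return EnergySeries(df["t"].to_numpy(), df["energy"].to_numpy())


def write_vortex_csv(vs: VortexSet, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "t": np.full(len(vs), vs.t),
            "x": vs.positions[:, 0],
            "y": vs.positions[:, 1],
            "polarity": vs.polarity,
            "peak_vorticity": vs.peak_vorticity,
        }
    ).to_csv(path, index=False)
    return path


def read_vortex_csv(path, L: float) -> VortexSet:
    df = pd.read_csv(path)
    for col in ("t", "x", "y", "polarity", "peak_vorticity"):
        if col not in df.columns:
            raise SchemaError(f"vortex CSV missing column {col!r}")
    t = float(df["t"].iloc[0]) if len(df) else 0.0
    return VortexSet(
        positions=df[["x", "y"]].to_numpy(),
        polarity=df["polarity"].to_numpy(int),
        peak_vorticity=df["peak_vorticity"].to_numpy(),
        t=t,
        L=L,
    )


def write_polarity_csv(counts: PolarityCounts, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"t": counts.times, "n_pos": counts.n_positive, "n_neg": counts.n_negative}
    ).to_csv(path, index=False)
    return path


def write_melt_field(mf: MeltField, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=mf.raw)
        f.create_dataset("smoothed", data=mf.smoothed)
        f.create_dataset("mask", data=mf.mask)
        f.attrs["area_fraction"] = mf.area_fraction
        f.attrs["degenerate"] = mf.degenerate
        f.attrs["code_version"] = __version__
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one command invocation."""

    config: dict
    seed: int | None = None
    files: dict = field(default_factory=dict)
    code_version: str = __version__
    platform: str = field(default_factory=platform.platform)
    created: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )

    def add_file(self, path) -> None:
        path = Path(path)
        self.files[path.name] = {
            "path": str(path),
            "sha256": _sha256(path),
            "bytes": path.stat().st_size,
        }

    def write(self, path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config,
            "seed": self.seed,
            "files": self.files,
            "code_version": self.code_version,
            "platform": self.platform,
            "created": self.created,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path
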