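"""Readers and writers for the package's on-disk formats.

CSV files are comma-separated UTF-8 with a mandatory header row and floats
written at 10 significant digits, so that reruns with the same seed diff
byte-identically.  Model parameters travel as flat JSON/YAML mappings with
exactly the dataclass field names; multi-channel frames as TIFF stacks
(channel order: coverage, dead, oxidized, reduced) with a JSON sidecar for
metadata.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fitting import FitResult, FitSpec, ObservationModel
from .model import FixedPoint, ModelParams, ModelState, Trajectory
from .observables import ChannelFrame
from .phase import BasinGrid

__all__ = [
    "SchemaError",
    "FLOAT_FORMAT",
    "write_params",
    "read_params",
    "write_trajectory",
    "read_trajectory",
    "write_basins",
    "read_basins",
    "render_basins_png",
    "write_fit_result",
    "read_fit_spec",
    "write_frames_tiff",
    "read_frames_tiff",
    "atomic_write_text",
]

FLOAT_FORMAT = "%.10g"

#: Basin-map colour convention: ferroptosis-sensitive basin warm,
#: insensitive basin blue (configurable at the call site).
BASIN_COLORS = {"sensitive": "#e66a4e", "insensitive": "#4e79c6", "unresolved": "#d9d9d9"}


class SchemaError(ValueError):
    """A file does not match its declared schema (names the offender)."""


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` atomically (write-temp-then-rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_params(params: ModelParams, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        atomic_write_text(path, yaml.safe_dump(d, sort_keys=True))
    else:
        atomic_write_text(path, json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_params(path: str | Path) -> ModelParams:
    path = Path(path)
    try:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(path.read_text())
        else:
            d = json.loads(path.read_text())
        if not isinstance(d, dict):
            raise SchemaError(f"{path}: expected a flat mapping of parameter names")
        return ModelParams.from_dict(d)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def _df_csv(df: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, df.to_csv(index=False, float_format=FLOAT_FORMAT))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    _df_csv(pd.DataFrame({"time_h": traj.times, "n": traj.n, "r": traj.r}), path)


def read_trajectory(path: str | Path, params: ModelParams) -> Trajectory:
    df = pd.read_csv(path)
    missing = {"time_h", "n", "r"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return Trajectory(times=df["time_h"].to_numpy(), n=df["n"].to_numpy(),
                      r=df["r"].to_numpy(), params=params)


def write_basins(basins: BasinGrid, csv_path: str | Path, attractors_path: str | Path | None = None) -> None:
    """BasinGrid as a tidy (r, n, label) CSV plus a JSON attractor table."""
    rr, nn = np.meshgrid(basins.r_axis, basins.n_axis)
    df = pd.DataFrame({"r": rr.ravel(), "n": nn.ravel(), "label": basins.labels.ravel()})
    _df_csv(df, csv_path)
    if attractors_path is not None:
        table = [
            {
                "index": i,
                "n": fp.state.n,
                "r": fp.state.r,
                "classification": fp.classification,
                "eigenvalues_real": [ev.real for ev in fp.eigenvalues],
                "eigenvalues_imag": [ev.imag for ev in fp.eigenvalues],
            }
            for i, fp in enumerate(basins.attractors)
        ]
        atomic_write_text(attractors_path, json.dumps(table, indent=2) + "\n")


def read_basins(csv_path: str | Path, attractors: list[FixedPoint]) -> BasinGrid:
    df = pd.read_csv(csv_path)
    missing = {"r", "n", "label"} - set(df.columns)
    if missing:
        raise SchemaError(f"{csv_path}: missing columns {sorted(missing)}")
    r_axis = np.unique(df["r"].to_numpy())
    n_axis = np.unique(df["n"].to_numpy())
    labels = (
        df.sort_values(["n", "r"])["label"].to_numpy().reshape(len(n_axis), len(r_axis))
    )
    return BasinGrid(r_axis=r_axis, n_axis=n_axis, labels=labels, attractors=attractors)


def render_basins_png(basins: BasinGrid, path: str | Path, colors: dict[str, str] | None = None) -> None:
    """Render the basin map (sensitive warm, insensitive blue by default)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    colors = {**BASIN_COLORS, **(colors or {})}
    # order attractors: highest-n stable point is the resistant state
    palette = []
    for fp in basins.attractors:
        resistant = fp.state.n == max(a.state.n for a in basins.attractors)
        palette.append(colors["insensitive"] if resistant else colors["sensitive"])
    cmap = ListedColormap([colors["unresolved"]] + palette)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.pcolormesh(basins.r_axis, basins.n_axis, basins.labels + 1, cmap=cmap,
                  vmin=-0.5, vmax=len(palette) + 0.5, shading="nearest")
    for fp in basins.attractors:
        ax.plot(fp.state.r, fp.state.n, "ko", ms=5)
    ax.set_xlabel("lipid ROS per cell, r")
    ax.set_ylabel("confluence fraction, n")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_fit_result(result: FitResult, path: str | Path) -> None:
    d = dataclasses.asdict(result)
    d["multistart_rss"] = list(d["multistart_rss"])
    d["multistart_dispersion"] = result.multistart_dispersion
    atomic_write_text(path, json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_fit_spec(path: str | Path) -> FitSpec:
    """FitSpec from YAML/JSON; unknown keys are rejected."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping")
    known = {f.name for f in dataclasses.fields(FitSpec)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        for key in ("free", "condition_specific"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "bounds" in raw:
            raw["bounds"] = {k: tuple(v) for k, v in raw["bounds"].items()}
        return FitSpec(**raw)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_frames_tiff(frames: list[ChannelFrame], path: str | Path, sidecar: str | Path | None = None) -> None:
    """Frames as a (time, channel, y, x) TIFF stack plus a JSON sidecar."""
    stack = np.stack(
        [
            np.stack([f.coverage.astype(np.float32), f.dead.astype(np.float32),
                      f.oxidized.astype(np.float32), f.reduced.astype(np.float32)])
            for f in frames
        ]
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack)
    if sidecar is not None:
        meta = {
            "channels": ["coverage", "dead", "oxidized", "reduced"],
            "times_h": [f.time_h for f in frames],
            "pixel_size_um": frames[0].pixel_size_um if frames else None,
        }
        atomic_write_text(sidecar, json.dumps(meta, indent=2) + "\n")


def read_frames_tiff(path: str | Path, sidecar: str | Path | None = None) -> list[ChannelFrame]:
    stack = tifffile.imread(path)
    if stack.ndim == 3:
        stack = stack[None]
    if stack.ndim != 4 or stack.shape[1] != 4:
        raise SchemaError(f"{path}: expected (time, 4-channel, y, x) stack, got {stack.shape}")
    times = list(range(stack.shape[0]))
    px = None
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
        if meta.get("channels") != ["coverage", "dead", "oxidized", "reduced"]:
            raise SchemaError(f"{sidecar}: unexpected channel order {meta.get('channels')}")
        times = meta.get("times_h", times)
        px = meta.get("pixel_size_um")
    return [
        ChannelFrame(coverage=fr[0] > 0.5, dead=fr[1], oxidized=fr[2], reduced=fr[3],
                     time_h=float(t), pixel_size_um=px)
        for fr, t in zip(stack, times)
    ]
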