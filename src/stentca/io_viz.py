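"""Config round-tripping, run artifacts, and lattice rendering.

Every run directory is self-describing: it contains the echoed config (YAML,
including the master seed and the full resolved material table), the per-step
component-count trace and rate tables (CSV), a milestone summary, snapshot
archives (.npz), and PNG renders with a fixed component colormap.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap

from . import metrics
from .engine import SimConfig, RunResult, resolve_materials
from .geometry import COMPONENTS, ELEC
from .materials import materials_to_dict
from .metrics import DegradationTrace

__all__ = [
    "load_config", "save_config", "write_trace", "read_trace",
    "render_cross_section", "render_cloud", "write_run",
    "COMPONENT_COLORS",
]

TRACE_SCHEMA = "stentca-trace-v1"

# fixed palette: electrolyte, polymer, MgF2, MgO, Mg, Mg(OH)2 product
COMPONENT_COLORS = {
    "ELEC": "#d6ecf5",
    "POLY": "#caa472",
    "MGF2": "#7fbf7f",
    "MGO": "#4f4f4f",
    "MG": "#9fa8b8",
    "PRODUCT": "#e0e0c0",
}
_CMAP = ListedColormap([COMPONENT_COLORS[c] for c in COMPONENTS])


# ---------------------------------------------------------------------------
# config

def save_config(cfg: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def load_config(path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError(f"config {path} is not a mapping")
    try:
        return SimConfig.from_dict(d)
    except TypeError as e:
        raise ValueError(f"config {path}: {e}") from None


# ---------------------------------------------------------------------------
# traces

def _trace_frame(trace: DegradationTrace) -> pd.DataFrame:
    rows = []
    for region, counts in trace.counts.items():
        for ci, comp in enumerate(COMPONENTS):
            col = counts[:, ci]
            rows.append(pd.DataFrame({
                "region": region, "component": comp,
                "step": np.arange(len(col)), "count": col,
            }))
    return pd.concat(rows, ignore_index=True)


def write_trace(trace: DegradationTrace, path) -> None:
    """CSV with a versioned schema header; lossless round trip."""
    with open(path, "w") as fh:
        fh.write(f"# schema={TRACE_SCHEMA} rate_window={trace.rate_window}\n")
        _trace_frame(trace).to_csv(fh, index=False)


def read_trace(path) -> DegradationTrace:
    with open(path) as fh:
        header = fh.readline()
        if TRACE_SCHEMA not in header:
            raise ValueError(f"{path}: expected schema {TRACE_SCHEMA!r}, got {header.strip()!r}")
        rate_window = int(header.strip().split("rate_window=")[1])
        df = pd.read_csv(fh)
    expected = {"region", "component", "step", "count"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}; found {list(df.columns)}")
    extra = set(df.columns) - expected
    if extra:
        import warnings
        warnings.warn(f"{path}: ignoring unknown columns {sorted(extra)}")
    counts = {}
    for region, g in df.groupby("region", sort=False):
        steps = g["step"].max() + 1
        arr = np.zeros((steps, len(COMPONENTS)), dtype=np.int64)
        for ci, comp in enumerate(COMPONENTS):
            sub = g[g["component"] == comp].sort_values("step")
            arr[sub["step"].to_numpy(), ci] = sub["count"].to_numpy()
        counts[region] = arr
    return DegradationTrace(counts, rate_window=rate_window)


# ---------------------------------------------------------------------------
# rendering

def render_cross_section(lattice_or_comp, path, slice_index: int | None = None,
                         dpi: int = 100) -> None:
    """PNG of a 2D component grid with the fixed palette and legend."""
    comp = getattr(lattice_or_comp, "comp", lattice_or_comp)
    if comp.ndim == 3:
        if slice_index is None:
            raise ValueError("3D lattice: pass slice_index for a cross-section")
        comp = comp[:, :, slice_index]
    fig, ax = plt.subplots(figsize=(max(4, comp.shape[1] / 100), max(2, comp.shape[0] / 50)))
    ax.imshow(comp, cmap=_CMAP, vmin=0, vmax=len(COMPONENTS) - 1,
              interpolation="nearest", aspect="auto")
    handles = [plt.Rectangle((0, 0), 1, 1, color=COMPONENT_COLORS[c]) for c in COMPONENTS]
    ax.legend(handles, COMPONENTS, loc="upper right", fontsize=6, ncol=3)
    ax.set_xlabel("arc position (cells)")
    ax.set_ylabel("depth (cells)")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def render_cloud(lattice_or_comp, path, dpi: int = 100, log=None) -> None:
    """Voxel render of a 3D lattice; electrolyte transparent, solids opaque."""
    comp = getattr(lattice_or_comp, "comp", lattice_or_comp)
    if comp.ndim != 3:
        raise ValueError("render_cloud needs a 3D lattice; use render_cross_section for 2D")
    solid = comp != ELEC
    fig = plt.figure(figsize=(6, 4))
    ax = fig.add_subplot(projection="3d")
    if not solid.any():
        (log or print)("render_cloud: lattice fully degraded; empty render")
    else:
        colors = np.empty(comp.shape, dtype=object)
        for ci, name in enumerate(COMPONENTS):
            colors[comp == ci] = COMPONENT_COLORS[name]
        ax.voxels(solid.transpose(1, 2, 0), facecolors=colors.transpose(1, 2, 0))
    ax.set_axis_off()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


# ---------------------------------------------------------------------------
# run artifacts

def write_run(result: RunResult, outdir, force: bool = False) -> Path:
    """Write the full artifact set for a completed run."""
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    cfg = result.config
    save_config(cfg, out / "config.yaml")
    (out / "materials.yaml").write_text(
        yaml.safe_dump(materials_to_dict(resolve_materials(cfg)), sort_keys=False))
    write_trace(result.trace, out / "trace.csv")

    rate_rows = []
    for region in result.trace.regions:
        for comp in COMPONENTS:
            if result.trace.initial_count(comp, region) == 0:
                continue
            if result.trace.n_steps < result.trace.rate_window:
                continue
            r = metrics.degradation_rate(result.trace, comp, region)
            w = result.trace.rate_window
            for i, v in enumerate(r):
                rate_rows.append((region, comp, (i + 1) * w, v))
    pd.DataFrame(rate_rows, columns=["region", "component", "step", "rate"]).to_csv(
        out / "rates.csv", index=False)

    if result.reports:
        pd.DataFrame(
            [{"step": r.step, **r.events, **{f"walkers_{k}": v for k, v in r.walkers.items()}}
             for r in result.reports]
        ).to_csv(out / "steps.csv", index=False)

    snapdir = out / "snapshots"
    snapdir.mkdir(exist_ok=True)
    width = len(str(cfg.steps))
    for t, comp_grid in result.snapshots:
        np.savez_compressed(snapdir / f"step_{t:0{width}d}.npz", comp=comp_grid)
    render_cross_section(result.snapshots[-1][1], out / "final.png",
                         slice_index=0 if result.snapshots[-1][1].ndim == 3 else None)

    milestones = {}
    for region in result.trace.regions:
        for comp in COMPONENTS:
            if result.trace.initial_count(comp, region) == 0:
                continue
            onset = metrics.detect_onset(result.trace.fraction(comp, region))
            if onset is not None:
                milestones[f"{region}.{comp}.onset_step"] = onset
    (out / "milestones.json").write_text(json.dumps(milestones, indent=2))
    return out
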