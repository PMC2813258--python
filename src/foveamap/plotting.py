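"""Flat-map renderings and model figure panels (SVG via matplotlib).

Conventions follow the canonical flat-map legend: dotted black
iso-eccentricity contours, red vertical-meridian lines, blue
horizontal-meridian lines, pale area fills.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib
matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .wedge import AreaLabel, VisualAreaMap

__all__ = ["write_flatmap_svg", "render_field_svg", "render_curves_svg"]

_AREA_FILL = {
    "V1": "#f4c7c3", "V2v": "#c9daf8", "V2d": "#c9daf8",
    "V3v": "#d9ead3", "V3d": "#d9ead3",
}


def write_flatmap_svg(isolines: list[dict], path: str | Path,
                      model: VisualAreaMap | None = None,
                      mirror: bool = False, ecc_max: float = 24.0) -> Path:
    """Render isolines (and optional area fills) to a layered SVG.

    ``mirror`` reflects x for a right-hemisphere layout.  An empty
    isoline list still produces a valid SVG with the background layer.
    """
    path = Path(path)
    if path.parent != Path("") and not path.parent.is_dir():
        raise FileNotFoundError(f"output directory {path.parent} not found")
    sgn = -1.0 if mirror else 1.0
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.set_facecolor("white")

    if model is not None:
        for area in AreaLabel:
            poly = _area_outline(model, area, ecc_max)
            ax.fill(sgn * poly[:, 0], poly[:, 1],
                    color=_AREA_FILL[area.value], lw=0, zorder=0,
                    label=area.value)
    for line in isolines:
        xy = np.asarray(line["xy"], dtype=float)
        if len(xy) == 0:
            continue
        if line["kind"] == "isoecc":
            ax.plot(sgn * xy[:, 0], xy[:, 1], ls=":", color="k", lw=0.8,
                    zorder=2)
        else:
            color = "red" if line.get("name") == "VM" else "blue"
            ax.plot(sgn * xy[:, 0], xy[:, 1], color=color, lw=1.2, zorder=3)
    ax.set_aspect("equal")
    ax.set_xlabel("cortical x (mm)")
    ax.set_ylabel("cortical y (mm)")
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


def _area_outline(model: VisualAreaMap, area: AreaLabel,
                  ecc_max: float, n: int = 121) -> np.ndarray:
    """Closed boundary polygon of one area's cortical image."""
    if area == AreaLabel.V1:
        lo, hi = -np.pi / 2, np.pi / 2
    elif area in (AreaLabel.V2v, AreaLabel.V3v):
        lo, hi = 0.0, np.pi / 2
    else:
        lo, hi = -np.pi / 2, 0.0
    th = np.linspace(lo, hi, n)
    eccs = np.geomspace(1e-3, ecc_max, n)
    segs = [
        model.project(np.full(n, 1e-3), th, area),          # foveal rim
        model.project(eccs, np.full(n, hi), area),          # one border out
        model.project(np.full(n, ecc_max), np.flip(th), area),  # outer rim
        model.project(np.flip(eccs), np.full(n, lo), area),  # back in
    ]
    w = np.concatenate(segs)
    return np.column_stack([np.real(w), np.imag(w)])


def render_field_svg(fields: Iterable[tuple[str, "object"]], value_col: str,
                     path: str | Path, vmax: float | None = None) -> Path:
    """Panels of a per-node field drawn at cortical positions.

    ``fields`` yields (panel title, field DataFrame) pairs; the frame
    needs columns ecc_deg, polar_rad, area, x_mm, y_mm and ``value_col``.
    """
    fields = list(fields)
    path = Path(path)
    fig, axes = plt.subplots(1, len(fields), figsize=(6 * len(fields), 5),
                             squeeze=False)
    for ax, (title, df) in zip(axes[0], fields):
        good = df[df["ok"]] if "ok" in df.columns else df
        sc = ax.scatter(good["x_mm"], good["y_mm"], c=good[value_col], s=4,
                        cmap="RdBu_r", vmax=vmax)
        fig.colorbar(sc, ax=ax, label=value_col)
        ax.set_title(title)
        ax.set_aspect("equal")
        ax.set_xlabel("cortical x (mm)")
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


def render_curves_svg(curves: Iterable["object"], path: str | Path,
                      title: str = "areal magnification") -> Path:
    """Log-log magnification curves M(E), one line per area group."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    for df in curves:
        ax.loglog(df["ecc_deg"], df["M_mm_per_deg"],
                  label=str(df["area"].iloc[0]))
    ax.set_xlabel("eccentricity (deg)")
    ax.set_ylabel("M (mm/deg)")
    ax.set_title(title)
    ax.legend()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


def attach_cortical_positions(df, model: VisualAreaMap):
    """Add x_mm, y_mm columns to a field frame by projecting its nodes."""
    out = df.copy()
    xs = np.empty(len(df))
    ys = np.empty(len(df))
    for area, idx in df.groupby("area").groups.items():
        sub = df.loc[idx]
        w = model.project(sub["ecc_deg"].to_numpy(),
                          sub["polar_rad"].to_numpy(), area, strict=False)
        xs[df.index.get_indexer(idx)] = np.real(w)
        ys[df.index.get_indexer(idx)] = np.imag(w)
    out["x_mm"] = xs
    out["y_mm"] = ys
    return out
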