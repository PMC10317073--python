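"""Rendering microbiome maps: intensity rasters and image export.

A *microbiome map* is a square image in which each position corresponds
to one genome of the reference collection (or to a small merged run of
curve segments) and the position's intensity encodes that genome's
relative abundance in one sample.  This module turns a
:class:`~hilbertmaps.layout.HilbertLayout` plus abundance vectors into
:class:`MapRaster` objects -- single-sample, colorless (reference-only),
average, aggregate, differential and animation-frame variants -- and
exports them as PNG, SVG and animated GIF/MP4 with a sidecar JSON
metadata file.

Cells come in three classes that render distinctly: *assigned* cells
carry an abundance intensity; *zero* cells belong to a taxon whose
abundance is zero or below the noise threshold tau (drawn in the
colormap's floor color); *gap* cells are reserved blanks with no taxon
(drawn in a neutral tone).  Intensities use per-map max normalization by
default so the most abundant taxon always saturates; a log10 scale with
floor tau is available because skewed abundance distributions otherwise
hide the low-abundance taxa.  Differential maps are signed, normalized
by the largest absolute difference onto [-1, 1], and drawn on a
diverging colormap centered at zero.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .layout import HilbertLayout, neighborhoods
from .hilbert import index_to_cell

logger = logging.getLogger("hilbertmaps")

__all__ = [
    "RenderOptions",
    "MapRaster",
    "CLASS_ASSIGNED",
    "CLASS_GAP",
    "CLASS_ZERO",
    "intensity_map",
    "colorless_map",
    "average_map",
    "aggregate_map",
    "differential_map",
    "animation_frames",
    "overlay_path",
    "save_png",
    "save_svg",
    "save_animation",
]

CLASS_ASSIGNED = 0
CLASS_GAP = 1
CLASS_ZERO = 2

#: neutral tone for reserved-gap cells (distinct from any colormap floor)
GAP_RGB = (190, 190, 190)

AGGREGATE_REDUCERS: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mean": lambda a: a.mean(axis=0),
    "sum": lambda a: a.sum(axis=0),
    "median": lambda a: np.median(a, axis=0),
    "max": lambda a: a.max(axis=0),
}


@dataclass(frozen=True)
class RenderOptions:
    """Rendering knobs shared by all map types.

    ``scale`` is ``"linear"`` (per-map max normalization) or ``"log"``
    (log10 with floor ``tau``); ``tau`` overrides the layout's noise
    threshold for display; ``colormap`` is any matplotlib colormap name;
    ``group_hues`` optionally names a grouping whose runs are tinted with
    distinct hues instead of the monochromatic colormap; ``cell_px`` is
    the rendered size of one grid cell in pixels.
    """

    scale: str = "linear"
    tau: float = 0.0
    colormap: str = "viridis"
    diverging_colormap: str = "coolwarm"
    group_hues: Optional[str] = None
    show_path: bool = False
    show_boundaries: bool = False
    boundaries_grouping: Optional[str] = None
    cell_px: int = 16

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        if self.tau < 0:
            raise ValueError("floor tau must be >= 0")
        if self.scale == "log" and self.tau <= 0:
            raise ValueError("log scale requires a positive floor tau")
        if self.cell_px < 1:
            raise ValueError("cell_px must be >= 1")


@dataclass
class MapRaster:
    """Per-cell intensity grid plus overlay geometry and metadata.

    ``intensity`` is a ``side x side`` float array in [0, 1] (signed maps
    use [-1, 1] and set ``signed``); ``classes`` carries the per-cell
    class channel.  ``metadata`` always records scale type, tau,
    orientation, level and order provenance, and accompanies every
    exported image as sidecar JSON.
    """

    intensity: np.ndarray
    classes: np.ndarray
    metadata: Dict[str, object]
    signed: bool = False
    boundaries: List[Tuple[Tuple[int, int], Tuple[int, int]]] = field(
        default_factory=list
    )
    path: Optional[List[Tuple[int, int]]] = None

    @property
    def side(self) -> int:
        return self.intensity.shape[0]


def _base_metadata(layout: HilbertLayout, opts: RenderOptions, scale: str) -> Dict:
    return {
        "level": layout.k,
        "side": layout.side,
        "orientation": "origin top-left; level-1 order (0,0)->(0,1)->(1,1)->(1,0)",
        "scale": scale,
        "tau": opts.tau,
        "order_provenance": layout.order.provenance,
        "n_taxa": layout.n_taxa,
        "n_gap_cells": sum(d1 - d0 + 1 for d0, d1 in layout.gaps),
    }


def _class_grid(layout: HilbertLayout) -> np.ndarray:
    side = layout.side
    classes = np.full((side, side), CLASS_ASSIGNED, dtype=np.uint8)
    for d0, d1 in layout.gaps:
        for d in range(d0, d1 + 1):
            x, y = index_to_cell(layout.k, d)
            classes[y, x] = CLASS_GAP
    return classes


def _paint(layout: HilbertLayout, per_taxon: Mapping[str, float]) -> np.ndarray:
    """Raw per-cell values: every cell of a taxon's interval gets its value."""
    side = layout.side
    grid = np.zeros((side, side), dtype=float)
    for taxon, (d0, d1) in layout.assignment.items():
        v = per_taxon[taxon]
        for d in range(d0, d1 + 1):
            x, y = index_to_cell(layout.k, d)
            grid[y, x] = v
    return grid


def _as_vector(sample: Union[Mapping[str, float], "object"], layout: HilbertLayout) -> Dict[str, float]:
    try:
        get = sample.__getitem__
        keys = set(sample.keys()) if hasattr(sample, "keys") else set(sample.index)
    except AttributeError as exc:
        raise TypeError("sample must be a mapping or Series of taxon -> abundance") from exc
    missing = [t for t in layout.assignment if t not in keys]
    if missing:
        raise ValueError(
            f"abundance vector is missing {len(missing)} layout taxa, e.g. "
            f"{missing[:5]}"
        )
    return {t: float(get(t)) for t in layout.assignment}


def _scale_values(
    values: Dict[str, float], opts: RenderOptions
) -> Tuple[Dict[str, float], Dict[str, bool], float]:
    """Normalize abundances to display intensities.

    Returns (intensity per taxon, above-threshold flag per taxon, the
    normalizing maximum).  Sub-tau abundances get intensity 0 and are
    flagged as zero-class.
    """
    tau = opts.tau
    above = {t: (v > 0 and v >= tau) for t, v in values.items()}
    vmax = max((v for t, v in values.items() if above[t]), default=0.0)
    out: Dict[str, float] = {}
    for t, v in values.items():
        if not above[t] or vmax <= 0:
            out[t] = 0.0
        elif opts.scale == "linear":
            out[t] = v / vmax
        else:  # log10 with floor tau
            if vmax <= tau:
                out[t] = 1.0
            else:
                out[t] = (math.log10(v) - math.log10(tau)) / (
                    math.log10(vmax) - math.log10(tau)
                )
    return out, above, vmax


def intensity_map(
    sample: Union[Mapping[str, float], "object"],
    layout: HilbertLayout,
    opts: RenderOptions = RenderOptions(),
    scale_max: Optional[float] = None,
) -> MapRaster:
    """Single-sample map: one intensity per taxon, painted over its cells.

    Multi-cell (merged) taxa paint all their cells with one value.
    Abundances below the display floor tau render as the zero-abundance
    class.  ``scale_max`` overrides the normalizing maximum (used by
    animation frames to share one global scale).
    """
    values = _as_vector(sample, layout)
    intens, above, vmax = _scale_values(values, opts)
    if scale_max is not None and scale_max > 0:
        if opts.scale == "linear":
            intens = {
                t: (values[t] / scale_max if above[t] else 0.0) for t in values
            }
        else:
            tau = opts.tau
            denom = math.log10(scale_max) - math.log10(tau)
            intens = {
                t: (
                    (math.log10(values[t]) - math.log10(tau)) / denom
                    if above[t] and denom > 0
                    else (1.0 if above[t] else 0.0)
                )
                for t in values
            }
        vmax = scale_max
    grid = _paint(layout, intens)
    np.clip(grid, 0.0, 1.0, out=grid)
    classes = _class_grid(layout)
    for taxon, (d0, d1) in layout.assignment.items():
        if not above[taxon]:
            for d in range(d0, d1 + 1):
                x, y = index_to_cell(layout.k, d)
                classes[y, x] = CLASS_ZERO
    meta = _base_metadata(layout, opts, opts.scale)
    meta["map_type"] = "single"
    meta["scale_max"] = vmax
    raster = MapRaster(intensity=grid, classes=classes, metadata=meta)
    _apply_overlays(raster, layout, opts)
    return raster


def colorless_map(
    layout: HilbertLayout, grouping: str, opts: RenderOptions = RenderOptions()
) -> MapRaster:
    """Reference-collection map with no abundance channel.

    Shows only the neighborhood boundaries (and optionally the curve
    path), giving a visual census of the collection's taxonomic
    distribution: region area tracks clade size.
    """
    side = layout.side
    grid = np.zeros((side, side), dtype=float)
    classes = _class_grid(layout)
    meta = _base_metadata(layout, opts, "none")
    meta["map_type"] = "colorless"
    meta["grouping"] = grouping
    nbs = neighborhoods(layout, grouping)
    boundaries = [e for nb in nbs for e in nb.boundary]
    raster = MapRaster(
        intensity=grid, classes=classes, metadata=meta, boundaries=boundaries
    )
    if opts.show_path:
        overlay_path(raster, layout)
    return raster


def _reduce(
    samples: Sequence[Union[Mapping[str, float], "object"]],
    layout: HilbertLayout,
    reducer: str,
) -> Dict[str, float]:
    if not samples:
        raise ValueError("need at least one sample vector")
    if reducer not in AGGREGATE_REDUCERS:
        raise ValueError(
            f"unknown reducer {reducer!r}; choose from {sorted(AGGREGATE_REDUCERS)}"
        )
    vectors = [_as_vector(s, layout) for s in samples]
    taxa = list(layout.assignment)
    arr = np.array([[vec[t] for t in taxa] for vec in vectors], dtype=float)
    red = AGGREGATE_REDUCERS[reducer](arr)
    return dict(zip(taxa, red))


def average_map(
    samples: Sequence[Union[Mapping[str, float], "object"]],
    layout: HilbertLayout,
    opts: RenderOptions = RenderOptions(),
) -> MapRaster:
    """Cell-wise arithmetic mean of several samples, then scaled as usual."""
    raster = intensity_map(_reduce(samples, layout, "mean"), layout, opts)
    raster.metadata["map_type"] = "average"
    raster.metadata["n_samples"] = len(samples)
    return raster


def aggregate_map(
    samples: Sequence[Union[Mapping[str, float], "object"]],
    layout: HilbertLayout,
    reducer: str = "sum",
    opts: RenderOptions = RenderOptions(),
) -> MapRaster:
    """Cell-wise reduction (sum, median, max, mean) of several samples."""
    raster = intensity_map(_reduce(samples, layout, reducer), layout, opts)
    raster.metadata["map_type"] = f"aggregate:{reducer}"
    raster.metadata["n_samples"] = len(samples)
    return raster


def differential_map(
    a: Union[Mapping[str, float], "object"],
    b: Union[Mapping[str, float], "object"],
    layout: HilbertLayout,
    opts: RenderOptions = RenderOptions(),
) -> MapRaster:
    """Signed per-cell difference ``a - b`` on a diverging scale.

    Values are normalized by the largest absolute difference onto
    [-1, 1] and centered at zero; the metadata records the operand
    order.  ``differential_map(a, a)`` is identically zero and
    ``differential_map(a, b) == -differential_map(b, a)`` cell-wise.
    """
    va = _as_vector(a, layout)
    vb = _as_vector(b, layout)
    diff = {t: va[t] - vb[t] for t in va}
    dmax = max((abs(v) for v in diff.values()), default=0.0)
    intens = {t: (v / dmax if dmax > 0 else 0.0) for t, v in diff.items()}
    grid = _paint(layout, intens)
    classes = _class_grid(layout)
    meta = _base_metadata(layout, opts, "diverging")
    meta["map_type"] = "differential"
    meta["operands"] = "a-b"
    meta["scale_max"] = dmax
    raster = MapRaster(
        intensity=grid, classes=classes, metadata=meta, signed=True
    )
    _apply_overlays(raster, layout, opts)
    return raster


def animation_frames(
    series: Sequence[Tuple[str, Union[Mapping[str, float], "object"]]],
    layout: HilbertLayout,
    opts: RenderOptions = RenderOptions(),
) -> List[MapRaster]:
    """One frame per (key, sample) pair with a shared global scale.

    All frames are normalized by the global maximum abundance across the
    whole series so brightness is comparable frame to frame; each frame's
    metadata carries its series key (time point or condition).
    """
    if len(series) < 2:
        raise ValueError("an animation needs at least two samples")
    vectors = [(key, _as_vector(s, layout)) for key, s in series]
    tau = opts.tau
    global_max = max(
        (v for _, vec in vectors for v in vec.values() if v > 0 and v >= tau),
        default=0.0,
    )
    frames: List[MapRaster] = []
    for key, vec in vectors:
        raster = intensity_map(vec, layout, opts, scale_max=global_max or None)
        raster.metadata["map_type"] = "frame"
        raster.metadata["series_key"] = key
        raster.metadata["scale_max"] = global_max
        frames.append(raster)
    return frames


def overlay_path(raster: MapRaster, layout: HilbertLayout) -> MapRaster:
    """Attach the curve polyline (through cell centers, in curve order)."""
    if raster.side != layout.side:
        raise ValueError(
            f"raster side {raster.side} does not match layout side {layout.side}"
        )
    raster.path = [index_to_cell(layout.k, d) for d in range(layout.n_cells)]
    return raster


def _apply_overlays(
    raster: MapRaster, layout: HilbertLayout, opts: RenderOptions
) -> None:
    if opts.show_boundaries:
        grouping = opts.boundaries_grouping
        if grouping is None and layout.order.groups:
            grouping = next(iter(layout.order.groups))
        if grouping is not None:
            nbs = neighborhoods(layout, grouping)
            raster.boundaries = [e for nb in nbs for e in nb.boundary]
    if opts.show_path:
        overlay_path(raster, layout)


# ---------------------------------------------------------------------------
# image export


def _group_hue_lut(layout: HilbertLayout, grouping: str) -> Dict[str, float]:
    import colorsys

    runs = layout.order.runs(grouping)
    n = len(runs)
    return {label: i / max(n, 1) for i, (label, _, _) in enumerate(runs)}


def _to_rgb(
    raster: MapRaster, layout: Optional[HilbertLayout], opts: RenderOptions
) -> np.ndarray:
    """Per-cell RGB array (uint8) before upscaling."""
    from matplotlib import colormaps

    side = raster.side
    rgb = np.zeros((side, side, 3), dtype=np.uint8)
    if raster.signed:
        cmap = colormaps[opts.diverging_colormap]
        mapped = (cmap((raster.intensity + 1.0) / 2.0)[..., :3] * 255).astype(np.uint8)
    else:
        cmap = colormaps[opts.colormap]
        mapped = (cmap(raster.intensity)[..., :3] * 255).astype(np.uint8)
    rgb[...] = mapped
    if opts.group_hues and layout is not None and not raster.signed:
        import colorsys

        lut = _group_hue_lut(layout, opts.group_hues)
        for label, start, end in layout.order.runs(opts.group_hues):
            hue = lut[label]
            for taxon in layout.order.taxa[start:end]:
                d0, d1 = layout.assignment[taxon]
                for d in range(d0, d1 + 1):
                    x, y = index_to_cell(layout.k, d)
                    val = float(raster.intensity[y, x])
                    r, g, b = colorsys.hsv_to_rgb(hue, 0.85, 0.15 + 0.85 * val)
                    rgb[y, x] = (int(r * 255), int(g * 255), int(b * 255))
    rgb[raster.classes == CLASS_GAP] = GAP_RGB
    if raster.metadata.get("map_type") == "colorless":
        rgb[raster.classes != CLASS_GAP] = (255, 255, 255)
    return rgb


def _render_image(
    raster: MapRaster, layout: Optional[HilbertLayout], opts: RenderOptions
):
    from PIL import Image, ImageDraw

    px = opts.cell_px
    rgb = _to_rgb(raster, layout, opts)
    big = np.kron(rgb, np.ones((px, px, 1), dtype=np.uint8))
    img = Image.fromarray(big, mode="RGB")
    draw = ImageDraw.Draw(img)
    if raster.path:
        pts = [(x * px + px // 2, y * px + px // 2) for x, y in raster.path]
        draw.line(pts, fill=(255, 80, 80), width=max(1, px // 8))
    for (x0, y0), (x1, y1) in raster.boundaries:
        draw.line(
            [(x0 * px, y0 * px), (x1 * px, y1 * px)],
            fill=(0, 0, 0),
            width=max(1, px // 6),
        )
    return img


def _write_metadata(path: Path, raster: MapRaster) -> None:
    meta_path = path.with_suffix(path.suffix + ".json")
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(raster.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")


def save_png(
    raster: MapRaster,
    path: Union[str, Path],
    layout: Optional[HilbertLayout] = None,
    opts: RenderOptions = RenderOptions(),
) -> Path:
    """Write the raster as PNG plus a sidecar ``.png.json`` metadata file."""
    path = Path(path)
    img = _render_image(raster, layout, opts)
    img.save(path, format="PNG")
    _write_metadata(path, raster)
    return path


def save_svg(
    raster: MapRaster,
    path: Union[str, Path],
    layout: Optional[HilbertLayout] = None,
    opts: RenderOptions = RenderOptions(),
) -> Path:
    """Write the raster as an SVG of unit cell rectangles plus overlays.

    The SVG is plain hand-assembled markup (one ``rect`` per cell, one
    ``polyline`` for the curve path, ``line`` elements for boundaries),
    written deterministically so repeated exports are byte-identical.
    """
    path = Path(path)
    px = opts.cell_px
    rgb = _to_rgb(raster, layout, opts)
    side = raster.side
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{side * px}" '
        f'height="{side * px}" viewBox="0 0 {side * px} {side * px}">',
    ]
    for y in range(side):
        for x in range(side):
            r, g, b = rgb[y, x]
            lines.append(
                f'<rect x="{x * px}" y="{y * px}" width="{px}" height="{px}" '
                f'fill="#{r:02x}{g:02x}{b:02x}"/>'
            )
    for (x0, y0), (x1, y1) in raster.boundaries:
        lines.append(
            f'<line x1="{x0 * px}" y1="{y0 * px}" x2="{x1 * px}" '
            f'y2="{y1 * px}" stroke="black" stroke-width="{max(1, px // 6)}"/>'
        )
    if raster.path:
        pts = " ".join(
            f"{x * px + px // 2},{y * px + px // 2}" for x, y in raster.path
        )
        lines.append(
            f'<polyline points="{pts}" fill="none" stroke="#ff5050" '
            f'stroke-width="{max(1, px // 8)}"/>'
        )
    lines.append("</svg>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    _write_metadata(path, raster)
    return path


def save_animation(
    frames: Sequence[MapRaster],
    path: Union[str, Path],
    layout: Optional[HilbertLayout] = None,
    opts: RenderOptions = RenderOptions(),
    fps: float = 2.0,
) -> Path:
    """Encode frames as GIF/MP4 via imageio (format from the extension)."""
    import imageio.v3 as iio

    path = Path(path)
    images = [np.asarray(_render_image(f, layout, opts)) for f in frames]
    if path.suffix.lower() == ".gif":
        iio.imwrite(path, images, duration=1000.0 / fps, loop=0)
    else:
        iio.imwrite(path, images, fps=fps)
    if frames:
        _write_metadata(path, frames[0])
    return path
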