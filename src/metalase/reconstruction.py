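"""Scattered-event gridding onto a Cartesian pixel grid.

Per-pulse events sampled along the sinusoidal scan trajectory are rendered
onto a regular (possibly asymmetric) pixel grid by Delaunay-based scattered
data interpolation — Sibson natural-neighbor by default, with barycentric
linear interpolation as an alternative.  Pixels outside the convex hull of
the event cloud are masked invalid and serialized as NaN.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay

from ._sibson import NaturalNeighborInterpolator
from .signal_extraction import VALUE_COLUMNS, PulseEventTable

logger = logging.getLogger(__name__)

_OME_NS = "http://www.openmicroscopy.org/Schemas/OME/2016-06"


@dataclass(frozen=True)
class GridSpec:
    """Cartesian pixel grid: pixel (0, 0) centre at ``origin`` (um),
    row index along the slow axis, column index along the fast axis."""

    origin: tuple[float, float]      # (x0, y0) um
    spacing: tuple[float, float]     # (fast dx, slow dy) um
    shape: tuple[int, int]           # (rows, cols)

    def __post_init__(self) -> None:
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"grid spacings must be > 0, got {self.spacing!r}")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError(f"grid shape must be >= 1x1, got {self.shape!r}")

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[1]) * self.spacing[0]

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[0]) * self.spacing[1]

    def pixel_centers(self) -> np.ndarray:
        xx, yy = np.meshgrid(self.x, self.y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @classmethod
    def from_events(cls, events: PulseEventTable,
                    spacing_fast: float = 0.25,
                    spacing_slow: float = 0.25) -> "GridSpec":
        """Grid over the event bounding box, shrunk by one pixel on each
        side so that most pixels fall inside the convex hull."""
        pos = events.positions
        x0, y0 = pos.min(axis=0)
        x1, y1 = pos.max(axis=0)
        x0, x1 = x0 + spacing_fast, x1 - spacing_fast
        y0, y1 = y0 + spacing_slow, y1 - spacing_slow
        ncols = max(1, int(np.floor((x1 - x0) / spacing_fast)) + 1)
        nrows = max(1, int(np.floor((y1 - y0) / spacing_slow)) + 1)
        return cls(origin=(float(x0), float(y0)),
                   spacing=(float(spacing_fast), float(spacing_slow)),
                   shape=(nrows, ncols))


@dataclass
class ImageStack:
    """Per-channel images on a common grid; NaN marks invalid pixels."""

    channels: dict[str, np.ndarray]
    mask: np.ndarray
    grid: GridSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {img.shape for img in self.channels.values()} | {self.mask.shape}
        if shapes != {self.grid.shape}:
            raise ValueError(
                f"channel/mask shapes {shapes} do not match grid shape {self.grid.shape}")

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


def grid_channels(events: PulseEventTable, grid: GridSpec | None = None,
                  method: str = "natural_neighbor",
                  spacing_fast: float = 0.25,
                  spacing_slow: float = 0.25) -> ImageStack:
    """Interpolate all five event channels onto ``grid``.

    Events with exactly duplicated positions are averaged first (and
    counted); events are then sorted lexicographically so the output is
    invariant under row permutation of the input table.  All channels share
    one Delaunay triangulation.
    """
    if method not in ("natural_neighbor", "linear"):
        raise ValueError(f"unknown interpolation method {method!r}")
    pos = events.positions
    vals = events.df.loc[:, list(VALUE_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("event table contains non-finite optical values")

    # average duplicates, then sort for order invariance
    order = np.lexsort((pos[:, 1], pos[:, 0]))
    pos, vals = pos[order], vals[order]
    uniq, inverse, counts = np.unique(pos, axis=0, return_inverse=True, return_counts=True)
    if len(uniq) < len(pos):
        summed = np.zeros((len(uniq), vals.shape[1]))
        np.add.at(summed, inverse, vals)
        vals = summed / counts[:, None]
        pos = uniq
        logger.info("averaged %d duplicate event positions", len(inverse) - len(uniq))
    if len(pos) < 3:
        raise ValueError("need at least 3 non-collinear event positions to triangulate")

    try:
        tri = Delaunay(pos)
    except Exception as exc:  # qhull degeneracy
        raise ValueError(f"degenerate event cloud (collinear or duplicate-only): {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("degenerate event cloud: no valid triangulation")

    if grid is None:
        grid = GridSpec.from_events(events, spacing_fast, spacing_slow)
    queries = grid.pixel_centers()

    if method == "natural_neighbor":
        interp = NaturalNeighborInterpolator(tri, vals)
        flat = interp(queries)
        n_fallback = interp.n_fallback
    else:
        flat = np.column_stack([
            LinearNDInterpolator(tri, vals[:, k])(queries) for k in range(vals.shape[1])
        ])
        n_fallback = 0

    images = {name: flat[:, k].reshape(grid.shape)
              for k, name in enumerate(VALUE_COLUMNS)}
    mask = np.isfinite(flat[:, 0]).reshape(grid.shape)
    meta = {"method": method, "n_events": int(len(pos)), "n_fallback_pixels": int(n_fallback)}
    return ImageStack(channels=images, mask=mask, grid=grid, meta=meta)


# ---------------------------------------------------------------------------
# OME-TIFF serialization (deterministic: no UUID / timestamps)


def _ome_xml(channel_names: list[str], shape: tuple[int, int],
             spacing: tuple[float, float], origin: tuple[float, float],
             meta: dict) -> str:
    ET.register_namespace("", _OME_NS)
    ome = ET.Element(f"{{{_OME_NS}}}OME")
    image = ET.SubElement(ome, f"{{{_OME_NS}}}Image", ID="Image:0")
    pixels = ET.SubElement(
        image, f"{{{_OME_NS}}}Pixels", ID="Pixels:0", DimensionOrder="XYCZT",
        Type="float", SizeX=str(shape[1]), SizeY=str(shape[0]),
        SizeC=str(len(channel_names)), SizeZ="1", SizeT="1",
        PhysicalSizeX=repr(spacing[0]), PhysicalSizeY=repr(spacing[1]),
        PhysicalSizeXUnit="um", PhysicalSizeYUnit="um")
    for i, name in enumerate(channel_names):
        ET.SubElement(pixels, f"{{{_OME_NS}}}Channel",
                      ID=f"Channel:0:{i}", Name=name, SamplesPerPixel="1")
    for i in range(len(channel_names)):
        td = ET.SubElement(pixels, f"{{{_OME_NS}}}TiffData",
                           FirstC=str(i), IFD=str(i), PlaneCount="1")
        del td
    ann = ET.SubElement(ome, f"{{{_OME_NS}}}StructuredAnnotations")
    xa = ET.SubElement(ann, f"{{{_OME_NS}}}XMLAnnotation", ID="Annotation:0")
    val = ET.SubElement(xa, f"{{{_OME_NS}}}Value")
    val.text = json.dumps({"origin_um": list(origin), "meta": meta}, sort_keys=True)
    return ET.tostring(ome, encoding="unicode")


def save_ome_tiff(stack: ImageStack, path) -> None:
    """Write the stack as a multi-page float32 OME-TIFF (NaN = invalid)."""
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    desc = _ome_xml(names, stack.grid.shape, stack.grid.spacing,
                    stack.grid.origin, stack.meta)
    tifffile.imwrite(path, data, description=desc, metadata=None,
                     photometric="minisblack")


def load_ome_tiff(path) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    root = ET.fromstring(desc)
    pixels = root.find(f"{{{_OME_NS}}}Image/{{{_OME_NS}}}Pixels")
    names = [ch.get("Name") for ch in pixels.findall(f"{{{_OME_NS}}}Channel")]
    spacing = (float(pixels.get("PhysicalSizeX")), float(pixels.get("PhysicalSizeY")))
    extra = json.loads(root.find(
        f"{{{_OME_NS}}}StructuredAnnotations/{{{_OME_NS}}}XMLAnnotation/{{{_OME_NS}}}Value").text)
    data = np.atleast_3d(data)
    if data.shape[-1] == len(names) and data.shape[0] != len(names):
        data = np.moveaxis(data, -1, 0)
    grid = GridSpec(origin=tuple(extra["origin_um"]), spacing=spacing,
                    shape=data.shape[1:])
    channels = {name: data[i].astype(np.float64) for i, name in enumerate(names)}
    mask = np.isfinite(next(iter(channels.values())))
    return ImageStack(channels=channels, mask=mask, grid=grid, meta=extra.get("meta", {}))
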