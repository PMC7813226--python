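"""Scriptable 3D freeform painting into a tag volume, plus region growing,
connected components, and tag-based sub-volume extraction.

The painter writes integer tags (1–255; 0 = untagged) into a
:class:`TagVolume` parallel to the scan.  The brush is a Euclidean sphere
in voxel units stamped along a stroke polyline; consecutive stroke centres
are resampled at half-radius spacing so the swept tube has no gaps.  A
stroke may be restricted to a selection mask so painting cannot leak out
of the thresholded phase — the scripted analogue of painting on a
thresholded view.  Tagged regions are exported as separate volumes cropped
to their bounding box (the tagging/extract workflow).

Strokes serialize as JSON lines:
``{"centers": [[z,y,x], ...], "radius": r, "tag": t, "mode": "paint"}``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DimensionMismatchError,
    EmptySelectionError,
    InvalidArgumentError,
    SeedNotInSelectionError,
)
from .morphology import structuring_element
from .threshold import SelectionMask
from .volume import Volume

__all__ = [
    "TagVolume",
    "BrushStroke",
    "sphere_voxels",
    "apply_stroke",
    "read_stroke_script",
    "region_grow",
    "connected_components",
    "extract_tag",
]

MAX_TAG = 255  # 8-bit tag volume


@dataclass
class TagVolume:
    """Per-voxel integer labels in ``[0, 255]``; 0 means untagged."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionMismatchError(f"tag volume must be 3D, got {self.data.shape}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > MAX_TAG):
            raise InvalidArgumentError("tag values must lie in [0, 255]")
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.data.shape)

    @classmethod
    def zeros(cls, dims, voxel_size_um=(1.0, 1.0, 1.0)) -> "TagVolume":
        return cls(np.zeros(dims, dtype=np.uint8), voxel_size_um)

    def mask(self, tag: int) -> SelectionMask:
        """Boolean mask of one tag."""
        return SelectionMask(self.data == tag, self.voxel_size_um)


@dataclass
class BrushStroke:
    """A polyline of sphere stamps carrying one tag.

    ``mode='paint'`` writes the tag over any prior value inside the
    footprint; ``mode='erase'`` resets covered voxels *of that same tag*
    to 0 (other tags are protected).
    """

    centers: Sequence[tuple[float, float, float]]
    radius_vox: float
    tag: int
    mode: str = "paint"

    def __post_init__(self) -> None:
        if len(self.centers) == 0:
            raise InvalidArgumentError("stroke needs at least one center")
        if self.radius_vox < 0:
            raise InvalidArgumentError(f"radius must be ≥ 0, got {self.radius_vox}")
        if self.mode not in ("paint", "erase"):
            raise InvalidArgumentError(f"mode must be 'paint' or 'erase', got {self.mode!r}")
        if not (1 <= self.tag <= MAX_TAG):
            raise InvalidArgumentError(f"tag must be in 1..{MAX_TAG}, got {self.tag}")


def sphere_voxels(
    center: tuple[float, float, float], radius_vox: float, dims: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of voxels whose centre lies within ``radius_vox`` of ``center``.

    Clipped to the volume bounds; returns ``(z, y, x)`` index arrays.
    """
    if radius_vox < 0:
        raise InvalidArgumentError(f"radius must be ≥ 0, got {radius_vox}")
    cz, cy, cx = center
    lo = [max(0, int(math.floor(c - radius_vox))) for c in (cz, cy, cx)]
    hi = [
        min(d - 1, int(math.ceil(c + radius_vox)))
        for c, d in zip((cz, cy, cx), dims)
    ]
    if any(l > h for l, h in zip(lo, hi)):
        empty = np.empty(0, dtype=np.intp)
        return empty, empty.copy(), empty.copy()
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    inside = d2 <= radius_vox**2 + 1e-12
    return zz[inside].ravel(), yy[inside].ravel(), xx[inside].ravel()


def _sample_polyline(
    centers: Sequence[tuple[float, float, float]], radius: float
) -> Iterable[tuple[float, float, float]]:
    """Stroke centres plus intermediate samples ≤ 0.5·radius apart.

    For a point brush (radius 0) segments are sampled at half-voxel
    spacing so a drawn line still stamps every voxel it passes near.
    """
    step = max(0.5 * radius, 0.5)
    pts = [tuple(float(c) for c in p) for p in centers]
    yield pts[0]
    for a, b in zip(pts[:-1], pts[1:]):
        dist = math.dist(a, b)
        n = max(1, int(math.ceil(dist / step)))
        for k in range(1, n + 1):
            t = k / n
            yield tuple(ai + t * (bi - ai) for ai, bi in zip(a, b))


def apply_stroke(
    tags: TagVolume, stroke: BrushStroke, restrict: SelectionMask | None = None
) -> TagVolume:
    """Stamp a brush stroke into a copy of the tag volume and return it.

    Only voxels inside the swept sphere footprint are touched; when
    ``restrict`` is given, only footprint voxels where the mask is True
    are modified.
    """
    if restrict is not None and restrict.dims != tags.dims:
        raise DimensionMismatchError(
            f"restrict dims {restrict.dims} != tag dims {tags.dims}"
        )
    footprint = np.zeros(tags.dims, dtype=bool)
    for p in _sample_polyline(stroke.centers, stroke.radius_vox):
        z, y, x = sphere_voxels(p, stroke.radius_vox, tags.dims)
        footprint[z, y, x] = True
    if restrict is not None:
        footprint &= restrict.data
    out = tags.data.copy()
    if stroke.mode == "paint":
        out[footprint] = stroke.tag
    else:  # erase clears only this stroke's own tag
        out[footprint & (tags.data == stroke.tag)] = 0
    return TagVolume(out, tags.voxel_size_um)


def read_stroke_script(path: str | Path) -> list[BrushStroke]:
    """Parse a JSON-lines stroke script (one stroke object per line)."""
    strokes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        doc = json.loads(line)
        strokes.append(
            BrushStroke(
                centers=[tuple(c) for c in doc["centers"]],
                radius_vox=float(doc["radius"]),
                tag=int(doc["tag"]),
                mode=doc.get("mode", "paint"),
            )
        )
    return strokes


def region_grow(
    mask: SelectionMask, seed: tuple[int, int, int], connectivity: int = 6
) -> SelectionMask:
    """Connected component of the mask containing the seed voxel."""
    seed = tuple(int(s) for s in seed)
    if any(s < 0 or s >= d for s, d in zip(seed, mask.dims)):
        raise SeedNotInSelectionError(f"seed {seed} outside volume dims {mask.dims}")
    if not mask.data[seed]:
        raise SeedNotInSelectionError(f"seed {seed} is not inside the selection")
    labels, _ = ndimage.label(mask.data, structure=structuring_element(connectivity))
    return SelectionMask(labels == labels[seed], mask.voxel_size_um)


def connected_components(
    mask: SelectionMask, connectivity: int = 6
) -> tuple[np.ndarray, list[int]]:
    """Label connected components 1..K in raster (z, y, x) first-encounter order.

    Returns the integer label grid and the per-component voxel counts;
    the counts sum to the mask's set-voxel count.
    """
    labels, k = ndimage.label(mask.data, structure=structuring_element(connectivity))
    if k == 0:
        return labels.astype(np.int32), []
    # relabel in first-encounter raster order
    flat = labels.ravel()
    labs = flat[flat != 0]
    uniq, first_idx = np.unique(labs, return_index=True)
    remap = np.zeros(k + 1, dtype=np.int32)
    remap[uniq[np.argsort(first_idx)]] = np.arange(1, len(uniq) + 1)
    relabeled = remap[labels]
    sizes = np.bincount(relabeled.ravel(), minlength=len(uniq) + 1)[1:]
    return relabeled, [int(s) for s in sizes]


def extract_tag(vol: Volume, tags: TagVolume, tag: int, pad_value: int = 0) -> Volume:
    """Export one tagged region as a separate volume.

    The output is cropped to the tag's tight bounding box; voxels carrying
    the tag keep their original scan values, all others are set to
    ``pad_value``.  Bit depth and voxel size are inherited.
    """
    if vol.dims != tags.dims:
        raise DimensionMismatchError(f"volume dims {vol.dims} != tag dims {tags.dims}")
    where = tags.data == tag
    if not where.any():
        raise EmptySelectionError(f"tag {tag} not present in tag volume")
    zs, ys, xs = np.nonzero(where)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in (zs, ys, xs))
    out = np.full(tuple(s.stop - s.start for s in sl), pad_value, dtype=vol.data.dtype)
    sub = where[sl]
    out[sub] = vol.data[sl][sub]
    return Volume(
        out,
        voxel_size_um=vol.voxel_size_um,
        bit_depth=vol.bit_depth,
        name=f"{vol.name}:tag{tag}" if vol.name else f"tag{tag}",
    )
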