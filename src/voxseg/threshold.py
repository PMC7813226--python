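"""Gradient thresholding operators and combined value/gradient selection.

Three per-voxel gradient measures are computed on a normalized volume
(values in ``[0, 1]``), each clamped to ``[0, 1]``:

* **type 1** — the Euclidean magnitude of the central-difference gradient,
  ``g = ‖(∂v/∂x, ∂v/∂y, ∂v/∂z)‖₂`` with replicate-padded borders.
* **type 2** — sum the 3×3×3 box around the voxel, subtract the central
  value (leaving the 26 neighbours), divide by 10, and take the absolute
  difference from the central value: ``g = |v_c − (S₃ − v_c)/10|``.
* **type 3** — the same with a 5×5×5 box (124 neighbours) and divisor 70:
  ``g = |v_c − (S₅ − v_c)/70|``.

Types 2 and 3 are deliberately value-shifted: on a constant volume they
grow with the constant, so bright phases carry larger "gradient" values
than dark ones at equal local contrast.  Combining a value range with a
gradient range (multiple-thresholding) selects phase interiors or phase
boundaries and is typically the first step of segmenting a volume.

Border handling is replicate padding for all three types, so a constant
volume yields an exactly constant field.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .errors import DimensionMismatchError, InvalidArgumentError
from .volume import NormalizedVolume

__all__ = [
    "GradientType",
    "GradientField",
    "ThresholdSpec",
    "SelectionMask",
    "gradient_volume",
    "gradient_volume_oracle",
    "histogram2d",
    "select",
]


class GradientType(Enum):
    """Which gradient measure a threshold specification uses."""

    NONE = "none"
    TYPE1_CENTRAL = "type1"
    TYPE2_BOX3 = "type2"
    TYPE3_BOX5 = "type3"


# box-sum divisors for the value-shifted gradient types
_DIVISOR = {GradientType.TYPE2_BOX3: 10.0, GradientType.TYPE3_BOX5: 70.0}
_BOX = {GradientType.TYPE2_BOX3: 3, GradientType.TYPE3_BOX5: 5}


@dataclass
class GradientField:
    """Per-voxel gradient measure in ``[0, 1]`` for one operator type."""

    data: np.ndarray
    gtype: GradientType
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.data.shape)


@dataclass
class ThresholdSpec:
    """A closed value range × closed gradient range predicate on voxels."""

    value_lo: float = 0.0
    value_hi: float = 1.0
    gtype: GradientType = GradientType.NONE
    grad_lo: float = 0.0
    grad_hi: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (self.value_lo, self.value_hi, "value"),
            (self.grad_lo, self.grad_hi, "gradient"),
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise InvalidArgumentError(
                    f"{what} range must satisfy 0 ≤ lo ≤ hi ≤ 1, got [{lo}, {hi}]"
                )


@dataclass
class SelectionMask:
    """Boolean voxel grid; True = selected."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise DimensionMismatchError(f"mask must be 3D, got shape {self.data.shape}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.data.shape)

    @property
    def count(self) -> int:
        return int(self.data.sum())


def _central_differences(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = np.pad(v, 1, mode="edge")
    gz = (p[2:, 1:-1, 1:-1] - p[:-2, 1:-1, 1:-1]) / 2.0
    gy = (p[1:-1, 2:, 1:-1] - p[1:-1, :-2, 1:-1]) / 2.0
    gx = (p[1:-1, 1:-1, 2:] - p[1:-1, 1:-1, :-2]) / 2.0
    return gz, gy, gx


def gradient_volume(nv: NormalizedVolume, gtype: GradientType) -> GradientField:
    """Compute one of the three gradient fields, clamped to ``[0, 1]``."""
    if gtype == GradientType.NONE:
        raise InvalidArgumentError("gradient_volume requires a concrete gradient type")
    v = nv.data
    if gtype == GradientType.TYPE1_CENTRAL:
        gz, gy, gx = _central_differences(v)
        g = np.sqrt(gx * gx + gy * gy + gz * gz)
    else:
        size = _BOX[gtype]
        kernel = np.ones((size, size, size), dtype=np.float64)
        box_sum = ndimage.correlate(v, kernel, mode="nearest")
        neighbour_sum = box_sum - v  # box minus the central value
        g = np.abs(v - neighbour_sum / _DIVISOR[gtype])
    return GradientField(np.clip(g, 0.0, 1.0), gtype, nv.voxel_size_um)


def gradient_volume_oracle(nv: NormalizedVolume, gtype: GradientType) -> GradientField:
    """Reference evaluation of :func:`gradient_volume` with explicit per-voxel loops.

    Identical contract; intended for cross-checking in tests only.
    """
    if gtype == GradientType.NONE:
        raise InvalidArgumentError("gradient_volume requires a concrete gradient type")
    v = nv.data
    nz, ny, nx = v.shape
    out = np.zeros_like(v, dtype=np.float64)

    def at(z: int, y: int, x: int) -> float:
        # replicate padding: clamp indices to the grid
        return v[min(max(z, 0), nz - 1), min(max(y, 0), ny - 1), min(max(x, 0), nx - 1)]

    if gtype == GradientType.TYPE1_CENTRAL:
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    gz = (at(z + 1, y, x) - at(z - 1, y, x)) / 2.0
                    gy = (at(z, y + 1, x) - at(z, y - 1, x)) / 2.0
                    gx = (at(z, y, x + 1) - at(z, y, x - 1)) / 2.0
                    out[z, y, x] = (gx * gx + gy * gy + gz * gz) ** 0.5
    else:
        r = _BOX[gtype] // 2
        div = _DIVISOR[gtype]
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    s = 0.0
                    for dz in range(-r, r + 1):
                        for dy in range(-r, r + 1):
                            for dx in range(-r, r + 1):
                                s += at(z + dz, y + dy, x + dx)
                    vc = v[z, y, x]
                    out[z, y, x] = abs(vc - (s - vc) / div)
    return GradientField(np.clip(out, 0.0, 1.0), gtype, nv.voxel_size_um)


def histogram2d(
    nv: NormalizedVolume, gf: GradientField, value_bins: int = 256, grad_bins: int = 256
) -> np.ndarray:
    """2D (value × gradient) voxel-count table over ``[0,1]×[0,1]``.

    Uniform bin edges; the last bin of each axis is right-closed, so counts
    always sum to the total voxel count.
    """
    if value_bins < 1 or grad_bins < 1:
        raise InvalidArgumentError("bin counts must be ≥ 1")
    if nv.dims != gf.dims:
        raise DimensionMismatchError(f"volume dims {nv.dims} != gradient dims {gf.dims}")
    counts, _, _ = np.histogram2d(
        nv.data.ravel(),
        gf.data.ravel(),
        bins=(value_bins, grad_bins),
        range=((0.0, 1.0), (0.0, 1.0)),
    )
    return counts.astype(np.int64)


def select(
    nv: NormalizedVolume, spec: ThresholdSpec, gf: GradientField | None = None
) -> SelectionMask:
    """Multiple-thresholding: voxels inside the closed value range and,
    when the spec names a gradient type, also inside the closed gradient range.

    A precomputed field for the spec's gradient type may be passed to avoid
    recomputation; otherwise it is computed on the fly.
    """
    mask = (nv.data >= spec.value_lo) & (nv.data <= spec.value_hi)
    if spec.gtype != GradientType.NONE:
        if gf is None:
            gf = gradient_volume(nv, spec.gtype)
        elif gf.gtype != spec.gtype:
            raise InvalidArgumentError(
                f"precomputed field is {gf.gtype}, spec wants {spec.gtype}"
            )
        if gf.dims != nv.dims:
            raise DimensionMismatchError(f"gradient dims {gf.dims} != volume dims {nv.dims}")
        mask &= (gf.data >= spec.grad_lo) & (gf.data <= spec.grad_hi)
    return SelectionMask(mask, nv.voxel_size_um)
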