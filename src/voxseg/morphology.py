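"""Binary 3D morphology on selection masks and tag volumes.

Dilation adds voxels on object boundaries (fills small holes); erosion
removes boundary voxels (removes islands and small objects).  The two
compose in any order — closing (dilate∘erode) and opening (erode∘dilate)
are the usual combinations.  The structuring element is the radius-1
neighbourhood at connectivity 6 (faces), 18 (faces+edges) or 26 (full
box); voxels outside the volume count as unset for both operations, so
there is no wrap-around growth at borders.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError
from .threshold import SelectionMask

__all__ = ["structuring_element", "dilate", "erode", "morph_tags"]

_CONN_RANK = {6: 1, 18: 2, 26: 3}


def structuring_element(connectivity: int) -> np.ndarray:
    """Radius-1 3D structuring element for connectivity 6, 18 or 26."""
    if connectivity not in _CONN_RANK:
        raise InvalidArgumentError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])


def _check_iters(iterations: int) -> None:
    if iterations < 1:
        raise InvalidArgumentError(f"iterations must be ≥ 1, got {iterations}")


def dilate(mask: SelectionMask, connectivity: int = 6, iterations: int = 1) -> SelectionMask:
    """Set every voxel whose radius-1 neighbourhood (or itself) contains a set voxel."""
    _check_iters(iterations)
    se = structuring_element(connectivity)
    out = ndimage.binary_dilation(mask.data, structure=se, iterations=iterations)
    return SelectionMask(out, mask.voxel_size_um)


def erode(mask: SelectionMask, connectivity: int = 6, iterations: int = 1) -> SelectionMask:
    """Keep a voxel only if itself and all its neighbours are set (outside = unset)."""
    _check_iters(iterations)
    se = structuring_element(connectivity)
    out = ndimage.binary_erosion(
        mask.data, structure=se, iterations=iterations, border_value=0
    )
    return SelectionMask(out, mask.voxel_size_um)


def morph_tags(tags, op: str, connectivity: int = 6, iterations: int = 1):
    """Apply dilation or erosion to every tag of a tag volume, one tag at a time.

    Dilation processes tags in ascending order; grown voxels claim only
    still-untagged voxels, so where the growth of two tags would overlap the
    smaller tag id wins (deterministic tie-break).  Erosion shrinks each tag
    independently.  Returns a new tag volume of the same type.
    """
    from .painter import TagVolume  # local import avoids a cycle

    if op not in ("dilate", "erode"):
        raise InvalidArgumentError(f"op must be 'dilate' or 'erode', got {op!r}")
    fn = dilate if op == "dilate" else erode
    data = tags.data
    out = data.copy() if op == "dilate" else np.zeros_like(data)
    for tag in sorted(int(t) for t in np.unique(data) if t != 0):
        m = SelectionMask(data == tag)
        grown = fn(m, connectivity=connectivity, iterations=iterations).data
        if op == "dilate":
            out[grown & (out == 0)] = tag
        else:
            out[grown] = tag
    return TagVolume(out, voxel_size_um=getattr(tags, "voxel_size_um", (1.0, 1.0, 1.0)))
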