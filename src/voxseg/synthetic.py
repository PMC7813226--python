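"""Deterministic synthetic micro-CT phantoms with ground-truth labels.

The generator emulates a mineralized specimen embedded in rock matrix as
seen in a lab micro-CT scan: a low-intensity matrix, a bright curved
shell (dense cortical/dermal bone), and intermediate-intensity internal
structures attached to the shell's inner surface (e.g. ossified
cartilage).  Phases are painted as ideal geometric solids into a
unit-scale field, then degraded by a Gaussian partial-volume blur
followed by additive Gaussian detector noise, clipped to [0, 1] and
quantized to the requested bit depth.  The label volume records the phase
id of every voxel *before* degradation, providing exact ground truth for
evaluating thresholding and segmentation operators.

Everything is driven by a single seeded PRNG stream: identical spec +
seed reproduce the volume bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError
from .painter import TagVolume
from .volume import Volume

__all__ = [
    "Phase",
    "PhantomSpec",
    "generate_phantom",
    "preset_fossil_cheek",
    "preset_fossil_cheek_spec",
]


@dataclass
class Phase:
    """One geometric phase: shape kind, geometry (voxel units), intensity in [0,1].

    Shapes:

    * ``ellipsoid`` — params ``center=(z,y,x)``, ``radii=(rz,ry,rx)``
    * ``spherical_shell`` — params ``center``, ``r_inner``, ``r_outer`` and
      optionally ``axis`` + ``half_angle_deg`` to keep only a spherical cap
      segment (a curved plate)
    * ``box`` — params ``lo=(z,y,x)``, ``hi=(z,y,x)`` (inclusive)
    """

    shape: str
    params: dict
    intensity: float

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "spherical_shell", "box"):
            raise InvalidArgumentError(f"unknown shape {self.shape!r}")
        if not (0.0 <= self.intensity <= 1.0):
            raise InvalidArgumentError("phase intensity must be in [0, 1]")


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom; later phases overwrite earlier."""

    dims: tuple[int, int, int] = (64, 64, 64)
    bit_depth: int = 16
    voxel_size_um: tuple[float, float, float] = (21.0, 21.0, 21.0)
    background_intensity: float = 0.0
    phases: Sequence[Phase] = field(default_factory=list)
    blur_sigma_vox: float = 0.0
    noise_sigma: float = 0.0  # fraction of full scale
    seed: int = 0
    name: str = "phantom"

    def __post_init__(self) -> None:
        if any(d < 8 for d in self.dims):
            raise InvalidArgumentError(f"phantom dims must be ≥ (8,8,8), got {self.dims}")
        if self.blur_sigma_vox < 0 or self.noise_sigma < 0:
            raise InvalidArgumentError("blur and noise sigmas must be ≥ 0")
        if not (0.0 <= self.background_intensity <= 1.0):
            raise InvalidArgumentError("background intensity must be in [0, 1]")


def _coordinate_grids(dims):
    return np.meshgrid(
        np.arange(dims[0], dtype=np.float64),
        np.arange(dims[1], dtype=np.float64),
        np.arange(dims[2], dtype=np.float64),
        indexing="ij",
    )


def _phase_mask(phase: Phase, dims) -> np.ndarray:
    zz, yy, xx = _coordinate_grids(dims)
    p = phase.params
    if phase.shape == "ellipsoid":
        cz, cy, cx = p["center"]
        rz, ry, rx = p["radii"]
        if min(rz, ry, rx) <= 0:
            raise InvalidArgumentError(f"ellipsoid radii must be > 0, got {p['radii']}")
        return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    if phase.shape == "spherical_shell":
        cz, cy, cx = p["center"]
        ri, ro = float(p["r_inner"]), float(p["r_outer"])
        if not (0 < ri < ro):
            raise InvalidArgumentError(
                f"shell radii must satisfy 0 < r_inner < r_outer, got {ri}, {ro}"
            )
        d = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
        mask = (d >= ri) & (d <= ro)
        if "axis" in p:
            az, ay, ax = np.asarray(p["axis"], dtype=np.float64)
            norm = np.sqrt(az * az + ay * ay + ax * ax)
            if norm == 0:
                raise InvalidArgumentError("shell cap axis must be non-zero")
            half = float(p.get("half_angle_deg", 90.0))
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = ((zz - cz) * az + (yy - cy) * ay + (xx - cx) * ax) / (
                    norm * np.maximum(d, 1e-12)
                )
            mask &= cosang >= np.cos(np.deg2rad(half))
        return mask
    # box
    lo, hi = p["lo"], p["hi"]
    if any(h < l for l, h in zip(lo, hi)):
        raise InvalidArgumentError(f"box hi must be ≥ lo, got lo={lo} hi={hi}")
    m = np.ones(dims, dtype=bool)
    for grid, l, h in zip((zz, yy, xx), lo, hi):
        m &= (grid >= l) & (grid <= h)
    return m


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, TagVolume]:
    """Render a phantom spec into a quantized volume plus ground-truth labels.

    Phases paint in listed order (later overwrites earlier); the ground
    truth records the last phase id per voxel (0 = background/matrix);
    the field is then blurred, noised, clipped and quantized.
    """
    field_ = np.full(spec.dims, spec.background_intensity, dtype=np.float64)
    gt = np.zeros(spec.dims, dtype=np.uint8)
    for i, phase in enumerate(spec.phases, start=1):
        mask = _phase_mask(phase, spec.dims)
        field_[mask] = phase.intensity
        gt[mask] = i
    if spec.blur_sigma_vox > 0:
        field_ = ndimage.gaussian_filter(field_, spec.blur_sigma_vox)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        field_ = field_ + rng.normal(0.0, spec.noise_sigma, size=spec.dims)
    field_ = np.clip(field_, 0.0, 1.0)
    max_code = (1 << spec.bit_depth) - 1
    data = np.rint(field_ * max_code).astype(np.uint16 if spec.bit_depth == 16 else np.uint8)
    vol = Volume(
        data,
        voxel_size_um=spec.voxel_size_um,
        bit_depth=spec.bit_depth,
        name=spec.name,
    )
    return vol, TagVolume(gt, spec.voxel_size_um)


def preset_fossil_cheek_spec(
    dims: tuple[int, int, int] = (64, 64, 64), seed: int = 7
) -> PhantomSpec:
    """The :func:`preset_fossil_cheek` geometry as an editable spec."""
    if any(d < 32 for d in dims):
        raise InvalidArgumentError(f"preset needs dims ≥ (32,32,32), got {dims}")
    nz, ny, nx = dims
    # sphere centre beyond the +x face; the shell ∩ volume is a curved plate
    # whose inner surface faces the low-x half of the volume
    center = (nz / 2, ny / 2, nx + 0.75 * nx)
    r_outer = 1.45 * nx
    r_inner = r_outer - 0.34 * min(dims)  # plate thickness ~22 vox at 64³
    # inner surface sits near x ≈ nx + 0.75 nx − r_inner
    x_inner = center[2] - r_inner
    ell_r = (0.11 * nz, 0.11 * ny, 0.13 * nx)
    phases = [
        Phase(
            "ellipsoid",
            {"center": (nz * 0.38, ny * 0.40, x_inner - 0.10 * nx), "radii": ell_r},
            0.55,
        ),
        Phase(
            "ellipsoid",
            {"center": (nz * 0.62, ny * 0.60, x_inner - 0.10 * nx), "radii": ell_r},
            0.55,
        ),
        Phase(
            "spherical_shell",
            {"center": center, "r_inner": r_inner, "r_outer": r_outer},
            0.85,
        ),
    ]
    return PhantomSpec(
        dims=dims,
        bit_depth=16,
        voxel_size_um=(21.0, 21.0, 21.0),
        background_intensity=0.15,
        phases=phases,
        blur_sigma_vox=0.7,
        noise_sigma=0.02,
        seed=seed,
        name="fossil-cheek-phantom",
    )


def preset_fossil_cheek(
    dims: tuple[int, int, int] = (64, 64, 64), seed: int = 7
) -> tuple[Volume, TagVolume]:
    """A specimen-in-matrix phantom: curved bony shell plate with two
    attached internal structures.

    Matrix 0.15, shell 0.85 (a spherical-shell segment whose centre lies
    outside the volume, giving a gently curved plate), two internal
    ellipsoids at 0.55 touching the shell's inner surface; partial-volume
    blur 0.7 voxels, noise 0.02 of full scale, 16-bit, 21 µm voxels.

    Phase ids in the ground truth: 1 and 2 = internal ellipsoids,
    3 = shell (painted last so attachments merge into it seamlessly).
    """
    return generate_phantom(preset_fossil_cheek_spec(dims, seed))
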