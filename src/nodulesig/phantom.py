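"""Synthetic CT nodule phantoms and simulated observer segmentations.

Phantoms emulate the imaging situation the pipeline targets: a lung
adenocarcinoma-like nodule spanning pure ground-glass opacity (GGO) through
fully solid attenuation, optionally abutting a vessel and/or the chest wall,
embedded in aerated lung parenchyma. Simulated observers perturb the true
nodule boundary with a smooth random displacement field, standing in for
manual border adjustment by different software users.

All randomness is seeded: every output is a deterministic function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import BoundsError, EmptyMaskError
from .volume_io import CTVolume, VoxelMask, HU_MIN, HU_MAX, voxel_centers_mm

# Tissue codes for the ground-truth class map.
TISSUE_LUNG = 0
TISSUE_GGO = 1
TISSUE_SOLID = 2
TISSUE_VESSEL = 3
TISSUE_WALL = 4
TISSUE_NAMES = {TISSUE_LUNG: "lung", TISSUE_GGO: "ggo", TISSUE_SOLID: "solid",
                TISSUE_VESSEL: "vessel", TISSUE_WALL: "wall"}

#: Soft-tissue attenuation used for vessels and the chest-wall slab.
VESSEL_HU = 40.0
WALL_HU = 40.0
#: Chest-wall slab thickness, voxels along the column axis.
WALL_THICKNESS_VOX = 4
#: Safety margin required between the nodule and the grid boundary, voxels.
NODULE_MARGIN_VOX = 10

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PhantomSpec:
    """Geometry and attenuation recipe for one synthetic nodule phantom.

    ``solid_core_radius`` controls the solid fraction: the nodule sphere of
    ``nodule_radius`` mm gets ``solid_hu`` inside the core and ``ggo_hu`` in
    the shell, so ``solid_core_radius == nodule_radius`` is a fully solid
    nodule and ``solid_core_radius == 0`` a pure GGO one.
    """

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    nodule_center: tuple[int, int, int]
    nodule_radius: float
    solid_core_radius: float
    solid_hu: float = 40.0
    ggo_hu: float = -550.0
    lung_hu: float = -850.0
    noise_sd: float = 0.0
    vessel_radius: float | None = None
    chest_wall: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.solid_core_radius > self.nodule_radius:
            raise ValueError("solid_core_radius must not exceed nodule_radius")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for hu in (self.solid_hu, self.ggo_hu, self.lung_hu):
            if not (HU_MIN <= hu <= HU_MAX):
                raise ValueError(f"HU value {hu} outside [{HU_MIN}, {HU_MAX}]")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("grid_shape", "spacing", "nodule_center"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for k in ("grid_shape", "spacing", "nodule_center"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """A phantom volume with its true nodule mask and per-voxel tissue map."""

    volume: CTVolume
    nodule_mask: VoxelMask
    class_map: np.ndarray
    spec: PhantomSpec


@dataclass
class ObserverJitter:
    """Stochastic model of one observer's manual boundary edits.

    ``boundary_sd`` is the standard deviation (mm) of a smooth random
    displacement applied to the nodule surface; ``vessel_inclusion_prob`` is
    the probability that an abutting vessel segment is (erroneously) kept in
    the segmentation, emulating an observer who declines to erase it.
    """

    boundary_sd: float = 0.5
    vessel_inclusion_prob: float = 0.0
    rng_seed: int = 0
    #: Correlation length (mm) of the Gaussian-smoothed displacement field.
    field_correlation_mm: float = 3.0
    #: Vessel voxels within this distance (mm) of the nodule count as abutting.
    vessel_attach_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.boundary_sd < 0:
            raise ValueError("boundary_sd must be >= 0")
        if not (0.0 <= self.vessel_inclusion_prob <= 1.0):
            raise ValueError("vessel_inclusion_prob must be in [0, 1]")


def generate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Render one phantom: lung background, optional wall/vessel, the nodule
    sphere (solid core + GGO shell), then additive Gaussian noise.

    Deterministic given ``spec.rng_seed``. Raises :class:`BoundsError` if the
    nodule sphere does not fit inside the grid with a 10-voxel margin.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.spacing)
    center = tuple(int(c) for c in spec.nodule_center)

    for ax in range(3):
        extent_vox = int(np.ceil(spec.nodule_radius / spacing[ax]))
        lo = center[ax] - extent_vox - NODULE_MARGIN_VOX
        hi = center[ax] + extent_vox + NODULE_MARGIN_VOX
        if lo < 0 or hi > shape[ax] - 1:
            raise BoundsError(
                f"nodule (radius {spec.nodule_radius} mm) plus {NODULE_MARGIN_VOX}-voxel "
                f"margin exceeds the grid along axis {ax} (shape {shape})")

    zz, yy, xx = voxel_centers_mm(shape, spacing, (0.0, 0.0, 0.0))
    cz, cy, cx = (center[i] * spacing[i] for i in range(3))
    dist = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
    nodule = dist <= spec.nodule_radius
    core = dist <= spec.solid_core_radius

    values = np.full(shape, spec.lung_hu, dtype=np.float64)
    class_map = np.full(shape, TISSUE_LUNG, dtype=np.uint8)

    if spec.chest_wall:
        wall = np.zeros(shape, dtype=bool)
        wall[:, :, shape[2] - WALL_THICKNESS_VOX:] = True
        values[wall] = WALL_HU
        class_map[wall] = TISSUE_WALL

    if spec.vessel_radius is not None and spec.vessel_radius > 0:
        # Cylinder along the row (y) axis, tangent to the nodule surface so
        # that it abuts (and marginally interpenetrates) the sphere.
        axis_x = cx + spec.nodule_radius + 0.5 * spec.vessel_radius
        rad2 = (zz - cz) ** 2 + (xx - axis_x) ** 2
        vessel = rad2 <= spec.vessel_radius ** 2
        vessel &= ~nodule
        values[vessel] = VESSEL_HU
        class_map[vessel] = TISSUE_VESSEL

    values[nodule] = spec.ggo_hu
    class_map[nodule] = TISSUE_GGO
    values[core & nodule] = spec.solid_hu
    class_map[core & nodule] = TISSUE_SOLID

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)
        np.clip(values, HU_MIN, HU_MAX, out=values)

    volume = CTVolume(values=values, spacing=spacing)
    mask = VoxelMask(values=nodule.astype(np.uint8), spacing=spacing)
    return GroundTruth(volume=volume, nodule_mask=mask, class_map=class_map, spec=spec)


def default_spec_sampler(rng: np.random.Generator) -> PhantomSpec:
    """Sample a phantom spec spanning pure-GGO through fully solid nodules.

    Defaults emulate low-dose screening CT of sub-3-cm adenocarcinomas:
    anisotropic voxels (1.25 mm slices, 0.7 mm in-plane), nodule radius
    4-8 mm, solid fraction uniform on [0, 1], ~30 HU image noise, vessels
    abutting half the nodules and chest wall in a third of cases.
    """
    radius = float(rng.uniform(4.0, 8.0))
    solid_frac = float(rng.uniform(0.0, 1.0))
    vessel = float(rng.uniform(1.0, 2.0)) if rng.random() < 0.5 else None
    return PhantomSpec(
        grid_shape=(40, 56, 56),
        spacing=(1.25, 0.7, 0.7),
        nodule_center=(20, 28, 28),
        nodule_radius=radius,
        solid_core_radius=solid_frac * radius,
        noise_sd=30.0,
        vessel_radius=vessel,
        chest_wall=bool(rng.random() < 0.3),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n: int,
    spec_sampler: Callable[[np.random.Generator], PhantomSpec] | None = None,
    seed: int = 0,
) -> tuple[list[GroundTruth], pd.DataFrame]:
    """Generate ``n`` independent phantoms plus a manifest of their specs.

    The manifest (one row per phantom, columns = spec fields) is what the
    ``simulate`` CLI writes as CSV.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    sampler = spec_sampler or default_spec_sampler
    rng = np.random.default_rng(seed)
    cohort, rows = [], []
    for i in range(n):
        spec = sampler(rng)
        cohort.append(generate_phantom(spec))
        row = {"phantom_id": i, **spec.to_dict()}
        rows.append(row)
    manifest = pd.DataFrame(rows)
    return cohort, manifest


def _signed_distance_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance to the mask surface: negative inside."""
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    return d_out - d_in


def simulate_observer_mask(truth: GroundTruth, jitter: ObserverJitter) -> VoxelMask:
    """Perturb the true nodule mask the way a human observer's manual border
    would differ from it.

    The true surface (zero level of the signed distance) is displaced by a
    Gaussian-smoothed random field scaled to standard deviation
    ``boundary_sd`` mm; the largest 26-connected component overlapping the
    truth is kept. With probability ``vessel_inclusion_prob`` the abutting
    vessel segment is unioned in. Deterministic given ``jitter.rng_seed``;
    ``boundary_sd == 0`` with no vessel inclusion reproduces the truth
    exactly.
    """
    mask = truth.nodule_mask.values.astype(bool)
    if not mask.any():
        raise EmptyMaskError("ground-truth nodule mask is empty")
    spacing = truth.nodule_mask.spacing
    rng = np.random.default_rng(jitter.rng_seed)

    if jitter.boundary_sd > 0:
        sdist = _signed_distance_mm(mask, spacing)
        sigma_vox = [jitter.field_correlation_mm / s for s in spacing]
        raw = rng.standard_normal(mask.shape)
        fld = ndimage.gaussian_filter(raw, sigma=sigma_vox)
        sd = fld.std()
        fld = fld * (jitter.boundary_sd / sd) if sd > 0 else np.zeros_like(fld)
        new = sdist < fld
        # keep the component that best overlaps the true nodule
        labels, nlab = ndimage.label(new, structure=_CONN26)
        if nlab == 0:
            raise EmptyMaskError("boundary perturbation emptied the mask")
        overlaps = ndimage.sum_labels(mask, labels, index=np.arange(1, nlab + 1))
        if overlaps.max() > 0:
            keep = int(np.argmax(overlaps)) + 1
        else:  # no component touches the truth: keep the largest
            sizes = ndimage.sum_labels(np.ones_like(mask), labels,
                                       index=np.arange(1, nlab + 1))
            keep = int(np.argmax(sizes)) + 1
        new = labels == keep
    else:
        new = mask.copy()
        rng.standard_normal(mask.shape)  # keep the draw sequence aligned

    if jitter.vessel_inclusion_prob > 0:
        vessel = truth.class_map == TISSUE_VESSEL
        if vessel.any() and rng.random() < jitter.vessel_inclusion_prob:
            d_to_nodule = ndimage.distance_transform_edt(~mask, sampling=spacing)
            abutting = vessel & (d_to_nodule <= jitter.vessel_attach_mm)
            new |= abutting

    if not new.any():
        raise EmptyMaskError("observer perturbation produced an empty mask")
    return VoxelMask(values=new.astype(np.uint8), spacing=spacing,
                     origin=truth.nodule_mask.origin)
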