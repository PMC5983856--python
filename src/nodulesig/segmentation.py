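"""Semi-automatic nodule segmentation: seeded region growing + scripted edits.

The observer places a seed inside the nodule; a volume of interest (VOI) box
is opened around it and the maximal connected component of voxels within a
dual HU threshold containing the seed becomes the initial border. Manual
border adjustment is modeled by two primitives — a spherical eraser and a
half-space exclusion plane — applied in order. A session records seed,
parameters, edits and result so any segmentation can be replayed and audited
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import (BoundsError, EmptyMaskError, ReproducibilityError,
                     SeedRejectedError)
from .volume_io import CTVolume, VoxelMask, check_aligned, voxel_centers_mm


@dataclass(frozen=True)
class SeedPoint:
    """A voxel index triple (slice, row, col) inside the grid."""

    voxel: tuple[int, int, int]


@dataclass
class SegmentationParams:
    """Region-growing controls.

    The default thresholds bracket the ground-glass-to-solid attenuation
    range (-750 to 200 HU) so that both sub-solid and solid nodule tissue is
    captured while aerated lung is excluded. The VOI is an axis-aligned box
    of half-width ``voi_half_extent`` mm around the seed, clipped at the grid
    boundary.
    """

    hu_low: float = -750.0
    hu_high: float = 200.0
    connectivity: Literal[6, 26] = 26
    voi_half_extent: float = 20.0

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError("hu_low must be < hu_high")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.voi_half_extent <= 0:
            raise ValueError("voi_half_extent must be > 0")


@dataclass
class EditOp:
    """One manual border adjustment.

    ``eraser_sphere`` removes voxels whose centers lie within ``radius`` mm
    of ``point`` (closed ball); ``exclusion_plane`` removes voxels strictly
    on the ``normal`` side of the plane through ``point``. Coordinates are
    world-space mm.
    """

    kind: Literal["eraser_sphere", "exclusion_plane"]
    point: tuple[float, float, float]
    radius: float | None = None
    normal: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == "eraser_sphere":
            if self.radius is None or self.radius < 0:
                raise ValueError("eraser_sphere needs radius >= 0")
        elif self.kind == "exclusion_plane":
            if self.normal is None or not np.linalg.norm(self.normal) > 0:
                raise ValueError("exclusion_plane needs a nonzero normal")
        else:
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass
class SegmentationSession:
    """Audit record: replaying (seed, params, edits) reproduces ``result``."""

    seed: SeedPoint
    params: SegmentationParams
    edits: list[EditOp]
    result: VoxelMask


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def region_grow(volume: CTVolume, seed: SeedPoint,
                params: SegmentationParams | None = None) -> VoxelMask:
    """Grow the nodule border from a seed voxel.

    Returns the maximal connected component (6- or 26-connectivity) of
    voxels with HU in ``[hu_low, hu_high]`` that contains the seed, clipped
    to the VOI box. Deterministic.
    """
    params = params or SegmentationParams()
    z, y, x = (int(c) for c in seed.voxel)
    shape = volume.shape
    if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
        raise BoundsError(f"seed {seed.voxel} outside grid {shape}")
    hu = float(volume.values[z, y, x])
    if not (params.hu_low <= hu <= params.hu_high):
        raise SeedRejectedError(
            f"seed HU {hu:.1f} outside [{params.hu_low}, {params.hu_high}]")

    half_vox = [int(np.floor(params.voi_half_extent / s)) for s in volume.spacing]
    lo = [max(0, c - h) for c, h in zip((z, y, x), half_vox)]
    hi = [min(shape[i], (z, y, x)[i] + half_vox[i] + 1) for i in range(3)]
    box = tuple(slice(lo[i], hi[i]) for i in range(3))

    sub = volume.values[box]
    in_range = (sub >= params.hu_low) & (sub <= params.hu_high)
    labels, _ = ndimage.label(in_range, structure=_structure(params.connectivity))
    seed_sub = (z - lo[0], y - lo[1], x - lo[2])
    lab = labels[seed_sub]
    grown = np.zeros(shape, dtype=np.uint8)
    grown[box] = (labels == lab).astype(np.uint8)
    return VoxelMask(values=grown, spacing=volume.spacing, origin=volume.origin)


def apply_edits(mask: VoxelMask, edits: Sequence[EditOp]) -> VoxelMask:
    """Apply manual edits in order; output is always a subset of the input.

    Raises :class:`EmptyMaskError` if any edit empties the mask — the
    observer would have to re-seed.
    """
    out = mask.values.astype(bool).copy()
    if not edits:
        return VoxelMask(values=out.astype(np.uint8), spacing=mask.spacing,
                         origin=mask.origin)
    zz, yy, xx = voxel_centers_mm(mask.shape, mask.spacing, mask.origin)
    for i, op in enumerate(edits):
        pz, py, px = (float(c) for c in op.point)
        if op.kind == "eraser_sphere":
            d2 = (zz - pz) ** 2 + (yy - py) ** 2 + (xx - px) ** 2
            out &= ~(d2 <= float(op.radius) ** 2)
        else:
            n = np.asarray(op.normal, dtype=float)
            side = (zz - pz) * n[0] + (yy - py) * n[1] + (xx - px) * n[2]
            out &= ~(side > 0)
        if not out.any():
            raise EmptyMaskError(f"edit {i} ({op.kind}) emptied the mask")
    return VoxelMask(values=out.astype(np.uint8), spacing=mask.spacing,
                     origin=mask.origin)


def run_session(volume: CTVolume, seed: SeedPoint,
                params: SegmentationParams | None = None,
                edits: Sequence[EditOp] = ()) -> SegmentationSession:
    """Segment and record the full session (seed, params, edits, result)."""
    params = params or SegmentationParams()
    mask = apply_edits(region_grow(volume, seed, params), list(edits))
    return SegmentationSession(seed=seed, params=params, edits=list(edits),
                               result=mask)


def replay_session(volume: CTVolume, session: SegmentationSession) -> VoxelMask:
    """Re-run a stored session and verify it reproduces the stored result
    voxel-for-voxel; raises :class:`ReproducibilityError` on any mismatch."""
    mask = apply_edits(region_grow(volume, session.seed, session.params),
                       session.edits)
    check_aligned(session.result, mask)
    if not np.array_equal(mask.values, session.result.values):
        ndiff = int(np.sum(mask.values != session.result.values))
        raise ReproducibilityError(
            f"replay differs from stored result at {ndiff} voxels")
    return mask


# --- JSON session (de)serialization -----------------------------------------

def session_to_dict(session: SegmentationSession) -> dict:
    return {
        "seed": list(session.seed.voxel),
        "params": asdict(session.params),
        "edits": [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(e).items() if v is not None}
            for e in session.edits
        ],
        "result_voxels": [list(map(int, v)) for v in np.argwhere(session.result.values)],
        "grid_shape": list(session.result.shape),
        "spacing": list(session.result.spacing),
        "origin": list(session.result.origin),
    }


def session_from_dict(d: dict) -> SegmentationSession:
    result = np.zeros(tuple(d["grid_shape"]), dtype=np.uint8)
    idx = np.asarray(d["result_voxels"], dtype=int)
    if idx.size:
        result[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    edits = []
    for e in d["edits"]:
        e = dict(e)
        e["point"] = tuple(e["point"])
        if "normal" in e:
            e["normal"] = tuple(e["normal"])
        edits.append(EditOp(**e))
    return SegmentationSession(
        seed=SeedPoint(tuple(d["seed"])),
        params=SegmentationParams(**d["params"]),
        edits=edits,
        result=VoxelMask(values=result, spacing=tuple(d["spacing"]),
                         origin=tuple(d["origin"])),
    )


def save_session(session: SegmentationSession, path: str | Path) -> None:
    Path(path).write_text(json.dumps(session_to_dict(session)))


def load_session(path: str | Path) -> SegmentationSession:
    return session_from_dict(json.loads(Path(path).read_text()))
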