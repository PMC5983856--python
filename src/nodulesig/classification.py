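"""Voxel classification, parametric signatures and the G/I/P risk call.

Every voxel of a segmented nodule is assessed together with its 80
surrounding in-plane voxels (a 9x9 window) and assigned the class of the
nearest exemplar in feature space. The relative representation of the nine
classes over all classified voxels is the nodule's parametric signature; the
summed fraction of the invasion-associated VIRO classes drives the overall
risk characterization: Good, Intermediate or Poor.

Mask voxels whose window would extend past the grid are left unclassified
rather than padded (padding would fabricate attenuation); fractions are
computed over classified voxels only, with the unclassified count reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import EmptyMaskError
from .exemplar_model import (ExemplarModel, FeatureConfig, HALF_WINDOW,
                             INTERMEDIATE_CLASSES, LEPIDIC_CLASSES, PALETTE,
                             VIRO_CLASSES, VOIPatch, WINDOW, _features_batch,
                             standardize)
from .volume_io import CTVolume, VoxelMask, check_aligned

#: ClassMap voxel codes: 0 background, 1..9 palette classes, 10 unclassified.
CLASSMAP_BACKGROUND = 0
CLASSMAP_UNCLASSIFIED = 10
CLASSMAP_LEGEND: dict[int, str] = {
    0: "background", **{i + 1: c for i, c in enumerate(PALETTE)}, 10: "unclassified"}


@dataclass
class ClassMap:
    """Per-voxel class labels over a nodule mask (uint8 coded, see legend)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: Mapping[int, str] = field(default_factory=lambda: dict(CLASSMAP_LEGEND))


@dataclass
class ParametricSignature:
    """Per-class composition of one segmented nodule."""

    counts: dict[str, int]
    total_classified: int
    n_unclassified: int

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total_classified
        return {c: self.counts.get(c, 0) / t for c in PALETTE}

    @property
    def viro_fraction(self) -> float:
        return sum(self.fractions[c] for c in VIRO_CLASSES)

    @property
    def lepidic_fraction(self) -> float:
        return sum(self.fractions[c] for c in LEPIDIC_CLASSES)

    @property
    def intermediate_fraction(self) -> float:
        return sum(self.fractions[c] for c in INTERMEDIATE_CLASSES)


@dataclass
class RiskRule:
    """Thresholds on the VIRO fraction for the Good/Intermediate/Poor call.

    Boundary values go to the more severe category: Poor iff
    viro >= ``t_poor``; Good iff viro < ``t_good``; Intermediate otherwise.
    The numeric defaults are this package's explicit, configurable
    assumption; every :class:`RiskCall` records the rule it used.
    """

    t_good: float = 0.10
    t_poor: float = 0.45

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_good < self.t_poor <= 1.0):
            raise ValueError(
                f"need 0 <= t_good < t_poor <= 1, got ({self.t_good}, {self.t_poor})")


@dataclass
class RiskCall:
    """A Good/Intermediate/Poor characterization plus its audit trace."""

    category: str  # "Good" | "Intermediate" | "Poor"
    viro_fraction: float
    rule: RiskRule


def classify_voxel(patch: VOIPatch | np.ndarray, model: ExemplarModel) -> str:
    """Class label of the exemplar nearest (in standardized feature space) to
    the patch; exact ties go to the lowest-index exemplar."""
    values = patch.values if isinstance(patch, VOIPatch) else np.asarray(patch)
    f = _features_batch(values.reshape(1, -1), model.config)
    z, _, _ = standardize(f, model.feat_mean, model.feat_sd)
    d2 = ((model.features_std - z) ** 2).sum(axis=1)
    return model.labels[int(np.argmin(d2))]


def classify_nodule(volume: CTVolume, mask: VoxelMask,
                    model: ExemplarModel) -> tuple[ClassMap, ParametricSignature]:
    """Classify every mask voxel with full 9x9 in-plane support and tally
    the parametric signature. Deterministic."""
    check_aligned(volume, mask)
    m = mask.values.astype(bool)
    if not m.any():
        raise EmptyMaskError("cannot classify an empty mask")

    _, nrow, ncol = m.shape
    zs, ys, xs = np.nonzero(m)
    supported = ((ys >= HALF_WINDOW) & (ys < nrow - HALF_WINDOW)
                 & (xs >= HALF_WINDOW) & (xs < ncol - HALF_WINDOW))
    n_unsupported = int((~supported).sum())
    zs, ys, xs = zs[supported], ys[supported], xs[supported]
    if zs.size == 0:
        raise EmptyMaskError("no mask voxel has full 9x9 in-plane support")

    flat = np.empty((zs.size, WINDOW * WINDOW), dtype=float)
    for z in np.unique(zs):
        sel = zs == z
        windows = sliding_window_view(volume.values[z], (WINDOW, WINDOW))
        flat[sel] = windows[ys[sel] - HALF_WINDOW,
                            xs[sel] - HALF_WINDOW].reshape(int(sel.sum()), -1)

    feats = _features_batch(flat, model.config)
    z_feats, _, _ = standardize(feats, model.feat_mean, model.feat_sd)
    ex = model.features_std
    # squared distances to each exemplar; argmin ties go to lowest index
    d2 = ((z_feats[:, None, :] - ex[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)

    label_codes = np.array([PALETTE.index(lab) + 1 for lab in model.labels])
    cm = np.zeros(m.shape, dtype=np.uint8)
    cm[m] = CLASSMAP_UNCLASSIFIED
    cm[zs, ys, xs] = label_codes[nearest]

    counts = {c: 0 for c in PALETTE}
    codes, tallies = np.unique(label_codes[nearest], return_counts=True)
    for code, tally in zip(codes, tallies):
        counts[PALETTE[int(code) - 1]] = int(tally)
    sig = ParametricSignature(counts=counts, total_classified=int(zs.size),
                              n_unclassified=n_unsupported)
    cmap = ClassMap(values=cm, spacing=mask.spacing, origin=mask.origin)
    return cmap, sig


def viro_fraction(signature: ParametricSignature) -> float:
    """Summed fraction of the V, I, R, O (most invasive) classes."""
    return signature.viro_fraction


def risk_characterize(signature: ParametricSignature,
                      rule: RiskRule | None = None) -> RiskCall:
    """Good/Intermediate/Poor call from the VIRO burden, severe-side ties."""
    rule = rule or RiskRule()
    v = signature.viro_fraction
    if v >= rule.t_poor:
        category = "Poor"
    elif v < rule.t_good:
        category = "Good"
    else:
        category = "Intermediate"
    return RiskCall(category=category, viro_fraction=v, rule=rule)


def signature_row(nodule_id, observer_id, signature: ParametricSignature,
                  call: RiskCall | None = None) -> dict:
    """One CSV-ready record: nodule, observer, 9 class fractions, VIRO,
    risk category."""
    row = {"nodule": nodule_id, "observer": observer_id}
    row.update({c: signature.fractions[c] for c in PALETTE})
    row["viro"] = signature.viro_fraction
    row["total_classified"] = signature.total_classified
    row["n_unclassified"] = signature.n_unclassified
    if call is not None:
        row["risk"] = call.category
    return row
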