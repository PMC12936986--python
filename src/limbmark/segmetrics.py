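"""Voxel segmentation overlap and surface-distance metrics: DSC, HD, HD95.

Distances are computed between the boundary-voxel centre point sets of the
two masks in world millimetres (anisotropic spacing honoured). HD95 uses
the nearest-rank 95th percentile of each directed distance set,
symmetrised by the maximum of the two directions — conventions vary in the
literature; this one is fixed here.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GridMismatchError, UndefinedMetricError
from .meshdata import LabelVolume


def _as_mask(vol) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(vol, LabelVolume):
        return vol.data.astype(bool), vol
    return np.asarray(vol).astype(bool), None


def _check_grids(a, b):
    ma, va = _as_mask(a)
    mb, vb = _as_mask(b)
    if ma.shape != mb.shape:
        raise GridMismatchError("masks differ in shape")
    if va is not None and vb is not None and not va.same_grid(vb):
        raise GridMismatchError("masks differ in affine")
    return ma, mb, va or vb


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); two empty masks → 1.0."""
    ma, mb, _ = _check_grids(a, b)
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices of mask voxels with at least one 6-connected background neighbour."""
    mask = np.asarray(mask).astype(bool)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff(a, b, percentile: int = 100) -> float:
    """(Percentile) Hausdorff distance in mm between two masks' boundaries.

    percentile=100 → max of the two directed maxima; percentile=95 → max of
    the two directed nearest-rank 95th percentiles.
    """
    if percentile not in (95, 100):
        raise ValueError("percentile must be 95 or 100")
    ma, mb, vol = _check_grids(a, b)
    if ma.sum() == 0 or mb.sum() == 0:
        raise UndefinedMetricError("Hausdorff distance undefined for an empty mask")
    pa = boundary_voxels(ma).astype(float)
    pb = boundary_voxels(mb).astype(float)
    if vol is not None:
        pa = vol.world_coords(pa)
        pb = vol.world_coords(pb)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile == 100:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(_nearest_rank(d_ab, 95), _nearest_rank(d_ba, 95)))


def _nearest_rank(values: np.ndarray, pct: float) -> float:
    v = np.sort(np.asarray(values))
    rank = int(np.ceil(pct / 100.0 * len(v))) - 1
    return float(v[max(rank, 0)])


def evaluate_masks(auto: LabelVolume, reference: LabelVolume, labels=None):
    """Per-label DSC/HD/HD95 rows (dicts), shaped like a per-bone metrics table."""
    if labels is None:
        labels = sorted(set(np.unique(reference.data)) - {0})
    rows = []
    for lab in labels:
        am = LabelVolume(auto.data == lab, auto.affine)
        rm = LabelVolume(reference.data == lab, reference.affine)
        name = reference.label_table.get(lab)
        rows.append(
            {
                "label": int(lab),
                "bone": name.value if name else str(lab),
                "DSC": dice(am, rm),
                "HD_mm": hausdorff(am, rm, 100),
                "HD95_mm": hausdorff(am, rm, 95),
            }
        )
    return rows
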