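"""WMH core and distance-banded NAWM rim ROI geometry.

The lesion mask (2 mm isotropic) is repeatedly dilated by one voxel with a
face-connectivity (6-neighbor) structuring element; each new shell, minus
everything already labeled, intersected with the white-matter mask, becomes
one rim ROI. Eight rims of one 2 mm voxel each cover a 16 mm band around the
lesions. Face connectivity makes each shell exactly one city-block step, so
shell k equals the set of voxels at city-block grid distance k from the core
(26-connectivity would make shell thickness anisotropic: a diagonal step is
3.46 mm). Growth proceeds through non-WM voxels; the WM filter is applied
per shell, so the union of rims equals (n-step dilation of the core) ∩ WM
minus the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .regions import N_RIMS, label_to_region

__all__ = [
    "RimAtlas",
    "resample_binarize",
    "filter_min_volume",
    "min_volume_ml",
    "build_rims",
    "wmh_load",
    "log_wmh_load",
    "classify_pv_deep",
]


@dataclass
class RimAtlas:
    """Labeled WMH core + rim ROIs on the acquisition grid.

    ``labels``: 0 background, 1 WMH core, 2..(n_rims+1) rims at nominal
    distances 2, 4, ..., 2*n_rims mm. ``counts`` records voxels per label
    (provenance; empty rims are permitted and show up as zero).
    """

    labels: np.ndarray
    voxel_mm: float = 2.0
    n_rims: int = N_RIMS
    counts: dict[int, int] = field(default_factory=dict)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def region_name(self, label: int) -> str:
        return label_to_region(label)

    @property
    def band_width_mm(self) -> float:
        return self.n_rims * self.voxel_mm


def resample_binarize(
    mask_hi: np.ndarray, factor: int = 2, threshold: float = 0.5
) -> np.ndarray:
    """Downsample a high-resolution binary mask by block averaging.

    An output voxel is set iff the mean of its ``factor**3`` children is at
    least ``threshold`` (default 0.5, i.e. majority). Grids not divisible by
    ``factor`` are zero-padded at the high end first.
    """
    m = np.asarray(mask_hi).astype(float)
    if m.ndim != 3:
        raise ValueError("mask must be 3-D")
    pad = [(0, (-s) % factor) for s in m.shape]
    if any(p[1] for p in pad):
        m = np.pad(m, pad)
    s = tuple(dim // factor for dim in m.shape)
    blocks = m.reshape(s[0], factor, s[1], factor, s[2], factor)
    means = blocks.mean(axis=(1, 3, 5))
    return means >= threshold


def min_volume_ml(min_voxels: int = 4, voxel_mm: float = 2.0) -> float:
    """Volume (ml) of the minimum-size threshold: n voxels at voxel_mm iso."""
    return min_voxels * voxel_mm**3 / 1000.0


def filter_min_volume(
    wmh: np.ndarray, min_voxels: int = 4, per_lesion: bool = False
) -> tuple[np.ndarray, bool]:
    """Apply the minimum WMH size rule (default 4 voxels = 0.032 ml at 2 mm).

    The default is a subject-level rule: if the total lesion voxel count is
    below ``min_voxels`` the subject is flagged excluded and the mask is
    returned unchanged. With ``per_lesion=True`` connected components below
    the threshold are removed instead, and the subject is excluded only if
    nothing survives.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    wmh = np.asarray(wmh, dtype=bool)
    if per_lesion:
        struct = ndimage.generate_binary_structure(3, 3)
        lab, n = ndimage.label(wmh, structure=struct)
        sizes = np.bincount(lab.ravel())
        keep = np.zeros_like(sizes, dtype=bool)
        keep[1:] = sizes[1:] >= min_voxels
        out = keep[lab]
        return out, not out.any()
    return wmh, int(wmh.sum()) < min_voxels


def build_rims(wmh: np.ndarray, wm: np.ndarray, n_rims: int = N_RIMS) -> RimAtlas:
    """Build the WMH core plus ``n_rims`` disjoint one-voxel rim ROIs.

    Each rim is the next face-connectivity dilation shell of the core,
    excluding previously labeled voxels, intersected with the WM mask.
    """
    wmh = np.asarray(wmh, dtype=bool)
    wm = np.asarray(wm, dtype=bool)
    if wmh.shape != wm.shape:
        raise ValueError("wmh and wm masks must share a grid")
    if not wmh.any():
        raise ValueError("WMH mask is empty: nothing to dilate")
    struct = ndimage.generate_binary_structure(3, 1)  # faces only
    labels = np.zeros(wmh.shape, dtype=np.int16)
    labels[wmh] = 1
    grown = wmh
    counts = {1: int(wmh.sum())}
    for k in range(1, n_rims + 1):
        nxt = ndimage.binary_dilation(grown, structure=struct)
        shell = nxt & ~grown
        rim = shell & wm
        labels[rim] = k + 1
        counts[k + 1] = int(rim.sum())
        grown = nxt
    return RimAtlas(labels=labels, n_rims=n_rims, counts=counts)


def wmh_load(wmh_volume_ml: float, brain_volume_ml: float) -> float:
    """WMH load: lesion volume as a percentage of brain volume."""
    if brain_volume_ml <= 0:
        raise ValueError("brain volume must be positive")
    return 100.0 * wmh_volume_ml / brain_volume_ml


def log_wmh_load(load_pct: float) -> float:
    """Natural log of the WMH load (%); zero-lesion subjects are excluded
    upstream, so a non-positive load is an error here."""
    if load_pct <= 0:
        raise ValueError("WMH load must be positive for the log transform")
    return float(np.log(load_pct))


def classify_pv_deep(
    wmh: np.ndarray,
    ventricles: np.ndarray | None,
    rule_mm: float = 10.0,
    voxel_mm: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split WMH into periventricular and deep components.

    A connected lesion component (26-connectivity) is periventricular iff its
    minimum Euclidean distance to the ventricle mask is <= ``rule_mm``
    (default 10 mm). Returns (pv_mask, deep_mask), a disjoint, exhaustive
    partition of the lesion mask.
    """
    if ventricles is None:
        raise ValueError("a ventricle mask is required for the PV/deep split")
    wmh = np.asarray(wmh, dtype=bool)
    vent = np.asarray(ventricles, dtype=bool)
    if wmh.shape != vent.shape:
        raise ValueError("masks must share a grid")
    if not vent.any():
        raise ValueError("ventricle mask is empty")
    dist = ndimage.distance_transform_edt(~vent, sampling=voxel_mm)
    struct = ndimage.generate_binary_structure(3, 3)
    lab, n = ndimage.label(wmh, structure=struct)
    pv = np.zeros_like(wmh)
    for comp in range(1, n + 1):
        m = lab == comp
        if dist[m].min() <= rule_mm:
            pv |= m
    deep = wmh & ~pv
    return pv, deep
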