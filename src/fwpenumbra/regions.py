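"""Shared region vocabulary: WMH core plus 8 concentric NAWM rims.

Labels in the rim atlas are 0 (background), 1 (WMH core) and 2..9 for the
rims at nominal outer distances 2, 4, ..., 16 mm (one 2 mm voxel shell each).
"""

from __future__ import annotations

N_RIMS = 8

#: Ordered region names, innermost first.
REGION_NAMES: tuple[str, ...] = ("WMH",) + tuple(f"{2 * k}mm" for k in range(1, N_RIMS + 1))


def region_mm(name: str) -> int:
    """Nominal outer distance of a region in mm (0 for the WMH core)."""
    if name == "WMH":
        return 0
    if name.endswith("mm"):
        return int(name[:-2])
    raise ValueError(f"unknown region name: {name!r}")


def label_to_region(label: int) -> str:
    """Map an atlas label (1..9) to its region name."""
    if label == 1:
        return "WMH"
    if 2 <= label <= N_RIMS + 1:
        return f"{2 * (label - 1)}mm"
    raise ValueError(f"label {label} is not a region label")


def contrast_names(levels: tuple[str, ...] = REGION_NAMES) -> list[str]:
    """Adjacency contrast names, e.g. 'WMH - 2mm', '2mm - 4mm', ..."""
    return [f"{a} - {b}" for a, b in zip(levels[:-1], levels[1:])]
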