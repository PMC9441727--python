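"""Per-ROI statistics: map means over the rim atlas, long-table assembly,
and the large-sample normality screen."""

from __future__ import annotations

import logging
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .regions import REGION_NAMES, region_mm
from .roigeom import RimAtlas

__all__ = [
    "extract_roi_means",
    "subject_long_rows",
    "assemble_long_table",
    "normality_check",
    "summarize_exclusions",
    "NormalityResult",
]

logger = logging.getLogger(__name__)


def extract_roi_means(
    scalar_map: np.ndarray, atlas: RimAtlas, strict_mask: np.ndarray | None = None
) -> pd.Series:
    """Arithmetic mean of a scalar map over every non-empty atlas label.

    Empty labels are dropped (with a logged warning) rather than reported as
    zero — a zero would masquerade as data in the mixed models. With
    ``strict_mask`` given, only voxels inside it contribute (e.g. to exclude
    non-converged fits).
    """
    scalar_map = np.asarray(scalar_map, dtype=float)
    if scalar_map.shape != atlas.labels.shape:
        raise ValueError("map and atlas grids differ")
    out: dict[str, float] = {}
    for label in range(1, atlas.n_rims + 2):
        m = atlas.labels == label
        if strict_mask is not None:
            m &= strict_mask
        name = atlas.region_name(label)
        if not m.any():
            logger.warning("ROI %s is empty; row dropped", name)
            continue
        out[name] = float(scalar_map[m].mean())
    return pd.Series(out, name="mean")


def subject_long_rows(
    subject: object,
    fw_map: np.ndarray,
    fat_map: np.ndarray,
    atlas: RimAtlas,
    covariates: Mapping[str, object],
    strict_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """One subject's (ROI x outcome) rows with covariates attached."""
    fw = extract_roi_means(fw_map, atlas, strict_mask)
    fat = extract_roi_means(fat_map, atlas, strict_mask)
    names = [n for n in REGION_NAMES if n in fw.index and n in fat.index]
    df = pd.DataFrame(
        {
            "subject": subject,
            "roi": names,
            "roi_mm": [region_mm(n) for n in names],
            "fw": fw.loc[names].to_numpy(),
            "fa_t": fat.loc[names].to_numpy(),
        }
    )
    for key, val in covariates.items():
        df[key] = val
    return df


def assemble_long_table(per_subject: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate subject rows into the cohort long table.

    Enforces the table contract: no duplicated (subject, roi) pairs and at
    most one row per subject and region.
    """
    table = pd.concat(per_subject, ignore_index=True)
    if table.duplicated(subset=["subject", "roi"]).any():
        raise ValueError("duplicated (subject, roi) rows in long table")
    table["roi"] = pd.Categorical(table["roi"], categories=REGION_NAMES, ordered=True)
    return table


class NormalityResult(NamedTuple):
    skewness: float
    kurtosis: float  # excess (Fisher) kurtosis
    passed: bool


def normality_check(
    values: np.ndarray, skew_threshold: float = 2.0, kurt_threshold: float = 7.0
) -> NormalityResult:
    """Large-sample normality screen via sample skewness and excess kurtosis.

    Uses the conventional large-dataset rule of thumb: |skewness| < 2 and
    |excess kurtosis| < 7. A constant vector has undefined moments and is an
    error.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(v) == 0:
        raise ValueError("constant vector: moments undefined")
    skew = float(stats.skew(v))
    kurt = float(stats.kurtosis(v))  # Fisher: normal -> 0
    return NormalityResult(skew, kurt, abs(skew) < skew_threshold and abs(kurt) < kurt_threshold)


def summarize_exclusions(n_initial: int, exclusions: Mapping[str, int]) -> dict:
    """Cohort accounting: initial N minus per-reason exclusion counts.

    Returns the flow as a dict with the final analyzable sample size.
    """
    n_excluded = int(sum(exclusions.values()))
    n_final = int(n_initial) - n_excluded
    if n_final < 0:
        raise ValueError("exclusions exceed the initial sample")
    return {
        "n_initial": int(n_initial),
        "exclusions": dict(exclusions),
        "n_excluded": n_excluded,
        "n_final": n_final,
    }
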