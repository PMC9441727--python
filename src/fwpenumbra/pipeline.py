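"""End-to-end orchestration: simulate → fit → rois → extract → analyze.

Configured by a TOML file (see ``PipelineConfig.from_toml``). Two data paths
exist and can be combined:

* an imaging path — a phantom (or pre-registered real volumes) is fitted
  with the free-water model, rim ROIs are built, and per-ROI means are
  extracted;
* a cohort path — the image-free generator produces the subject × ROI long
  table directly, which feeds the mixed models, penumbra rule, and risk
  regressions.

Inputs are assumed pre-aligned on the 2 mm DWI grid: this package performs
NO registration. Every stage directory receives a provenance JSON with
versions, seeds, and the config hash.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .fwfit import FitConfig, fit_freewater
from .penumbra import detect_penumbra, fit_risk_models, fit_roi_lmm, penumbra_mean
from .roigeom import build_rims, filter_min_volume
from .roistats import extract_roi_means
from .synthcohort import (
    CohortSpec,
    Ellipsoid,
    make_gradient_scheme,
    make_phantom,
    simulate_cohort_rois,
    simulate_dwi,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_phantom_stage", "analyze_cohort_table"]


@dataclass
class PipelineConfig:
    """Pipeline settings with sane demo defaults (16³ phantom, n=30 cohort)."""

    out_dir: Path = Path("fwpenumbra_out")
    seed: int = 0
    # phantom / scheme
    grid: tuple[int, int, int] = (16, 16, 16)
    voxel_mm: float = 2.0
    n_dirs: int = 64
    b_value: float = 1000.0
    n_b0: int = 1
    snr: float = float("inf")
    lesion_center: tuple[float, float, float] | None = None
    lesion_semiaxes: tuple[float, float, float] = (2.5, 2.0, 2.0)
    # fit
    fit: FitConfig = field(default_factory=lambda: FitConfig(lambda_reg=0.0))
    # rois
    n_rims: int = 8
    min_lesion_voxels: int = 4
    # cohort / analysis
    n_subjects: int = 30
    alpha: float = 0.05
    penumbra_rule: str = "outer"

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        kwargs: dict = {}
        for key in (
            "out_dir",
            "seed",
            "voxel_mm",
            "n_dirs",
            "b_value",
            "n_b0",
            "snr",
            "n_rims",
            "min_lesion_voxels",
            "n_subjects",
            "alpha",
            "penumbra_rule",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "grid" in raw:
            kwargs["grid"] = tuple(raw["grid"])
        if "lesion_center" in raw:
            kwargs["lesion_center"] = tuple(raw["lesion_center"])
        if "lesion_semiaxes" in raw:
            kwargs["lesion_semiaxes"] = tuple(raw["lesion_semiaxes"])
        if "fit" in raw:
            kwargs["fit"] = FitConfig(**raw["fit"])
        if "out_dir" in kwargs:
            kwargs["out_dir"] = Path(kwargs["out_dir"])
        if "snr" in kwargs:
            kwargs["snr"] = float(kwargs["snr"])
        return cls(**kwargs)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        return d


def _default_profiles():
    # FW decays from the lesion outward; FA-t peaks in the second rim.
    fw_profile = lambda d: 0.15 + 0.25 * np.exp(-np.asarray(d) / 4.0)
    fa_profile = lambda d: 0.30 + 0.25 * np.exp(-(((np.asarray(d) - 3.2) / 1.2) ** 2))
    return fw_profile, fa_profile


def simulate_phantom_stage(cfg: PipelineConfig, out: Path) -> dict:
    """Generate phantom + DWI, write NIfTI/bval/bvec, return in-memory objects."""
    rng = np.random.default_rng(cfg.seed)
    sub = int(rng.integers(0, 2**31 - 1))
    center = cfg.lesion_center or tuple(s / 2.0 for s in cfg.grid)
    fw_profile, fa_profile = _default_profiles()
    phantom = make_phantom(
        cfg.grid,
        [Ellipsoid(center, cfg.lesion_semiaxes)],
        fw_profile,
        fa_profile,
        seed=sub,
        voxel_mm=cfg.voxel_mm,
    )
    scheme = make_gradient_scheme(cfg.n_dirs, cfg.b_value, cfg.n_b0, seed=sub)
    dwi = simulate_dwi(phantom, scheme, snr=cfg.snr, seed=sub)
    out.mkdir(parents=True, exist_ok=True)
    io.save_nifti(out / "dwi.nii.gz", dwi, phantom.affine)
    io.save_nifti(out / "wmh_mask.nii.gz", phantom.wmh_mask, phantom.affine)
    io.save_nifti(out / "wm_mask.nii.gz", phantom.wm_mask, phantom.affine)
    io.save_nifti(out / "f_true.nii.gz", phantom.f_true, phantom.affine)
    io.save_bvals_bvecs(scheme, out / "dwi.bval", out / "dwi.bvec")
    io.write_provenance(out, cfg.seed, cfg.as_dict())
    return {"phantom": phantom, "scheme": scheme, "dwi": dwi}


def analyze_cohort_table(
    table: pd.DataFrame, alpha: float = 0.05, rule: str = "outer"
) -> dict:
    """Mixed models, penumbra delimitation, and risk regressions on a long table."""
    results: dict = {}
    for outcome in ("fw", "fa_t"):
        lmm = fit_roi_lmm(table, outcome=outcome)
        pen = detect_penumbra(lmm.contrasts, alpha=alpha, rule=rule, outcome=outcome)
        results[outcome] = {"lmm": lmm, "penumbra": pen}
    # risk regressions in WMH and the FW-defined merged penumbra
    members = results["fw"]["penumbra"].member_rims
    subj = (
        table[table["roi"].astype(str) == "WMH"]
        .set_index("subject")
        .sort_index()
    )
    risk = {}
    for outcome in ("fw", "fa_t"):
        wmh_col = subj[outcome]
        tab = subj.drop(columns=["roi"]).copy()
        tab[f"{outcome}_wmh"] = wmh_col
        tab = tab.reset_index()
        risk[f"{outcome}_wmh"] = fit_risk_models(tab, f"{outcome}_wmh")
        if members:
            pmean = penumbra_mean(table, members, outcome=outcome)
            tab2 = tab.set_index("subject")
            tab2[f"{outcome}_penumbra"] = pmean
            risk[f"{outcome}_penumbra"] = fit_risk_models(
                tab2.reset_index(), f"{outcome}_penumbra"
            )
    results["risk"] = risk
    return results


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate → fit → rois → extract → analyze end to end."""
    out = Path(cfg.out_dir)
    bundle: dict = {}

    sim = simulate_phantom_stage(cfg, out / "simulate")
    phantom, scheme, dwi = sim["phantom"], sim["scheme"], sim["dwi"]

    fit_dir = out / "fit"
    fit_dir.mkdir(parents=True, exist_ok=True)
    maps = fit_freewater(dwi, scheme, phantom.fit_region, cfg.fit)
    io.save_nifti(fit_dir / "fw.nii.gz", maps.fw, phantom.affine)
    io.save_nifti(fit_dir / "fa_t.nii.gz", maps.fa_t, phantom.affine)
    from .fwfit import tensor_to_vec

    io.save_nifti(fit_dir / "tensor.nii.gz", tensor_to_vec(maps.tensor), phantom.affine)
    io.write_provenance(fit_dir, cfg.seed, cfg.as_dict())
    bundle["maps"] = maps

    roi_dir = out / "rois"
    roi_dir.mkdir(parents=True, exist_ok=True)
    wmh, excluded = filter_min_volume(phantom.wmh_mask, cfg.min_lesion_voxels)
    if excluded:
        raise RuntimeError("phantom lesion below the minimum-size threshold")
    atlas = build_rims(wmh, phantom.wm_mask, cfg.n_rims)
    io.save_nifti(roi_dir / "rim_atlas.nii.gz", atlas.labels, phantom.affine)
    io.write_provenance(roi_dir, cfg.seed, {"counts": atlas.counts})
    bundle["atlas"] = atlas

    extract_dir = out / "extract"
    extract_dir.mkdir(parents=True, exist_ok=True)
    fw_means = extract_roi_means(maps.fw, atlas)
    fat_means = extract_roi_means(maps.fa_t, atlas)
    profile = pd.DataFrame({"roi": fw_means.index, "fw": fw_means.values, "fa_t": fat_means.reindex(fw_means.index).values})
    io.save_table(profile, extract_dir / "phantom_roi_means.csv")
    io.write_provenance(extract_dir, cfg.seed, cfg.as_dict())
    bundle["phantom_profile"] = profile

    analyze_dir = out / "analyze"
    analyze_dir.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(n_subjects=cfg.n_subjects, seed=cfg.seed)
    table = simulate_cohort_rois(spec)
    io.save_table(table, analyze_dir / "cohort_long_table.csv")
    results = analyze_cohort_table(table, alpha=cfg.alpha, rule=cfg.penumbra_rule)
    for outcome in ("fw", "fa_t"):
        io.save_table(
            results[outcome]["lmm"].contrasts, analyze_dir / f"contrasts_{outcome}.csv"
        )
        pen = results[outcome]["penumbra"]
        (analyze_dir / f"penumbra_{outcome}.json").write_text(
            pd.Series(
                {
                    "outcome": pen.outcome,
                    "extent_mm": pen.extent_mm,
                    "member_rims": pen.member_rims,
                    "rule": pen.rule,
                    "alpha": pen.alpha,
                }
            ).to_json()
        )
    for name, df in results["risk"].items():
        io.save_table(df, analyze_dir / f"risk_{name}.csv")
    io.write_provenance(analyze_dir, cfg.seed, cfg.as_dict())
    bundle["cohort"] = results
    bundle["table"] = table
    return bundle
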