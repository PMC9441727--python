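"""File formats: NIfTI-1 volumes, FSL bval/bvec gradient tables, CSV tables,
and JSON provenance records."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthcohort import GradientScheme

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_table",
    "load_table",
    "write_provenance",
]

#: CSV float formatting: 10 significant digits, enough for bit-stable
#: round-trips of every quantity the pipeline writes.
CSV_FLOAT_FORMAT = "%.10g"


def save_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_bvals_bvecs(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write FSL-style gradient files: b-values on one row, directions as
    three rows (x, y, z)."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10g")


def load_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    for p in (bval_path, bvec_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"gradient file not found: {p}")
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientScheme(bvals, bvecs)


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def load_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path)


def write_provenance(out_dir: str | Path, seed: int | None, config: dict) -> Path:
    """Drop a provenance JSON (package/library versions, seed, config hash)
    into an output directory."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record = {
        "fwpenumbra": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
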