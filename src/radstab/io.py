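"""NIfTI / TSV / CSV persistence for series, masks and parametric maps.

All volumes are written as NIfTI-1 with a diagonal affine built from the
voxel spacing; float data is stored as float64 so write-then-read round
trips are lossless. The b-value table is a two-column TSV (b, n_averages)
with integer averages.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import ParametricMapSet
from .synthetic import AfProfile, BValueScheme, DwiSeries

__all__ = [
    "write_series", "read_series", "write_mask", "read_mask",
    "write_volume", "read_volume", "write_map_set", "read_map_set",
    "write_bval_table", "read_bval_table",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(path, data, spacing=(1.0, 1.0, 1.0)) -> None:
    data = np.asarray(data)
    dtype = np.uint8 if data.dtype == bool else np.float64
    img = nib.Nifti1Image(data.astype(dtype), _affine(spacing))
    nib.save(img, str(path))


def read_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def write_mask(path, mask, spacing=(1.0, 1.0, 1.0)) -> None:
    write_volume(path, np.asarray(mask, dtype=bool), spacing)


def read_mask(path):
    data, spacing = read_volume(path)
    return data.astype(bool), spacing


def write_bval_table(path, scheme: BValueScheme) -> None:
    df = pd.DataFrame(
        {"b": [int(b) if float(b).is_integer() else float(b) for b, _ in scheme.entries],
         "n_averages": [int(n) for _, n in scheme.entries]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_bval_table(path) -> BValueScheme:
    df = pd.read_csv(path, sep="\t")
    return BValueScheme(tuple((float(b), int(n)) for b, n in zip(df["b"], df["n_averages"])))


def write_series(prefix, series: DwiSeries, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write <prefix>_dwi.nii.gz, <prefix>_bvals.tsv and <prefix>_meta.json."""
    prefix = Path(prefix)
    write_volume(f"{prefix}_dwi.nii.gz", series.volumes, spacing)
    write_bval_table(f"{prefix}_bvals.tsv", series.scheme)
    meta = {
        "subject_id": series.subject_id,
        "sequence_label": series.sequence_label,
        "flags": series.flags,
        "af_profile": None,
    }
    if series.af_profile is not None:
        p = series.af_profile
        meta["af_profile"] = {"af": p.af, "tr_ms": p.tr_ms, "t1_ms": p.t1_ms,
                              "sigma_scale": p.sigma_scale}
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1))


def read_series(prefix) -> DwiSeries:
    prefix = Path(prefix)
    vols, _ = read_volume(f"{prefix}_dwi.nii.gz")
    scheme = read_bval_table(f"{prefix}_bvals.tsv")
    meta = json.loads(Path(f"{prefix}_meta.json").read_text())
    prof = meta.get("af_profile")
    af_profile = AfProfile(**prof) if prof else None
    return DwiSeries(
        volumes=np.asarray(vols, dtype=np.float64),
        scheme=scheme,
        sequence_label=meta["sequence_label"],
        af_profile=af_profile,
        subject_id=meta["subject_id"],
        flags=meta.get("flags", {}),
    )


_MAP_ATTRS = {"ADC": "adc", "D": "d", "Dstar": "d_star", "f": "f",
              "MD": "md", "MK": "mk", "R2ivim": "r2_ivim", "R2dki": "r2_dki"}


def write_map_set(prefix, map_set: ParametricMapSet, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write six parameter maps, two R^2 maps, fit mask and JSON report."""
    prefix = Path(prefix)
    for label, attr in _MAP_ATTRS.items():
        write_volume(f"{prefix}_{label}.nii.gz", getattr(map_set, attr), spacing)
    write_mask(f"{prefix}_fitmask.nii.gz", map_set.fit_mask, spacing)
    Path(f"{prefix}_fitreport.json").write_text(json.dumps(map_set.report, indent=1))


def read_map_set(prefix) -> ParametricMapSet:
    prefix = Path(prefix)
    arrays = {}
    for label, attr in _MAP_ATTRS.items():
        data, _ = read_volume(f"{prefix}_{label}.nii.gz")
        arrays[attr] = np.asarray(data, dtype=np.float64)
    fit_mask, _ = read_mask(f"{prefix}_fitmask.nii.gz")
    report = json.loads(Path(f"{prefix}_fitreport.json").read_text())
    return ParametricMapSet(fit_mask=fit_mask, report=report, **arrays)
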