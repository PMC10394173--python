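"""File readers/writers and the clinical cohort summary table.

TSV matrices are genes x samples with the gene id in the first column;
clinical tables are CSV keyed by sample_id; volumes travel as NIfTI pairs
(image + binary mask) with voxel spacing taken from the header.  Gene and
sample ids are opaque strings; duplicates are a hard error naming the
offenders.  Cohort-table percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import nibabel as nib
import numpy as np
import pandas as pd

from .scoring import MarkerSet, read_gmt  # noqa: F401  (re-exported)
from .synthetic import MaskedVolume

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "read_nifti_pair",
    "write_nifti_pair",
    "read_gmt",
    "round_half_up",
    "cohort_table",
]


def _check_unique(values, what):
    values = pd.Index(values)
    if values.has_duplicates:
        dup = values[values.duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what}: {dup}")


def read_matrix(path, kind: str = "expression") -> pd.DataFrame:
    """Read a genes x samples TSV (first column = gene id)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.index.name = "gene_id"
    _check_unique(mat.index, f"{kind} gene ids")
    _check_unique(mat.columns, f"{kind} sample ids")
    return mat


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> pd.DataFrame:
    clin = pd.read_csv(path)
    if "sample_id" not in clin.columns:
        raise ValueError("clinical table must have a sample_id column")
    _check_unique(clin["sample_id"], "clinical sample ids")
    return clin.set_index("sample_id")


def write_clinical(clin: pd.DataFrame, path) -> None:
    clin.to_csv(path, index_label="sample_id")


def read_nifti_pair(image_path, mask_path) -> MaskedVolume:
    """Load a volume + mask pair; spacing comes from the image header."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj) > 0.5
    if data.shape != mask.shape:
        raise ValueError(
            f"image shape {data.shape} does not match mask shape {mask.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MaskedVolume(intensities=data, mask=mask, spacing=spacing)


def write_nifti_pair(vol: MaskedVolume, image_path, mask_path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), str(mask_path))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_table(
    clinical: pd.DataFrame,
    labels: pd.Series,
    categorical: list[str] | None = None,
    time_col: str = "time_months",
) -> pd.DataFrame:
    """Clinical characteristics per TLS group: counts, percentages, PFS.

    For each categorical characteristic the table carries the per-group
    count and the within-group percentage (100 * count / group total,
    rounded half-up to one decimal; unknown categories stay in the
    denominator).  The survival-time row reports the per-group median and
    IQR.  Group names come from the label values.
    """
    labels = labels.loc[clinical.index]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("empty group: the cohort table compares at least two groups")
    if categorical is None:
        categorical = [
            c for c in ("age_band", "stage", "residual_disease", "relapse")
            if c in clinical.columns
        ]
    rows = []
    for char in categorical:
        col = clinical[char].astype(str).fillna("unknown")
        cats = sorted(col.unique())
        for cat in cats:
            row = {"characteristic": char, "category": cat}
            for g in groups:
                in_g = labels == g
                n_g = int(in_g.sum())
                cnt = int(((col == cat) & in_g).sum())
                row[f"n_{g}"] = cnt
                row[f"pct_{g}"] = round_half_up(100.0 * cnt / n_g, 1)
            rows.append(row)
    if time_col in clinical.columns:
        row = {"characteristic": time_col, "category": "median (IQR)"}
        for g in groups:
            t = clinical.loc[labels == g, time_col]
            row[f"n_{g}"] = int(t.notna().sum())
            row[f"pct_{g}"] = np.nan
            row[f"median_{g}"] = round_half_up(float(t.median()), 1)
            row[f"iqr_{g}"] = (
                round_half_up(float(t.quantile(0.25)), 1),
                round_half_up(float(t.quantile(0.75)), 1),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index(["characteristic", "category"])
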