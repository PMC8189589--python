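"""File formats: NIfTI volumes and masks, CSV manifests, NPZ matrices, TSV tables.

Voxel data live on millimetre lattices; volumes are written through nibabel
with a diagonal affine recovered from the lattice spacing, and masked
matrices round-trip through NPZ files with a JSON-compatible manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .map_prep import Mask

__all__ = [
    "volume_from_masked",
    "write_mask_nifti",
    "read_mask_nifti",
    "write_masked_nifti",
    "read_masked_values",
    "save_matrix",
    "load_matrix",
    "write_cohort",
    "read_manifest",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_influence_csv",
]


def _lattice_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Infer (origin, spacing, ijk indices) of a millimetre lattice."""
    coords = np.asarray(coords, dtype=float)
    origin = coords.min(axis=0)
    spacing = np.empty(3)
    for ax in range(3):
        vals = np.unique(np.round(coords[:, ax] - origin[ax], 6))
        diffs = np.diff(vals)
        spacing[ax] = float(diffs.min()) if len(diffs) else 1.0
    ijk = np.rint((coords - origin) / spacing).astype(int)
    return origin, spacing, ijk


def volume_from_masked(values: np.ndarray, mask: Mask, fill: float = 0.0) -> nib.Nifti1Image:
    """Embed masked voxel values into a dense volume (``fill`` outside)."""
    origin, spacing, ijk = _lattice_geometry(mask.coords_mm)
    shape = ijk.max(axis=0) + 1
    vol = np.full(shape, fill, dtype=np.float32)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = values
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = origin
    return nib.Nifti1Image(vol, affine)


def write_mask_nifti(mask: Mask, path: str | Path) -> None:
    img = volume_from_masked(np.ones(mask.n_voxels), mask)
    nib.save(img, str(path))


def read_mask_nifti(path: str | Path, space_tag: str = "") -> Mask:
    """Read a binary mask volume into an ordered voxel list with mm coords."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    ijk = np.argwhere(data > 0.5)
    coords = nib.affines.apply_affine(img.affine, ijk)
    return Mask(voxel_ids=np.arange(len(ijk)), coords_mm=coords, space_tag=space_tag)


def write_masked_nifti(values: np.ndarray, mask: Mask, path: str | Path) -> None:
    nib.save(volume_from_masked(values, mask), str(path))


def read_masked_values(path: str | Path, mask: Mask) -> np.ndarray:
    """Extract the mask's voxel values from a volume in the same grid."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    origin, spacing, ijk = _lattice_geometry(mask.coords_mm)
    inv = np.linalg.inv(img.affine)
    vox = nib.affines.apply_affine(inv, mask.coords_mm)
    vox = np.rint(vox).astype(int)
    return data[vox[:, 0], vox[:, 1], vox[:, 2]].astype(float)


def save_matrix(path: str | Path, matrix: np.ndarray, mask: Mask, manifest: pd.DataFrame) -> None:
    """Save a scans-by-voxels matrix with its mask and row manifest."""
    np.savez_compressed(
        path,
        matrix=matrix,
        voxel_ids=mask.voxel_ids,
        coords_mm=mask.coords_mm,
        manifest_json=json.dumps(manifest.to_dict(orient="list")),
        space_tag=mask.space_tag,
    )


def load_matrix(path: str | Path) -> tuple[np.ndarray, Mask, pd.DataFrame]:
    with np.load(path, allow_pickle=False) as z:
        matrix = z["matrix"]
        mask = Mask(z["voxel_ids"], z["coords_mm"], str(z["space_tag"]))
        manifest = pd.DataFrame(json.loads(str(z["manifest_json"])))
    return matrix, mask, manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    required = {"subject_id", "condition"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return manifest


def write_expression_tsv(expression: ExpressionMatrix, path: str | Path) -> None:
    """Samples-by-genes TSV with donor and x/y/z coordinate columns."""
    coords = np.asarray(expression.coords_mm)
    frame = pd.DataFrame(
        {
            "donor": expression.donor_ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )
    frame = pd.concat(
        [frame, pd.DataFrame(expression.values, columns=expression.gene_ids)], axis=1
    )
    frame.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t")
    meta = ["donor", "x", "y", "z"]
    genes = [c for c in frame.columns if c not in meta]
    return ExpressionMatrix(
        values=frame[genes].to_numpy(dtype=float),
        gene_ids=genes,
        coords_mm=frame[["x", "y", "z"]].to_numpy(dtype=float),
        donor_ids=frame["donor"].to_numpy(),
    )


def write_influence_csv(values: np.ndarray, mask: Mask, path: str | Path) -> None:
    coords = np.asarray(mask.coords_mm)
    pd.DataFrame(
        {
            "voxel_id": mask.voxel_ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "influence": values,
        }
    ).to_csv(path, index=False)


def write_cohort(cohort, outdir: str | Path, write_volumes: bool = True) -> pd.DataFrame:
    """Write a synthetic cohort to disk: NIfTI volumes + CSV manifest + tables.

    Returns the manifest augmented with the per-scan file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mask_nifti(cohort.roi_mask, outdir / "roi_mask.nii.gz")
    write_mask_nifti(cohort.brain_mask, outdir / "brain_mask.nii.gz")
    manifest = cohort.manifest.copy()
    roi_paths, brain_paths = [], []
    for i, row in manifest.iterrows():
        stem = f"{row['subject_id']}_{row['condition']}"
        roi_paths.append(f"{stem}_roi.nii.gz")
        brain_paths.append(f"{stem}_brain.nii.gz")
        if write_volumes:
            write_masked_nifti(cohort.roi_maps[i], cohort.roi_mask, outdir / roi_paths[-1])
            write_masked_nifti(
                cohort.brain_maps[i], cohort.brain_mask, outdir / brain_paths[-1]
            )
    manifest["roi_path"] = roi_paths
    manifest["brain_path"] = brain_paths
    manifest.to_csv(outdir / "scans.csv", index=False)
    if cohort.expression is not None:
        write_expression_tsv(cohort.expression, outdir / "expression.tsv")
    if cohort.parcellation is not None:
        pd.DataFrame(
            {"voxel_id": cohort.brain_mask.voxel_ids, "network": cohort.parcellation}
        ).to_csv(outdir / "parcellation.csv", index=False)
    if cohort.subjective_scale is not None:
        pd.DataFrame(
            cohort.subjective_scale,
            columns=[f"item_{i + 1}" for i in range(cohort.subjective_scale.shape[1])],
        ).to_csv(outdir / "subjective_scale.csv", index=False)
    if cohort.gene_sets:
        from .enrichment import write_gmt

        write_gmt(cohort.gene_sets, outdir / "gene_sets.gmt")
    return manifest
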