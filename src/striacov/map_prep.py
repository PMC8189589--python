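"""Per-scan voxel maps and the matrix preparation steps feeding the CCA.

A scan contributes one :class:`MaskedMap` per modality: a vector of voxel
values restricted to a common :class:`Mask`. This module quantifies CBF from
a perfusion-weighted / proton-density image pair, converts maps to relative
(mean-divided) maps, stacks a cohort into a scans-by-voxels matrix, and
provides train-only column standardization and PCA used throughout the
cross-validated analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Mask",
    "MaskedMap",
    "CBFQuantParams",
    "Standardization",
    "PCABasis",
    "quantify_cbf",
    "make_relative_map",
    "stack_cohort",
    "standardize_columns",
    "apply_standardization",
    "fit_pca",
    "project_pca",
]


@dataclass
class Mask:
    """An ordered set of voxels with millimetre coordinates."""

    voxel_ids: np.ndarray
    coords_mm: np.ndarray
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids)
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        if self.coords_mm.ndim != 2 or self.coords_mm.shape[1] != 3:
            raise ValueError("coords_mm must be an (n, 3) array")
        if len(self.voxel_ids) != len(self.coords_mm):
            raise ValueError("voxel_ids and coords_mm length mismatch")
        if len(np.unique(self.voxel_ids)) != len(self.voxel_ids):
            raise ValueError("voxel_ids must be unique")
        if not np.all(np.isfinite(self.coords_mm)):
            raise ValueError("coords_mm must be finite")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)


@dataclass
class MaskedMap:
    """One scan's values over the voxels of a mask."""

    values: np.ndarray
    mask: Mask
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mask.n_voxels,):
            raise ValueError(
                f"values length {self.values.shape} does not match mask "
                f"({self.mask.n_voxels} voxels)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")


@dataclass
class CBFQuantParams:
    """Constants of the pcASL quantification formula.

    Times are in seconds. Defaults follow the acquisition described in the
    study: partition coefficient lambda = 0.9 (whole-brain average), blood T1
    = 1.6 s at 3 T, grey-matter tissue T1 = 1.2 s, labeling efficiency 0.6,
    post-labeling delay 2.025 s, labeling duration 1.45 s. The proton-density
    saturation time and the perfusion-weighted scale factor / number of
    excitations are scanner-sequence constants.
    """

    lambda_partition: float = 0.9
    t1_blood: float = 1.6
    t1_tissue: float = 1.2
    efficiency: float = 0.6
    post_label_delay: float = 2.025
    label_duration: float = 1.45
    saturation_time: float = 2.0
    scale_factor_pw: float = 32.0
    nex_pw: float = 4.0

    def validate(self) -> None:
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"CBF quantification parameter {name} must be > 0")
        if self.lambda_partition > 1:
            raise ValueError("lambda_partition must be <= 1")


def quantify_cbf(
    pw_map: MaskedMap, pd_map: MaskedMap, params: CBFQuantParams
) -> MaskedMap:
    """Quantify cerebral blood flow (ml/100g/min) from PW and PD images.

    Implements the multiplicative pcASL quantification

        CBF = 6000*lambda * (1 - exp(-ST/T1t)) * exp(PLD/T1b)
              / (2*T1b*(1 - exp(-LT/T1b))*eps) * NEX_PW * PW / (SF_PW * PD)

    combining the PD partial-saturation correction, label decay over the
    post-labeling delay, and the labeling-duration/efficiency normalization.
    Linear in PW by construction.
    """
    params.validate()
    if pw_map.mask is not pd_map.mask and not np.array_equal(
        pw_map.mask.voxel_ids, pd_map.mask.voxel_ids
    ):
        raise ValueError("PW and PD maps must share one mask")
    pd_vals = pd_map.values
    bad = np.nonzero(pd_vals <= 0)[0]
    if bad.size:
        vid = pw_map.mask.voxel_ids[bad[0]]
        raise ValueError(
            f"proton-density value must be positive; voxel {vid} has {pd_vals[bad[0]]}"
        )
    p = params
    saturation = 1.0 - np.exp(-p.saturation_time / p.t1_tissue)
    decay = np.exp(p.post_label_delay / p.t1_blood)
    labeling = 2.0 * p.t1_blood * (1.0 - np.exp(-p.label_duration / p.t1_blood)) * p.efficiency
    cbf = (
        6000.0
        * p.lambda_partition
        * saturation
        * decay
        / labeling
        * p.nex_pw
        * pw_map.values
        / (p.scale_factor_pw * pd_vals)
    )
    return MaskedMap(cbf, pw_map.mask, pw_map.subject_id, pw_map.condition)


def make_relative_map(map_: MaskedMap, mean_center: bool = False) -> MaskedMap:
    """Remove the within-mask global value from a map.

    By default each voxel is divided by the within-mask mean so the output
    has mean exactly 1 (global drug effects and between-subject perfusion
    differences cancel). ``mean_center=True`` subtracts the mean instead.
    """
    mean = float(np.mean(map_.values))
    if mean_center:
        values = map_.values - mean
    else:
        if mean == 0:
            raise ValueError("cannot derive a relative map: within-mask mean is zero")
        values = map_.values / mean
    return MaskedMap(values, map_.mask, map_.subject_id, map_.condition)


def stack_cohort(maps: list[MaskedMap]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack per-scan maps into a scans-by-voxels matrix plus a row manifest."""
    if not maps:
        raise ValueError("no maps supplied")
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask is not mask and not np.array_equal(m.mask.voxel_ids, mask.voxel_ids):
            raise ValueError("all maps must share one mask")
    matrix = np.vstack([m.values for m in maps])
    manifest = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in maps],
            "condition": [m.condition for m in maps],
        }
    )
    return matrix, manifest


@dataclass
class Standardization:
    """Per-column mean/sd estimated on training rows."""

    mean: np.ndarray
    sd: np.ndarray


def standardize_columns(
    matrix: np.ndarray, fit_rows: np.ndarray | None = None
) -> tuple[np.ndarray, Standardization]:
    """Z-score columns using statistics from ``fit_rows`` only.

    Parameters are computed on the fit rows and applied to every row, so
    held-out rows are transformed with training statistics. Columns constant
    on the fit rows map to zero (sd treated as 1).
    """
    matrix = np.asarray(matrix, dtype=float)
    fit = matrix if fit_rows is None else matrix[np.asarray(fit_rows)]
    if fit.shape[0] < 2:
        raise ValueError("need at least 2 fit rows to standardize")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    params = Standardization(mean=mean, sd=sd)
    return (matrix - mean) / sd, params


def apply_standardization(matrix: np.ndarray, params: Standardization) -> np.ndarray:
    return (np.asarray(matrix, dtype=float) - params.mean) / params.sd


@dataclass
class PCABasis:
    """Top-K principal axes of a train-standardized matrix.

    ``component_loadings`` rows are the right singular vectors of the
    standardized fit matrix (orthonormal, sign-fixed so the largest-magnitude
    loading of each component is positive). Standardization parameters are
    stored so new rows can be projected with frozen training statistics.
    """

    component_loadings: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    n_components: int
    explained_variance_fraction: np.ndarray
    singular_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def standardization(self) -> Standardization:
        return Standardization(self.column_means, self.column_sds)


def fit_pca(matrix: np.ndarray, k: int, fit_rows: np.ndarray | None = None) -> PCABasis:
    """Fit a K-component PCA (via SVD) on the standardized fit rows."""
    matrix = np.asarray(matrix, dtype=float)
    fit_idx = np.arange(matrix.shape[0]) if fit_rows is None else np.asarray(fit_rows)
    n, p = len(fit_idx), matrix.shape[1]
    if not 1 <= k <= min(n, p):
        raise ValueError(f"K={k} exceeds min(rows, cols) = {min(n, p)} of fit data")
    standardized, params = standardize_columns(matrix, fit_idx)
    fit = standardized[fit_idx]
    _, s, vt = np.linalg.svd(fit, full_matrices=False)
    total = float(np.sum(s**2))
    loadings = vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)])
    loadings = loadings * flip[:, None]
    evf = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return PCABasis(
        component_loadings=loadings,
        column_means=params.mean,
        column_sds=params.sd,
        n_components=k,
        explained_variance_fraction=evf,
        singular_values=s[:k],
    )


def project_pca(basis: PCABasis, rows: np.ndarray) -> np.ndarray:
    """Project raw rows through the stored standardization and loadings."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != basis.component_loadings.shape[1]:
        raise ValueError(
            f"rows have {rows.shape[1]} columns, basis expects "
            f"{basis.component_loadings.shape[1]}"
        )
    standardized = apply_standardization(rows, basis.standardization)
    return standardized @ basis.component_loadings.T
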