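"""Synthetic cohorts with a planted cross-modal mode and known ground truth.

The generator emulates the statistical structure the analysis assumes: a
cohort of scans (paired placebo/drug plus a few single-session subjects) in
which one latent score per scan expresses itself in both modalities through
fixed spatial loading patterns, buried in spatially autocorrelated noise;
striatal expression samples in which a subset of genes tracks the planted
loading; and gene sets built to overlap those signal genes. Everything is
driven by a single seed and is bit-reproducible.

Maps are exponentiated Gaussian fields, so values are strictly positive and
relative-map division is well defined (receptor availability and blood flow
are positive quantities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .expression import ExpressionMatrix, ProbeTable
from .map_prep import Mask

__all__ = [
    "SyntheticTruth",
    "SyntheticCohort",
    "lattice_coords",
    "generate_smooth_field",
    "generate_paired_cohort",
    "generate_expression",
    "generate_gene_sets",
    "generate_parcellation",
    "generate_subjective_scale",
    "generate_study",
]


@dataclass
class SyntheticTruth:
    """Planted quantities used by recovery tests."""

    latent_scores: np.ndarray
    striatal_loading: np.ndarray
    brain_loading: np.ndarray
    planted_rho: float
    drug_shift: float
    signal_genes: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, generated with known truth."""

    manifest: pd.DataFrame
    roi_maps: np.ndarray
    brain_maps: np.ndarray
    roi_mask: Mask
    brain_mask: Mask
    expression: ExpressionMatrix | None = None
    probe_table: ProbeTable | None = None
    gene_sets: list[GeneSet] = field(default_factory=list)
    parcellation: np.ndarray | None = None
    subjective_scale: np.ndarray | None = None

    @property
    def roi_coords(self) -> np.ndarray:
        return self.roi_mask.coords_mm

    @property
    def brain_coords(self) -> np.ndarray:
        return self.brain_mask.coords_mm


def lattice_coords(n_voxels: int, spacing_mm: float = 2.0) -> np.ndarray:
    """A compact, roughly spherical blob of ``n_voxels`` lattice points (mm)."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    side = 1
    while side**3 < n_voxels:
        side += 1
    side += 2
    axis = (np.arange(side) - (side - 1) / 2) * spacing_mm
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(grid, axis=1)
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], dist))
    return grid[order[:n_voxels]]


def _sq_dists(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def smoothing_kernel(coords: np.ndarray, correlation_length: float) -> np.ndarray:
    """Isotropic exponential-decay smoothing kernel over voxel coordinates.

    The same kernel family the surrogate engine uses for variogram matching,
    so autocorrelation-aware nulls face noise they can actually emulate.
    """
    if correlation_length == 0:
        return np.eye(len(coords))
    return np.exp(-np.sqrt(_sq_dists(coords)) / correlation_length)


def _standardize_fields(fields: np.ndarray) -> np.ndarray:
    fields = fields - fields.mean(axis=-1, keepdims=True)
    sd = fields.std(axis=-1, keepdims=True)
    return fields / np.where(sd > 0, sd, 1.0)


def generate_smooth_field(
    coords: np.ndarray, correlation_length: float, rng: np.random.Generator
) -> np.ndarray:
    """White noise smoothed at the given length, re-standardized to z-scores.

    ``correlation_length=0`` returns standardized white noise unchanged.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("coords must be non-empty")
    if correlation_length < 0:
        raise ValueError("correlation_length must be >= 0")
    white = rng.standard_normal(len(coords))
    if correlation_length == 0:
        return _standardize_fields(white)
    kernel = smoothing_kernel(coords, correlation_length)
    return _standardize_fields(kernel @ white)


def _marginal_smooth_fields(
    kernel: np.ndarray, n_fields: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth Gaussian fields with exactly unit marginal voxel variance.

    Each field is K @ w with w white, divided per voxel by the row norm of K,
    so the voxel-voxel covariance is exactly the correlation matrix
    C = D^-1/2 K K' D^-1/2. Returns (fields, row norms of K).
    """
    row_norms = np.linalg.norm(kernel, axis=1)
    white = rng.standard_normal((n_fields, kernel.shape[0]))
    return (white @ kernel.T) / row_norms, row_norms


def _build_manifest(
    n_paired: int, n_unpaired: int, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for i in range(n_paired):
        sid = f"S{i + 1:02d}"
        rows.append((sid, "placebo"))
        rows.append((sid, "drug"))
    for i in range(n_unpaired):
        sid = f"S{n_paired + i + 1:02d}"
        # the study does not report the single-scan subjects' conditions;
        # assign them at random
        rows.append((sid, rng.choice(["placebo", "drug"])))
    return pd.DataFrame(rows, columns=["subject_id", "condition"])


def generate_paired_cohort(
    n_paired: int = 23,
    n_unpaired: int = 5,
    n_roi_vox: int = 500,
    n_brain_vox: int = 2000,
    planted_rho: float = 0.5,
    drug_shift: float = 0.5,
    noise_corr_length: float = 6.0,
    voxel_noise_sd: float = 0.2,
    loading_corr_length: float = 8.0,
    log_amplitude: float = 0.1,
    roi_spacing: float = 2.0,
    brain_spacing: float = 4.0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[SyntheticCohort, SyntheticTruth]:
    """Generate a paired placebo/drug cohort sharing one cross-modal mode.

    Per scan, a latent score z ~ N(0, 1) (plus ``drug_shift`` for drug
    sessions) drives both modalities through unit-norm smooth loading maps a
    (ROI) and b (brain): log-maps are ``log_amplitude * (gamma*z*loading +
    structured smooth noise + voxel white noise)`` and maps are their
    exponentials. The signal gain gamma and the structured-noise scale are
    chosen so the population correlation of the planted modal projections
    (a'log-ROI vs b'log-brain, conditional on condition) equals
    ``planted_rho``. Defaults mirror the study design: 23 paired + 5 single
    subjects = 51 scans.
    """
    if not 0 <= planted_rho < 1:
        raise ValueError("planted_rho must lie in [0, 1); rho = 1 is degenerate")
    if not 0 <= voxel_noise_sd <= 1:
        raise ValueError("voxel_noise_sd must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    manifest = _build_manifest(n_paired, n_unpaired, rng)
    n_scans = len(manifest)
    roi_coords = lattice_coords(n_roi_vox, roi_spacing)
    brain_coords = lattice_coords(n_brain_vox, brain_spacing)

    gamma = np.sqrt(planted_rho / (1.0 - planted_rho))
    is_drug = (manifest["condition"] == "drug").to_numpy()
    z = rng.standard_normal(n_scans) + drug_shift * is_drug

    maps, loadings = [], []
    for coords in (roi_coords, brain_coords):
        loading = generate_smooth_field(coords, loading_corr_length, rng)
        loading = loading / np.linalg.norm(loading)
        kernel = smoothing_kernel(coords, noise_corr_length)
        smooth, row_norms = _marginal_smooth_fields(kernel, n_scans, rng)
        # exact variance of the loading projection of the structured field:
        # a' C a with C = D^-1/2 K K' D^-1/2
        proj_var = float(np.sum((kernel.T @ (loading / row_norms)) ** 2))
        sigma_s = np.sqrt(max(1.0 - voxel_noise_sd**2, 0.0) / proj_var)
        white = rng.standard_normal((n_scans, len(coords)))
        log_map = log_amplitude * (
            gamma * np.outer(z, loading) + sigma_s * smooth + voxel_noise_sd * white
        )
        maps.append(np.exp(log_map))
        loadings.append(loading)

    roi_mask = Mask(np.arange(n_roi_vox), roi_coords, space_tag="synthetic-roi")
    brain_mask = Mask(np.arange(n_brain_vox), brain_coords, space_tag="synthetic-brain")
    cohort = SyntheticCohort(
        manifest=manifest,
        roi_maps=maps[0],
        brain_maps=maps[1],
        roi_mask=roi_mask,
        brain_mask=brain_mask,
    )
    truth = SyntheticTruth(
        latent_scores=z,
        striatal_loading=loadings[0],
        brain_loading=loadings[1],
        planted_rho=planted_rho,
        drug_shift=drug_shift,
    )
    return cohort, truth


def generate_expression(
    striatal_loading: np.ndarray,
    roi_coords: np.ndarray,
    n_samples: int = 153,
    n_genes: int = 500,
    n_signal: int = 50,
    effect_beta: float = 1.0,
    noise_sd: float = 0.2,
    n_donors: int = 6,
    jitter_mm: float = 2.0,
    jitter_frac: float = 0.3,
    donor_effect_sd: float = 0.3,
    seed: int | np.random.Generator | None = 0,
) -> tuple[ExpressionMatrix, ProbeTable, list[str]]:
    """Striatal expression samples in which signal genes track the loading.

    Samples are placed at ROI voxel centres (donors overlap on a shared pool
    of sites so differential stability is estimable); a fraction is jittered
    off-centre by up to ``jitter_mm`` to exercise nearest-voxel matching.
    Signal genes follow ``effect_beta * loading-at-sample + noise``; the rest
    are pure noise. A probe-level table carries >= 1 probe per gene with
    background-exceedance flags, including low-stability duplicate probes
    and low-background probes destined to be filtered.

    Returns (gene-level expression, probe table, signal gene ids).
    """
    if n_signal > n_genes:
        raise ValueError("n_signal must be <= n_genes")
    rng = np.random.default_rng(seed)
    roi_coords = np.asarray(roi_coords, dtype=float)
    n_vox = len(roi_coords)
    if n_samples > n_vox:
        raise ValueError(f"n_samples = {n_samples} exceeds available voxels ({n_vox})")

    pool_size = min(n_vox, max(int(np.ceil(n_samples / n_donors)), int(np.ceil(n_samples / 3))))
    pool = rng.choice(n_vox, size=pool_size, replace=False)
    donors = np.array([f"D{(i % n_donors) + 1}" for i in range(n_samples)])
    voxel_ids = np.empty(n_samples, dtype=int)
    for d in np.unique(donors):
        idx = np.nonzero(donors == d)[0]
        voxel_ids[idx] = rng.choice(pool, size=len(idx), replace=False)

    coords = roi_coords[voxel_ids].copy()
    n_jitter = int(round(jitter_frac * n_samples))
    jitter_idx = rng.choice(n_samples, size=n_jitter, replace=False)
    directions = rng.standard_normal((n_jitter, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = rng.uniform(0, jitter_mm, size=n_jitter)
    coords[jitter_idx] += directions * radii[:, None]

    loading_z = (striatal_loading - striatal_loading.mean()) / striatal_loading.std()
    y = loading_z[voxel_ids]

    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    signal_idx = rng.choice(n_genes, size=n_signal, replace=False)
    values = rng.standard_normal((n_samples, n_genes))
    values[:, signal_idx] = (
        effect_beta * y[:, None] + noise_sd * rng.standard_normal((n_samples, n_signal))
    )
    donor_codes = pd.factorize(donors)[0]
    donor_offsets = donor_effect_sd * rng.standard_normal((n_donors, n_genes))
    values = values + donor_offsets[donor_codes]

    expression = ExpressionMatrix(
        values=values,
        gene_ids=list(gene_ids),
        coords_mm=coords,
        donor_ids=donors,
    )

    # probe table: one stable probe per gene; ~30% of genes get a noisy
    # duplicate probe; ~5% of probes have low background exceedance
    probe_rows, probe_exprs, probe_flags = [], [], []
    for g, gid in enumerate(gene_ids):
        n_probes = 2 if rng.random() < 0.3 else 1
        for j in range(n_probes):
            probe_sd = 0.05 if j == 0 else 0.8
            expr = values[:, g] + probe_sd * rng.standard_normal(n_samples)
            if j == 0:
                flag_prob = 0.95
            else:
                flag_prob = 0.3 if rng.random() < 0.15 else 0.9
            flags = rng.random(n_samples) < flag_prob
            probe_rows.append((f"P{gid[1:]}_{j + 1}", gid))
            probe_exprs.append(expr)
            probe_flags.append(flags)
    probe_table = ProbeTable(
        probes=pd.DataFrame(probe_rows, columns=["probe_id", "gene_id"]),
        expression=np.vstack(probe_exprs),
        background_exceeded=np.vstack(probe_flags),
        donor_ids=donors,
        coords_mm=coords,
    )
    signal_genes = [gene_ids[i] for i in sorted(signal_idx)]
    return expression, probe_table, signal_genes


def generate_gene_sets(
    signal_genes: list[str],
    all_genes: list[str],
    n_sets: int = 10,
    overlap_frac: float = 0.8,
    set_size: int = 40,
    seed: int | np.random.Generator | None = 0,
) -> list[GeneSet]:
    """Gene sets: one planted set overlapping the signal genes, rest random."""
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must lie in [0, 1]")
    if set_size > len(all_genes):
        raise ValueError("set_size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    signal = [g for g in signal_genes if g in set(all_genes)]
    background = [g for g in all_genes if g not in set(signal)]
    n_from_signal = min(int(round(overlap_frac * set_size)), len(signal))
    members = list(rng.choice(signal, size=n_from_signal, replace=False)) + list(
        rng.choice(background, size=set_size - n_from_signal, replace=False)
    )
    sets = [GeneSet(name="PLANTED_ENRICHED", genes=tuple(sorted(members)), direction="up")]
    for i in range(n_sets - 1):
        members = rng.choice(all_genes, size=set_size, replace=False)
        sets.append(GeneSet(name=f"RANDOM_{i + 1:02d}", genes=tuple(sorted(members))))
    return sets


def generate_parcellation(
    brain_coords: np.ndarray,
    n_networks: int = 7,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Label every voxel with one of ``n_networks`` contiguous (Voronoi) blobs."""
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    rng = np.random.default_rng(seed)
    brain_coords = np.asarray(brain_coords, dtype=float)
    centers = brain_coords[rng.choice(len(brain_coords), size=n_networks, replace=False)]
    dists = np.linalg.norm(brain_coords[:, None, :] - centers[None, :, :], axis=2)
    return np.argmin(dists, axis=1)


def generate_subjective_scale(
    conditions: np.ndarray | pd.Series,
    drug_shift: float,
    slope: float = 1.0,
    noise_sd: float = 0.5,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Ten five-point drug-effect items per scan, drug scans shifted by slope*delta."""
    rng = np.random.default_rng(seed)
    is_drug = (np.asarray(conditions) == "drug").astype(float)
    base = 3.0 + slope * drug_shift * is_drug[:, None]
    items = np.rint(base + noise_sd * rng.standard_normal((len(is_drug), 10)))
    return np.clip(items, 1, 5).astype(int)


def generate_study(
    seed: int | np.random.Generator | None = 0,
    expression_kwargs: dict | None = None,
    gene_set_kwargs: dict | None = None,
    n_networks: int = 7,
    scale_slope: float = 1.0,
    scale_noise_sd: float = 0.5,
    **cohort_kwargs,
) -> tuple[SyntheticCohort, SyntheticTruth]:
    """Generate the full study bundle: scans, expression, sets, labels, scale."""
    root = np.random.default_rng(seed)
    streams = root.spawn(5)
    cohort, truth = generate_paired_cohort(seed=streams[0], **cohort_kwargs)
    expression, probes, signal = generate_expression(
        truth.striatal_loading,
        cohort.roi_coords,
        seed=streams[1],
        **(expression_kwargs or {}),
    )
    cohort.expression = expression
    cohort.probe_table = probes
    truth.signal_genes = signal
    cohort.gene_sets = generate_gene_sets(
        signal, expression.gene_ids, seed=streams[2], **(gene_set_kwargs or {})
    )
    truth.enriched_sets = [cohort.gene_sets[0].name]
    cohort.parcellation = generate_parcellation(
        cohort.brain_coords, n_networks=n_networks, seed=streams[3]
    )
    cohort.subjective_scale = generate_subjective_scale(
        cohort.manifest["condition"],
        truth.drug_shift,
        slope=scale_slope,
        noise_sd=scale_noise_sd,
        seed=streams[4],
    )
    return cohort, truth
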