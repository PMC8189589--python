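"""Cross-modal mode of covariation: CCA, permutation inference, influence maps.

The analysis asks whether spatial patterns in a small ROI modality (e.g.
striatal receptor availability) share information with patterns in a
whole-brain modality (e.g. blood flow) across scans. Each modality is
standardized and PCA-reduced to K components; CCA then finds canonical
weight vectors U, V maximizing the Pearson correlation of the canonical
variates PU and CV. Because CCA maximizes in-sample correlation by
construction, significance rests on cross-validated out-of-sample
correlations compared against permutation nulls that respect the repeated-
measures structure (a subject's two scans form an exchangeability block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .map_prep import PCABasis, fit_pca, project_pca

__all__ = [
    "CCAMode",
    "PermutationScheme",
    "ModeTestResult",
    "InfluenceMap",
    "fit_cca",
    "fit_mode",
    "score_scans",
    "scheme_from_manifest",
    "block_permutation",
    "cross_validated_mode_test",
    "matching_accuracy_test",
    "covariation_influence",
]

_RANK_TOL = 1e-10


def _cca_core(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """First canonical correlation and weight pair via whitening SVD.

    Columns are centered internally; inputs are expected to be standardized
    (or PCA scores). Raises on rank-deficient blocks, where canonical
    weights are not identified.
    """
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    ux, sx, vtx = np.linalg.svd(x, full_matrices=False)
    uy, sy, vty = np.linalg.svd(y, full_matrices=False)
    if sx[-1] <= _RANK_TOL * sx[0] or sy[-1] <= _RANK_TOL * sy[0]:
        raise ValueError(
            "rank-deficient input: a modality block has linearly dependent "
            "columns; reduce K or remove collinear components"
        )
    a, r, bt = np.linalg.svd(ux.T @ uy)
    u = vtx.T @ (a[:, 0] / sx)
    v = vty.T @ (bt[0] / sy)
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    # deterministic overall sign (joint flip preserves the correlation)
    if u[np.argmax(np.abs(u))] < 0:
        u, v = -u, -v
    return float(min(r[0], 1.0)), u, v


@dataclass
class CCAMode:
    """A fitted first canonical mode, optionally with its PCA front-ends.

    ``u``/``v`` are unit-norm canonical weight vectors in component space;
    ``variates`` holds the per-scan (ROI score, brain score) pairs of the
    fitted scans. When ``roi_basis``/``brain_basis`` are present the mode can
    score raw voxel rows end to end with frozen training parameters.
    """

    u: np.ndarray
    v: np.ndarray
    k: int
    canonical_r: float
    variates: np.ndarray
    roi_basis: PCABasis | None = None
    brain_basis: PCABasis | None = None


def fit_cca(p_scores: np.ndarray, c_scores: np.ndarray) -> CCAMode:
    """Fit the first canonical weight pair on two N x K score matrices."""
    p_scores = np.asarray(p_scores, dtype=float)
    c_scores = np.asarray(c_scores, dtype=float)
    n, k = p_scores.shape
    if c_scores.shape[0] != n:
        raise ValueError("modality blocks must have the same number of rows")
    if not n > max(k, c_scores.shape[1]):
        raise ValueError("need more rows than columns (N > K)")
    r, u, v = _cca_core(p_scores, c_scores)
    variates = np.column_stack([p_scores @ u, c_scores @ v])
    return CCAMode(u=u, v=v, k=k, canonical_r=r, variates=variates)


def fit_mode(
    roi_matrix: np.ndarray,
    brain_matrix: np.ndarray,
    k: int,
    fit_rows: np.ndarray | None = None,
) -> CCAMode:
    """Standardize + PCA(K) + CCA, all fit on ``fit_rows`` only.

    Returns a mode whose stored bases allow raw held-out rows to be scored
    with the frozen training transform.
    """
    fit_idx = (
        np.arange(np.asarray(roi_matrix).shape[0])
        if fit_rows is None
        else np.asarray(fit_rows)
    )
    roi_basis = fit_pca(roi_matrix, k, fit_idx)
    brain_basis = fit_pca(brain_matrix, k, fit_idx)
    p = project_pca(roi_basis, np.asarray(roi_matrix)[fit_idx])
    c = project_pca(brain_basis, np.asarray(brain_matrix)[fit_idx])
    mode = fit_cca(p, c)
    mode.roi_basis = roi_basis
    mode.brain_basis = brain_basis
    return mode


def score_scans(
    mode: CCAMode, roi_rows: np.ndarray, brain_rows: np.ndarray
) -> np.ndarray:
    """Score raw scans through the mode's frozen PCA bases and weights.

    Returns an (n, 2) array of (ROI score, brain score) pairs.
    """
    if mode.roi_basis is None or mode.brain_basis is None:
        raise ValueError("mode has no stored PCA bases; fit it with fit_mode()")
    p = project_pca(mode.roi_basis, roi_rows)
    c = project_pca(mode.brain_basis, brain_rows)
    if p.shape[1] != len(mode.u) or c.shape[1] != len(mode.v):
        raise ValueError("dimensionality mismatch between rows and mode")
    return np.column_stack([p @ mode.u, c @ mode.v])


# ---------------------------------------------------------------------------
# permutation schemes


@dataclass
class PermutationScheme:
    """Free or block (subject-grouped) permutation of scan indices."""

    kind: str
    blocks: list[np.ndarray] = field(default_factory=list)
    n_scans: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("free", "block"):
            raise ValueError("scheme kind must be 'free' or 'block'")
        if self.kind == "block":
            flat = np.concatenate(self.blocks) if self.blocks else np.array([], int)
            if len(flat) != self.n_scans or len(np.unique(flat)) != len(flat):
                raise ValueError("blocks must partition the scan indices")


def scheme_from_manifest(manifest: pd.DataFrame, kind: str = "block") -> PermutationScheme:
    """Build the exchangeability scheme from a (subject_id, condition) manifest."""
    n = len(manifest)
    if kind == "free":
        return PermutationScheme(kind="free", n_scans=n)
    blocks = [
        np.asarray(idx)
        for _, idx in manifest.groupby("subject_id", sort=False).indices.items()
    ]
    return PermutationScheme(kind="block", blocks=blocks, n_scans=n)


def block_permutation(scheme: PermutationScheme, rng: np.random.Generator) -> np.ndarray:
    """Draw one scan-index permutation respecting the scheme.

    Free: uniform permutation. Block: whole blocks of equal size are
    exchanged as units, preserving within-block order, so a subject's two
    scans travel together.
    """
    if scheme.kind == "free":
        return rng.permutation(scheme.n_scans)
    perm = np.empty(scheme.n_scans, dtype=int)
    sizes: dict[int, list[np.ndarray]] = {}
    for b in scheme.blocks:
        sizes.setdefault(len(b), []).append(b)
    for size, group in sizes.items():
        if len(group) < 2:
            raise ValueError(
                f"block of size {size} has no same-size partner to exchange with"
            )
        order = rng.permutation(len(group))
        for dest, src in zip(group, (group[i] for i in order)):
            perm[dest] = src
    return perm


# ---------------------------------------------------------------------------
# cross-validated mode test


@dataclass
class ModeTestResult:
    """Out-of-sample mode strength with its permutation null."""

    mean_oos_r: float
    per_k_r: dict[int, float]
    null_distribution: np.ndarray
    p_value: float
    n_splits: int
    n_perm: int


def _test_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _pca_split_fit(
    matrix: np.ndarray, train: np.ndarray, kmax: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train-only standardization + SVD for the mode-test inner loop.

    Returns (train-row left singular vectors, singular values, PCA scores of
    all rows), truncated to ``kmax`` components.
    """
    from .map_prep import standardize_columns

    standardized, _ = standardize_columns(matrix, train)
    u, s, vt = np.linalg.svd(standardized[train], full_matrices=False)
    if s[kmax - 1] <= _RANK_TOL * s[0]:
        raise ValueError("rank-deficient training data for the requested K")
    return u[:, :kmax], s[:kmax], standardized @ vt[:kmax].T


def _split_statistic(
    roi_matrix: np.ndarray,
    brain_rows_by_scan: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    k_values: tuple[int, ...],
    roi_cache: dict | None = None,
) -> np.ndarray:
    """Per-K out-of-sample first-variate correlation for one split.

    PCA components are nested in K, so one K_max SVD per modality serves
    every K; train PCA scores are orthogonal with variances given by the
    singular values, so CCA whitening reduces to a diagonal rescaling and
    the canonical pair comes from one small SVD of U_p' U_c (equivalent to
    fit_cca on the PCA scores, which is asserted in the test suite). The ROI
    side does not change under brain-map permutations, so its per-split fit
    is cached by the caller.
    """
    kmax = max(k_values)
    if roi_cache is not None and "fit" in roi_cache:
        up, sp, p_all = roi_cache["fit"]
    else:
        up, sp, p_all = _pca_split_fit(roi_matrix, train, kmax)
        if roi_cache is not None:
            roi_cache["fit"] = (up, sp, p_all)
    uc, sc, c_all = _pca_split_fit(brain_rows_by_scan, train, kmax)
    cross = up.T @ uc
    p_test, c_test = p_all[test], c_all[test]
    out = np.empty(len(k_values))
    for i, k in enumerate(k_values):
        a, _, bt = np.linalg.svd(cross[:k, :k])
        u = a[:, 0] / sp[:k]
        v = bt[0] / sc[:k]
        out[i] = _test_correlation(p_test[:, :k] @ u, c_test[:, :k] @ v)
    return out


def _make_splits(
    manifest: pd.DataFrame,
    n_splits: int,
    train_frac: float,
    pair_preserving: bool,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    n = len(manifest)
    if pair_preserving:
        units = [
            np.asarray(idx)
            for _, idx in manifest.groupby("subject_id", sort=False).indices.items()
        ]
    else:
        units = [np.array([i]) for i in range(n)]
    n_train_units = int(round(train_frac * len(units)))
    if not 1 <= n_train_units < len(units):
        raise ValueError("train_frac leaves no train or no test units")
    splits = []
    for _ in range(n_splits):
        order = rng.permutation(len(units))
        train = np.concatenate([units[i] for i in order[:n_train_units]])
        test = np.concatenate([units[i] for i in order[n_train_units:]])
        if len(test) < 3:
            raise ValueError("test partition too small to correlate variates")
        splits.append((np.sort(train), np.sort(test)))
    return splits


def cross_validated_mode_test(
    roi_matrix: np.ndarray,
    brain_matrix: np.ndarray,
    manifest: pd.DataFrame,
    k_values: tuple[int, ...] = tuple(range(2, 11)),
    n_splits: int = 100,
    train_frac: float = 0.8,
    n_perm: int = 1000,
    scheme: PermutationScheme | str = "block",
    pair_preserving_split: bool = False,
    rng: np.random.Generator | int | None = None,
) -> ModeTestResult:
    """Cross-validated out-of-sample test of the first canonical mode.

    For each PCA dimensionality K, the data are split ``n_splits`` times
    (80/20 by default); standardization, PCA and CCA are fit on the training
    rows and the first-variate correlation is computed on the test rows. The
    overall statistic is the mean over splits and over K. The null re-runs
    the identical procedure (same splits) after permuting the brain-map rows
    under the requested exchangeability scheme; p uses the add-one estimator
    (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    roi_matrix = np.asarray(roi_matrix, dtype=float)
    brain_matrix = np.asarray(brain_matrix, dtype=float)
    if isinstance(scheme, str):
        scheme = scheme_from_manifest(manifest, scheme)
    k_values = tuple(int(k) for k in k_values)
    splits = _make_splits(manifest, n_splits, train_frac, pair_preserving_split, rng)

    roi_caches = [dict() for _ in splits]
    per_split = np.vstack(
        [
            _split_statistic(roi_matrix, brain_matrix, tr, te, k_values, cache)
            for (tr, te), cache in zip(splits, roi_caches)
        ]
    )
    per_k = per_split.mean(axis=0)
    observed = float(per_k.mean())

    null = np.empty(n_perm)
    for j in range(n_perm):
        perm = block_permutation(scheme, rng)
        permuted = brain_matrix[perm]
        stats = np.vstack(
            [
                _split_statistic(roi_matrix, permuted, tr, te, k_values, cache)
                for (tr, te), cache in zip(splits, roi_caches)
            ]
        )
        null[j] = stats.mean()
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return ModeTestResult(
        mean_oos_r=observed,
        per_k_r={k: float(r) for k, r in zip(k_values, per_k)},
        null_distribution=null,
        p_value=p,
        n_splits=n_splits,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# matching accuracy test


def _matching_rounds(
    roi_matrix: np.ndarray,
    brain_matrix: np.ndarray,
    holdouts: list[np.ndarray],
    k: int,
) -> float:
    n = roi_matrix.shape[0]
    successes = 0
    for pair in holdouts:
        train = np.setdiff1d(np.arange(n), pair)
        mode = fit_mode(roi_matrix, brain_matrix, k, train)
        scores = score_scans(mode, roi_matrix[pair], brain_matrix[pair])
        d_roi = scores[0, 0] - scores[1, 0]
        d_brain = scores[0, 1] - scores[1, 1]
        # ties count as failure (conservative, deterministic)
        if d_roi * d_brain > 0:
            successes += 1
    return successes / len(holdouts)


def matching_accuracy_test(
    roi_matrix: np.ndarray,
    brain_matrix: np.ndarray,
    manifest: pd.DataFrame,
    k: int = 8,
    n_rounds: int = 100,
    n_perm: int = 100,
    scheme: PermutationScheme | str = "block",
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float, float]:
    """Leave-two-out matching test: can ROI scans identify their brain scans?

    Each round leaves out two scans, fits the mode on the rest, scores the
    held-out pair in both modalities and counts a success iff the rank order
    of the two ROI scores equals that of the two brain scores (chance = 1/2).
    The null repeats the whole procedure on permuted modality pairings.
    Returns (accuracy, null_mean, null_sd, p).
    """
    roi_matrix = np.asarray(roi_matrix, dtype=float)
    brain_matrix = np.asarray(brain_matrix, dtype=float)
    n = roi_matrix.shape[0]
    if n < 4:
        raise ValueError("matching test needs at least 4 scans")
    rng = np.random.default_rng(rng)
    if isinstance(scheme, str):
        scheme = scheme_from_manifest(manifest, scheme)
    holdouts = [rng.choice(n, size=2, replace=False) for _ in range(n_rounds)]
    accuracy = _matching_rounds(roi_matrix, brain_matrix, holdouts, k)
    null = np.empty(n_perm)
    for j in range(n_perm):
        perm = block_permutation(scheme, rng)
        null[j] = _matching_rounds(roi_matrix, brain_matrix[perm], holdouts, k)
    p = (1 + int(np.sum(null >= accuracy))) / (1 + n_perm)
    return accuracy, float(null.mean()), float(null.std(ddof=0)), p


# ---------------------------------------------------------------------------
# covariation influence


@dataclass
class InfluenceMap:
    """Per-voxel correlation between the data and a canonical variate."""

    values: np.ndarray
    mask: object | None = None
    modality: str = ""


def covariation_influence(
    data_matrix: np.ndarray, variate: np.ndarray, mask=None, modality: str = ""
) -> InfluenceMap:
    """Correlate each voxel column with the canonical variate.

    Captures how strongly each voxel tracks the mode of covariation.
    Constant voxels are assigned influence 0.
    """
    data_matrix = np.asarray(data_matrix, dtype=float)
    variate = np.asarray(variate, dtype=float)
    if data_matrix.shape[0] != len(variate):
        raise ValueError("matrix rows must align with variate entries")
    if data_matrix.shape[0] < 3:
        raise ValueError("need at least 3 scans to estimate influence")
    x = data_matrix - data_matrix.mean(axis=0)
    v = variate - variate.mean()
    vnorm = np.linalg.norm(v)
    xnorm = np.linalg.norm(x, axis=0)
    if vnorm == 0:
        raise ValueError("variate is constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x.T @ v) / (xnorm * vnorm)
    r[xnorm == 0] = 0.0
    return InfluenceMap(values=np.clip(r, -1.0, 1.0), mask=mask, modality=modality)
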