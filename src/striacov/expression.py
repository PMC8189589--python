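"""Spatial gene expression preparation and the PLS link to covariation influence.

Mirrors the standard microarray-atlas workflow: intensity-based probe
filtering, representative-probe selection by differential stability across
donors, nearest-voxel sample matching (3 mm radius), and scaled robust
sigmoid normalization within donor. A univariate partial least squares
(NIPALS) regression then predicts the covariation-influence value at each
matched voxel from gene expression; inference uses cross-validated accuracy
against permutation / spatial-surrogate nulls, and genes are ranked by
bootstrap-stabilized VIP (variable importance in the projection) z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.model_selection import KFold

from .map_prep import Mask

__all__ = [
    "ProbeTable",
    "ExpressionMatrix",
    "PLSModel",
    "filter_probes",
    "differential_stability",
    "select_probe_by_differential_stability",
    "match_samples_to_voxels",
    "scaled_robust_sigmoid",
    "normalize_expression",
    "fit_pls",
    "predict_pls",
    "cv_pls_accuracy",
    "pls_significance",
    "vip_scores",
    "bootstrap_vip_ranking",
]

logger = logging.getLogger(__name__)


@dataclass
class ProbeTable:
    """Probe-level expression with background-exceedance flags.

    ``expression`` and ``background_exceeded`` are (n_probes, n_samples);
    every probe maps to exactly one gene.
    """

    probes: pd.DataFrame  # columns: probe_id, gene_id
    expression: np.ndarray
    background_exceeded: np.ndarray
    donor_ids: np.ndarray
    coords_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.expression.shape != self.background_exceeded.shape:
            raise ValueError("background flags must have the shape of expression")
        if len(self.probes) != self.expression.shape[0]:
            raise ValueError("probe metadata rows must match expression rows")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass
class ExpressionMatrix:
    """Samples-by-genes expression with coordinates and donor labels."""

    values: np.ndarray
    gene_ids: list[str]
    coords_mm: np.ndarray
    donor_ids: np.ndarray
    matched_voxel_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        keys = list(zip(self.donor_ids, map(tuple, np.asarray(self.coords_mm))))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (donor, coordinate) sample rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def filter_probes(probes: ProbeTable, min_frac: float = 0.5) -> ProbeTable:
    """Keep probes exceeding background noise in >= ``min_frac`` of samples.

    Probes at exactly the threshold are kept (the removal set is
    strictly-below-threshold).
    """
    frac = probes.background_exceeded.mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        logger.warning("intensity filter removed every probe")
    return ProbeTable(
        probes=probes.probes.loc[keep].reset_index(drop=True),
        expression=probes.expression[keep],
        background_exceeded=probes.background_exceeded[keep],
        donor_ids=probes.donor_ids,
        coords_mm=probes.coords_mm,
    )


def _location_keys(coords: np.ndarray) -> list[tuple]:
    return [tuple(np.round(c, 6)) for c in np.asarray(coords)]


def differential_stability(probes: ProbeTable) -> np.ndarray:
    """Mean inter-donor correlation of each probe's spatial profile.

    For every donor pair, each probe's expression across the locations
    sampled by both donors is correlated; DS is the mean over pairs. Pairs
    with fewer than 3 common locations (or a constant profile) are skipped;
    a probe with no usable pair gets DS = nan.
    """
    donors = np.unique(probes.donor_ids)
    if len(donors) < 2:
        raise ValueError("differential stability needs >= 2 donors")
    keys = np.array(_location_keys(probes.coords_mm), dtype=object)
    by_donor = {}
    for d in donors:
        idx = np.nonzero(probes.donor_ids == d)[0]
        by_donor[d] = dict(zip([tuple(k) for k in keys[idx]], idx))
    n_probes = probes.expression.shape[0]
    sums = np.zeros(n_probes)
    counts = np.zeros(n_probes)
    for i, d1 in enumerate(donors):
        for d2 in donors[i + 1 :]:
            common = sorted(set(by_donor[d1]) & set(by_donor[d2]))
            if len(common) < 3:
                continue
            idx1 = np.array([by_donor[d1][k] for k in common])
            idx2 = np.array([by_donor[d2][k] for k in common])
            x = probes.expression[:, idx1]
            y = probes.expression[:, idx2]
            x = x - x.mean(axis=1, keepdims=True)
            y = y - y.mean(axis=1, keepdims=True)
            nx = np.linalg.norm(x, axis=1)
            ny = np.linalg.norm(y, axis=1)
            ok = (nx > 0) & (ny > 0)
            r = np.zeros(n_probes)
            r[ok] = np.einsum("ij,ij->i", x[ok], y[ok]) / (nx[ok] * ny[ok])
            sums[ok] += r[ok]
            counts[ok] += 1
    with np.errstate(invalid="ignore"):
        ds = sums / counts
    ds[counts == 0] = np.nan
    return ds


def select_probe_by_differential_stability(probes: ProbeTable) -> ExpressionMatrix:
    """Collapse to one probe per gene: the highest-DS probe (ties by probe id)."""
    ds = differential_stability(probes)
    meta = probes.probes.assign(ds=np.where(np.isnan(ds), -np.inf, ds))
    chosen = (
        meta.sort_values(["gene_id", "ds", "probe_id"], ascending=[True, False, True])
        .groupby("gene_id", sort=True)
        .head(1)
    )
    gene_ids = chosen["gene_id"].tolist()
    values = probes.expression[chosen.index.to_numpy()].T
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        coords_mm=probes.coords_mm,
        donor_ids=probes.donor_ids,
    )


def match_samples_to_voxels(
    expression: ExpressionMatrix, mask: Mask, max_dist_mm: float = 3.0
) -> tuple[ExpressionMatrix, int]:
    """Match each sample to its nearest mask voxel within ``max_dist_mm``.

    In-mask samples take their containing voxel (distance 0 to its centre);
    samples farther than the radius from every mask voxel are dropped.
    Returns the matched matrix and the number of dropped samples.
    """
    tree = cKDTree(mask.coords_mm)
    dists, nearest = tree.query(np.asarray(expression.coords_mm, dtype=float))
    keep = dists <= max_dist_mm
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropped %d samples beyond %.1f mm of the mask", n_dropped, max_dist_mm)
    matched = ExpressionMatrix(
        values=expression.values[keep],
        gene_ids=list(expression.gene_ids),
        coords_mm=np.asarray(expression.coords_mm)[keep],
        donor_ids=np.asarray(expression.donor_ids)[keep],
        matched_voxel_id=np.asarray(mask.voxel_ids)[nearest[keep]],
    )
    return matched, n_dropped


def scaled_robust_sigmoid(values: np.ndarray) -> np.ndarray:
    """Robust sigmoid (median / IQR-scaled), min-max rescaled to [0, 1].

    s(x) = 1 / (1 + exp(-(x - median) / (IQR / 1.35))); the 1.35 constant
    makes IQR/1.35 a normal-consistent spread estimate. Zero IQR (all-equal
    quartiles) falls back to a flat 0.5.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        return np.full_like(values, 0.5)
    s = 1.0 / (1.0 + np.exp(-(values - med) / (iqr / 1.35)))
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full_like(values, 0.5)
    return (s - lo) / (hi - lo)


def normalize_expression(
    expression: ExpressionMatrix, axis: str = "gene"
) -> ExpressionMatrix:
    """Scaled-robust-sigmoid normalization applied within each donor.

    ``axis='gene'`` (default) normalizes each gene across that donor's
    samples, making genes comparable across donors before pooling;
    ``axis='sample'`` normalizes each sample across genes instead.
    Normalization never mixes donors.
    """
    if axis not in ("gene", "sample"):
        raise ValueError("axis must be 'gene' or 'sample'")
    values = np.array(expression.values, dtype=float)
    for d in np.unique(expression.donor_ids):
        rows = np.nonzero(np.asarray(expression.donor_ids) == d)[0]
        block = values[rows]
        if axis == "gene":
            for j in range(block.shape[1]):
                block[:, j] = scaled_robust_sigmoid(block[:, j])
        else:
            for i in range(block.shape[0]):
                block[i] = scaled_robust_sigmoid(block[i])
        values[rows] = block
    return ExpressionMatrix(
        values=values,
        gene_ids=list(expression.gene_ids),
        coords_mm=expression.coords_mm,
        donor_ids=expression.donor_ids,
        matched_voxel_id=expression.matched_voxel_id,
    )


# ---------------------------------------------------------------------------
# partial least squares (NIPALS, univariate response)


@dataclass
class PLSModel:
    """A fitted univariate-response PLS regression.

    ``x_weights`` columns are the unit-norm NIPALS weight vectors w_k;
    ``ss`` holds the response variance captured by each component
    (q_k^2 * t_k't_k on the standardized scale). Training standardization
    parameters are stored so predictions use frozen statistics.
    """

    x_weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    ss: np.ndarray
    coef: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    n_components: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.n_components:
            self.n_components = self.x_weights.shape[1]


def fit_pls(
    x: np.ndarray, y: np.ndarray, n_components: int, standardize: bool = True
) -> PLSModel:
    """NIPALS partial least squares with a univariate response.

    With a single response the NIPALS inner loop is closed-form per
    component: w_k = X'y / ||X'y||, t_k = X w_k, followed by deflation of X
    and y. Predictor columns are z-scored on the training data by default
    (VIP is scale-sensitive); y is centred and scaled.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if len(y) != n:
        raise ValueError("X and y have different sample counts")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components = {n_components} exceeds min(samples - 1, genes) = "
            f"{min(n - 1, p)}"
        )
    if standardize:
        x_mean, x_sd = x.mean(axis=0), x.std(axis=0, ddof=0)
        x_sd = np.where(x_sd > 0, x_sd, 1.0)
    else:
        x_mean, x_sd = np.zeros(p), np.ones(p)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=0))
    if y_sd == 0:
        raise ValueError("response is constant; PLS is undefined")
    xc = (x - x_mean) / x_sd
    yc = (y - y_mean) / y_sd

    weights = np.empty((p, n_components))
    scores = np.empty((n, n_components))
    loadings = np.empty((p, n_components))
    q = np.empty(n_components)
    ss = np.empty(n_components)
    for k in range(n_components):
        w = xc.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"component {k + 1}: residual response orthogonal to X")
        w /= nw
        t = xc @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"component {k + 1}: degenerate score vector")
        pk = xc.T @ t / tt
        qk = float(yc @ t / tt)
        xc = xc - np.outer(t, pk)
        yc = yc - qk * t
        weights[:, k] = w
        scores[:, k] = t
        loadings[:, k] = pk
        q[k] = qk
        ss[k] = qk**2 * tt
    # coefficients on the standardized scale: B = W (P'W)^-1 q
    bw = np.linalg.solve(loadings.T @ weights, q)
    coef = weights @ bw
    return PLSModel(
        x_weights=weights,
        x_scores=scores,
        x_loadings=loadings,
        y_loadings=q,
        ss=ss,
        coef=coef,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def predict_pls(model: PLSModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    xc = (x - model.x_mean) / model.x_sd
    return model.y_mean + model.y_sd * (xc @ model.coef)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def cv_pls_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    components: tuple[int, ...] = tuple(range(2, 11)),
    n_folds: int = 5,
    n_repeats: int = 5,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Repeated k-fold out-of-sample prediction accuracy per component count.

    For each repeat, out-of-fold predictions are pooled and correlated
    (Pearson) with the observed response; accuracies are averaged over
    repeats per component count, and the overall statistic is their mean
    over the component grid. Also reports the best component count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < n_folds:
        raise ValueError("need at least as many samples as folds")
    rng = np.random.default_rng(rng)
    components = tuple(int(c) for c in components)
    acc = np.zeros((n_repeats, len(components)))
    for rep in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        folds = list(kf.split(x))
        for tr, te in folds:
            if len(te) < 2 or len(tr) < 2:
                raise ValueError("a fold has fewer than 2 samples")
        preds = np.zeros((len(components), n))
        for tr, te in folds:
            for ci, c in enumerate(components):
                model = fit_pls(x[tr], y[tr], n_components=c)
                preds[ci, te] = predict_pls(model, x[te])
        for ci in range(len(components)):
            acc[rep, ci] = _pearson(preds[ci], y)
    per_component = {c: float(a) for c, a in zip(components, acc.mean(axis=0))}
    mean_r = float(np.mean(list(per_component.values())))
    best = max(per_component, key=per_component.get)
    return {"per_component_r": per_component, "mean_r": mean_r, "best_component": best}


def pls_significance(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    surrogates: np.ndarray | None = None,
    components: tuple[int, ...] = tuple(range(2, 11)),
    n_folds: int = 5,
    n_repeats: int = 5,
    rng: np.random.Generator | int | None = None,
    use_surrogates: bool = False,
) -> dict:
    """Permutation (and optional spatial-surrogate) test of PLS accuracy.

    The null recomputes the cross-validated mean accuracy with the response
    replaced by a permutation of itself, or by autocorrelation-preserving
    surrogate maps when provided. Add-one p-values.
    """
    if use_surrogates and surrogates is None:
        raise ValueError("surrogate maps requested but none provided")
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float).ravel()
    kwargs = dict(components=components, n_folds=n_folds, n_repeats=n_repeats)
    observed = cv_pls_accuracy(x, y, rng=rng, **kwargs)["mean_r"]

    def _null_accuracies(draw) -> np.ndarray:
        out = np.empty(n_perm)
        for j in range(n_perm):
            out[j] = cv_pls_accuracy(x, draw(j), rng=rng, **kwargs)["mean_r"]
        return out

    null_perm = _null_accuracies(lambda j: y[rng.permutation(len(y))])
    result = {
        "observed_r": observed,
        "p_perm": (1 + int(np.sum(null_perm >= observed))) / (1 + n_perm),
        "null_perm": null_perm,
    }
    if surrogates is not None:
        surrogates = np.asarray(surrogates, dtype=float)
        if surrogates.shape[1] != len(y):
            raise ValueError("surrogate maps must align with the response voxels")
        n_surr = min(n_perm, surrogates.shape[0])
        null_surr = np.empty(n_surr)
        for j in range(n_surr):
            null_surr[j] = cv_pls_accuracy(x, surrogates[j], rng=rng, **kwargs)["mean_r"]
        result["p_surrogate"] = (1 + int(np.sum(null_surr >= observed))) / (1 + n_surr)
        result["null_surrogate"] = null_surr
    return result


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in the projection for every predictor.

    VIP_j = sqrt(p * sum_k SS_k (w_jk / ||w_k||)^2 / sum_k SS_k); the mean
    squared VIP is 1 by construction (sum of VIP^2 equals p).
    """
    total = float(model.ss.sum())
    if total == 0:
        raise ValueError("model captured no response variance; VIP undefined")
    w2 = model.x_weights**2  # columns already unit norm
    p = model.x_weights.shape[0]
    return np.sqrt(p * (w2 @ model.ss) / total)


def bootstrap_vip_ranking(
    x: np.ndarray,
    y: np.ndarray,
    gene_ids: list[str],
    n_components: int = 6,
    n_boot: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Rank genes by bootstrap-stabilized VIP z-scores.

    Samples are resampled with replacement ``n_boot`` times; the PLS model is
    refit and VIP recorded each time. z = bootstrap-mean VIP / bootstrap SE,
    genes ranked by z descending (ties broken by gene id). Degenerate
    resamples (constant response) are redrawn.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(rng)
    n = len(y)
    vips = np.empty((n_boot, x.shape[1]))
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if np.ptp(y[idx]) > 0:
                break
        else:
            raise ValueError("could not draw a non-degenerate bootstrap resample")
        model = fit_pls(x[idx], y[idx], n_components=n_components)
        vips[b] = vip_scores(model)
    mean_vip = vips.mean(axis=0)
    se = vips.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mean_vip / se, np.inf)
    ranking = pd.DataFrame({"gene_id": gene_ids, "vip": mean_vip, "vip_se": se, "z": z})
    ranking = ranking.sort_values(["z", "gene_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking
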