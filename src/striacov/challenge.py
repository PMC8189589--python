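"""Within-subject drug-vs-placebo change analysis of mode-of-covariation scores.

If the canonical mode is functionally meaningful, a drug that shifts the
latent state should move a subject's ROI score and brain score together:
the drug-minus-placebo delta of the two scores should correlate across
paired subjects. Spearman correlations are used throughout so outliers do
not dominate. A placebo-trained variant refits the whole mode on placebo
scans only before scoring both sessions, removing circularity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cca import CCAMode, fit_mode, score_scans

__all__ = [
    "scores_frame",
    "delta_score_correlation",
    "placebo_trained_scores",
    "subjective_effect_correlation",
]


def scores_frame(
    mode: CCAMode,
    roi_matrix: np.ndarray,
    brain_matrix: np.ndarray,
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Per-scan canonical scores as a tidy frame aligned with the manifest."""
    scores = score_scans(mode, roi_matrix, brain_matrix)
    return pd.DataFrame(
        {
            "subject_id": manifest["subject_id"].to_numpy(),
            "condition": manifest["condition"].to_numpy(),
            "striatal_score": scores[:, 0],
            "cbf_score": scores[:, 1],
        }
    )


def delta_score_correlation(scores: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation of drug-minus-placebo deltas of the two scores.

    Only subjects with both conditions contribute a delta record. Ties are
    handled by average ranks; the p-value is two-sided.
    """
    deltas = []
    for sid, grp in scores.groupby("subject_id", sort=False):
        conditions = set(grp["condition"])
        if {"placebo", "drug"} <= conditions:
            drug = grp[grp["condition"] == "drug"].iloc[0]
            plac = grp[grp["condition"] == "placebo"].iloc[0]
            deltas.append(
                {
                    "subject_id": sid,
                    "d_striatal": drug["striatal_score"] - plac["striatal_score"],
                    "d_cbf": drug["cbf_score"] - plac["cbf_score"],
                }
            )
    records = pd.DataFrame(deltas)
    if len(records) < 3:
        raise ValueError("need at least 3 paired subjects for a delta correlation")
    rho, p = stats.spearmanr(records["d_striatal"], records["d_cbf"])
    return float(rho), float(p), records


def placebo_trained_scores(
    roi_matrix: np.ndarray,
    brain_matrix: np.ndarray,
    manifest: pd.DataFrame,
    k: int = 8,
) -> tuple[CCAMode, pd.DataFrame]:
    """Score every scan with a mode fit exclusively on placebo scans.

    Standardization, PCA and CCA are all estimated on placebo rows; both
    sessions are then scored with those frozen parameters, so drug scans
    never influence the model.
    """
    placebo_rows = np.nonzero((manifest["condition"] == "placebo").to_numpy())[0]
    if len(placebo_rows) < k + 1:
        raise ValueError(
            f"need more than K = {k} placebo scans, found {len(placebo_rows)}"
        )
    mode = fit_mode(roi_matrix, brain_matrix, k, fit_rows=placebo_rows)
    return mode, scores_frame(mode, roi_matrix, brain_matrix, manifest)


def subjective_effect_correlation(
    scores: pd.DataFrame,
    scale_totals: np.ndarray,
    subset: str = "all",
) -> tuple[float, float]:
    """Spearman correlation of mean canonical score vs subjective-scale total.

    The per-scan score is the mean of the striatal and brain scores;
    ``subset='drug_only'`` restricts to drug-condition scans. Degenerate
    (constant) inputs raise rather than returning NaN.
    """
    if subset not in ("all", "drug_only"):
        raise ValueError("subset must be 'all' or 'drug_only'")
    scale_totals = np.asarray(scale_totals, dtype=float)
    if len(scale_totals) != len(scores):
        raise ValueError("scale totals must align with scans")
    mean_score = (scores["striatal_score"] + scores["cbf_score"]).to_numpy() / 2.0
    keep = (
        np.ones(len(scores), dtype=bool)
        if subset == "all"
        else (scores["condition"] == "drug").to_numpy()
    )
    if not keep.any():
        raise ValueError(f"subset {subset!r} selects no scans")
    a, b = mean_score[keep], scale_totals[keep]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: an input is constant")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
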