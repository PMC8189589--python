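"""End-to-end orchestration: synthetic demo cohort through every analysis stage.

A single master seed spawns independent per-stage random streams, so each
stage is reproducible in isolation and the whole run is bit-identical for a
fixed configuration. Stage outputs are persisted under the output directory
as JSON / CSV / TSV / NPZ (+ NIfTI influence maps), and the result bundle is
stamped with the seed, a configuration hash and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .cca import (
    covariation_influence,
    cross_validated_mode_test,
    fit_mode,
    matching_accuracy_test,
)
from .challenge import (
    delta_score_correlation,
    placebo_trained_scores,
    scores_frame,
    subjective_effect_correlation,
)
from .enrichment import median_rank_test
from .expression import (
    bootstrap_vip_ranking,
    cv_pls_accuracy,
    filter_probes,
    match_samples_to_voxels,
    normalize_expression,
    pls_significance,
    select_probe_by_differential_stability,
)
from .map_prep import MaskedMap, make_relative_map
from .surrogates import generate_surrogates, network_overlap_test
from .synthetic import generate_study

__all__ = ["PipelineConfig", "run_full", "validate_manifest"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of the full synthetic-demo pipeline run."""

    seed: int = 0
    outdir: str = "striacov_results"
    # synthetic cohort (reduced demo scale)
    n_paired: int = 23
    n_unpaired: int = 5
    n_roi_vox: int = 500
    n_brain_vox: int = 2000
    planted_rho: float = 0.5
    drug_shift: float = 0.5
    voxel_noise_sd: float = 0.2
    n_genes: int = 500
    n_signal_genes: int = 50
    n_expression_samples: int = 153
    # mode test
    k_min: int = 2
    k_max: int = 10
    n_splits: int = 100
    train_frac: float = 0.8
    n_perm: int = 200
    scheme: str = "block"
    pair_preserving_split: bool = False
    full_sample_k: int = 8
    # matching test
    matching_rounds: int = 100
    matching_perms: int = 100
    # surrogates / overlap
    n_surrogates: int = 200
    n_networks: int = 7
    # gene PLS
    pls_components: tuple[int, ...] = tuple(range(2, 11))
    pls_folds: int = 5
    pls_repeats: int = 5
    pls_perms: int = 200
    vip_components: int = 6
    n_boot: int = 500
    enrichment_draws: int = 1000
    write_volumes: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pls_components" in raw:
            raw["pls_components"] = tuple(raw["pls_components"])
        return cls(**raw)

    def config_hash(self) -> str:
        # the output path is not part of the scientific configuration
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_manifest(path: str | Path) -> pd.DataFrame:
    """Parse and validate a scan manifest; raise with row context on errors."""
    manifest = io.read_manifest(path)
    dupes = manifest.duplicated(subset=["subject_id", "condition"], keep=False)
    if dupes.any():
        rows = manifest.loc[dupes].index.tolist()
        raise ValueError(f"duplicated (subject, condition) pairs in manifest rows {rows}")
    bad = ~manifest["condition"].isin(["placebo", "drug"])
    if bad.any():
        raise ValueError(
            f"unknown conditions: {sorted(manifest.loc[bad, 'condition'].unique())}"
        )
    base = Path(path).parent
    for col in ("roi_path", "brain_path"):
        if col in manifest.columns:
            for p in manifest[col]:
                if not (base / p).exists():
                    raise ValueError(f"manifest references a missing file: {p}")
    return manifest


def _relative(matrix: np.ndarray, mask) -> np.ndarray:
    rows = [make_relative_map(MaskedMap(row, mask)).values for row in matrix]
    return np.vstack(rows)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_full(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort and persist all artifacts.

    Returns the result bundle (also written to ``results.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    streams = master.spawn(8)
    results: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        }
    }

    logger.info("stage 1: synthetic cohort")
    cohort, truth = generate_study(
        seed=streams[0],
        n_paired=config.n_paired,
        n_unpaired=config.n_unpaired,
        n_roi_vox=config.n_roi_vox,
        n_brain_vox=config.n_brain_vox,
        planted_rho=config.planted_rho,
        drug_shift=config.drug_shift,
        voxel_noise_sd=config.voxel_noise_sd,
        expression_kwargs={
            "n_genes": config.n_genes,
            "n_signal": config.n_signal_genes,
            "n_samples": config.n_expression_samples,
        },
        n_networks=config.n_networks,
    )
    manifest = io.write_cohort(cohort, outdir / "cohort", config.write_volumes)
    n_scans = len(manifest)
    logger.info("scans: %d, roi voxels: %d, brain voxels: %d",
                n_scans, config.n_roi_vox, config.n_brain_vox)

    logger.info("stage 2: relative maps")
    roi_rel = _relative(cohort.roi_maps, cohort.roi_mask)
    brain_rel = _relative(cohort.brain_maps, cohort.brain_mask)
    io.save_matrix(outdir / "roi_relative.npz", roi_rel, cohort.roi_mask, manifest)
    io.save_matrix(outdir / "brain_relative.npz", brain_rel, cohort.brain_mask, manifest)

    logger.info("stage 3: cross-validated mode test")
    k_values = tuple(range(config.k_min, config.k_max + 1))
    mode_test = cross_validated_mode_test(
        roi_rel,
        brain_rel,
        manifest,
        k_values=k_values,
        n_splits=config.n_splits,
        train_frac=config.train_frac,
        n_perm=config.n_perm,
        scheme=config.scheme,
        pair_preserving_split=config.pair_preserving_split,
        rng=streams[1],
    )
    results["mode_test"] = {
        "mean_oos_r": mode_test.mean_oos_r,
        "p_value": mode_test.p_value,
        "per_k_r": mode_test.per_k_r,
    }

    logger.info("stage 4: full-sample mode and influence maps")
    mode = fit_mode(roi_rel, brain_rel, config.full_sample_k)
    roi_infl = covariation_influence(roi_rel, mode.variates[:, 0], cohort.roi_mask)
    brain_infl = covariation_influence(brain_rel, mode.variates[:, 1], cohort.brain_mask)
    io.write_influence_csv(roi_infl.values, cohort.roi_mask, outdir / "roi_influence.csv")
    io.write_influence_csv(
        brain_infl.values, cohort.brain_mask, outdir / "brain_influence.csv"
    )
    io.write_masked_nifti(roi_infl.values, cohort.roi_mask, outdir / "roi_influence.nii.gz")
    io.write_masked_nifti(
        brain_infl.values, cohort.brain_mask, outdir / "brain_influence.nii.gz"
    )
    recovery = float(np.corrcoef(roi_infl.values, truth.striatal_loading)[0, 1])
    results["influence"] = {
        "in_sample_canonical_r": mode.canonical_r,
        "roi_loading_recovery_r": abs(recovery),
    }

    logger.info("stage 5: matching accuracy test")
    accuracy, null_mean, null_sd, match_p = matching_accuracy_test(
        roi_rel,
        brain_rel,
        manifest,
        k=config.full_sample_k,
        n_rounds=config.matching_rounds,
        n_perm=config.matching_perms,
        scheme=config.scheme,
        rng=streams[2],
    )
    results["matching"] = {
        "accuracy": accuracy,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "p_value": match_p,
    }

    logger.info("stage 6: pharmacological challenge")
    scores = scores_frame(mode, roi_rel, brain_rel, manifest)
    scores.to_csv(outdir / "cca_scores.csv", index=False)
    rho, p_delta, deltas = delta_score_correlation(scores)
    deltas.to_csv(outdir / "delta_scores.csv", index=False)
    _, placebo_scores = placebo_trained_scores(
        roi_rel, brain_rel, manifest, k=config.full_sample_k
    )
    rho_pl, p_pl, _ = delta_score_correlation(placebo_scores)
    totals = cohort.subjective_scale.sum(axis=1)
    rho_subj, p_subj = subjective_effect_correlation(scores, totals, "all")
    rho_subj_drug, p_subj_drug = subjective_effect_correlation(scores, totals, "drug_only")
    results["challenge"] = {
        "delta_spearman_rho": rho,
        "delta_p": p_delta,
        "delta_spearman_rho_placebo_trained": rho_pl,
        "delta_p_placebo_trained": p_pl,
        "subjective_rho_all": rho_subj,
        "subjective_p_all": p_subj,
        "subjective_rho_drug": rho_subj_drug,
        "subjective_p_drug": p_subj_drug,
    }

    logger.info("stage 7: surrogate maps and network overlap")
    brain_surr = generate_surrogates(
        brain_infl.values,
        cohort.brain_coords,
        n_surrogates=config.n_surrogates,
        rng=streams[3],
    )
    overlap = network_overlap_test(brain_infl.values, cohort.parcellation, brain_surr)
    pd.DataFrame(overlap).to_csv(outdir / "network_overlap.csv", index=False)
    results["network_overlap"] = overlap

    logger.info("stage 8: expression preparation and gene PLS")
    probes = filter_probes(cohort.probe_table)
    n_probes_kept = len(probes.probes)
    expr = select_probe_by_differential_stability(probes)
    matched, n_dropped = match_samples_to_voxels(expr, cohort.roi_mask)
    matched = normalize_expression(matched)
    io.write_expression_tsv(matched, outdir / "expression_normalized.tsv")
    voxel_index = {v: i for i, v in enumerate(cohort.roi_mask.voxel_ids)}
    sample_vox = np.array([voxel_index[v] for v in matched.matched_voxel_id])
    y = roi_infl.values[sample_vox]
    x = matched.values
    cv = cv_pls_accuracy(
        x,
        y,
        components=config.pls_components,
        n_folds=config.pls_folds,
        n_repeats=config.pls_repeats,
        rng=streams[4],
    )
    roi_surr = generate_surrogates(
        roi_infl.values,
        cohort.roi_coords,
        n_surrogates=config.pls_perms,
        rng=streams[5],
    )
    signif = pls_significance(
        x,
        y,
        n_perm=config.pls_perms,
        surrogates=roi_surr.maps[:, sample_vox],
        components=config.pls_components,
        n_folds=config.pls_folds,
        n_repeats=config.pls_repeats,
        rng=streams[6],
    )
    ranking = bootstrap_vip_ranking(
        x,
        y,
        matched.gene_ids,
        n_components=config.vip_components,
        n_boot=config.n_boot,
        rng=streams[7],
    )
    ranking.to_csv(outdir / "gene_ranking.tsv", sep="\t", index=False)
    # ranked lists for external GO tools, in both orders
    ranking[["gene_id", "z"]].to_csv(
        outdir / "gene_list_descending.tsv", sep="\t", index=False, header=False
    )
    ranking[["gene_id", "z"]].iloc[::-1].to_csv(
        outdir / "gene_list_ascending.tsv", sep="\t", index=False, header=False
    )
    signal_set = set(truth.signal_genes)
    top_decile = set(ranking.head(max(1, len(ranking) // 10))["gene_id"])
    results["gene_pls"] = {
        "n_probes_kept": n_probes_kept,
        "n_samples_matched": int(matched.n_samples),
        "n_samples_dropped": int(n_dropped),
        "cv_mean_r": cv["mean_r"],
        "best_component": cv["best_component"],
        "p_perm": signif["p_perm"],
        "p_surrogate": signif.get("p_surrogate"),
        "signal_gene_top_decile_frac": len(signal_set & top_decile) / len(signal_set),
    }

    logger.info("stage 9: gene-set enrichment")
    enrich_rng = np.random.default_rng(master.spawn(1)[0])
    enrichment = []
    for gene_set in cohort.gene_sets:
        res = median_rank_test(
            ranking, gene_set, n_random=config.enrichment_draws, rng=enrich_rng
        )
        enrichment.append(
            {
                "set_name": res.set_name,
                "n_in_list": res.n_in_list,
                "median_rank": res.observed_median_rank,
                "center_distance": res.center_distance,
                "p": res.p,
            }
        )
    pd.DataFrame(enrichment).to_csv(outdir / "enrichment.csv", index=False)
    results["enrichment"] = enrichment
    results["truth"] = {
        "planted_rho": truth.planted_rho,
        "drug_shift": truth.drug_shift,
        "n_signal_genes": len(truth.signal_genes),
        "enriched_sets": truth.enriched_sets,
    }

    (outdir / "results.json").write_text(json.dumps(_jsonable(results), indent=2))
    return results
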