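"""Median-rank gene-set enrichment against random-set nulls.

Given a gene list ranked by association strength (bootstrap VIP z-scores),
the test asks whether a disease gene set sits unusually far from the centre
of the list: the statistic is |median rank of set members - (n+1)/2|,
compared with the same statistic for random same-size gene draws from the
list. Distance from the centre is symmetric, so enrichment at either end of
the list is detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "subset_to_expressed",
    "median_rank_test",
]


@dataclass
class GeneSet:
    """A named gene set, optionally tagged with a direction (e.g. up/down)."""

    name: str
    genes: tuple[str, ...]
    direction: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name} has duplicate members")


@dataclass
class EnrichmentResult:
    set_name: str
    n_in_list: int
    observed_median_rank: float
    center_distance: float
    null_distances: np.ndarray
    p: float


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members per line)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, description, genes = fields[0], fields[1], fields[2:]
        sets.append(GeneSet(name=name, genes=tuple(genes), direction=description))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.direction or "na", *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def subset_to_expressed(ranking: pd.DataFrame, expressed_genes: set[str]) -> pd.DataFrame:
    """Restrict a ranked gene list to expressed genes, recomputing ranks 1..n."""
    if not expressed_genes:
        raise ValueError("expressed_genes is empty")
    out = ranking[ranking["gene_id"].isin(expressed_genes)].reset_index(drop=True)
    if out.empty:
        raise ValueError("no ranked gene is in the expressed set")
    out = out.copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def median_rank_test(
    ranking: pd.DataFrame,
    gene_set: GeneSet,
    n_random: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> EnrichmentResult:
    """Test whether a set's median rank is far from the list centre.

    The null draws ``n_random`` random gene sets of the same size from the
    ranked list (without replacement within a draw) and records the same
    centre distance; p is the add-one fraction of null distances >= the
    observed one. Members absent from the list are ignored (their count is
    reflected in ``n_in_list``). Median uses the midpoint convention.
    """
    rng = np.random.default_rng(rng)
    n = len(ranking)
    ranks = ranking.loc[ranking["gene_id"].isin(gene_set.genes), "rank"].to_numpy()
    if ranks.size == 0:
        raise ValueError(f"no member of gene set {gene_set.name!r} is in the ranked list")
    center = (n + 1) / 2.0
    observed_median = float(np.median(ranks))
    observed = abs(observed_median - center)
    all_ranks = ranking["rank"].to_numpy()
    null = np.empty(n_random)
    for j in range(n_random):
        draw = rng.choice(all_ranks, size=ranks.size, replace=False)
        null[j] = abs(float(np.median(draw)) - center)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_random)
    return EnrichmentResult(
        set_name=gene_set.name,
        n_in_list=int(ranks.size),
        observed_median_rank=observed_median,
        center_distance=observed,
        null_distances=null,
        p=p,
    )
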