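"""CNVR -> gene mapping and hypergeometric gene-set over-representation.

Genes (already reduced to one longest-transcript interval each) are mapped
to CNVRs by any-base overlap of half-open intervals. Over-representation of
a gene set with K members in a background of N genes, given a query of n
genes with k hits, is the hypergeometric upper tail P(X >= k); Bonferroni
correction is applied within each gene-set category by default (so each
category's table is corrected for its own number of tests), with a global
option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .io_formats import GeneModel, GeneSetCollection

logger = logging.getLogger(__name__)


def map_cnvr_to_genes(
    regions: list[tuple[str, int, int]],
    genes: list[GeneModel],
) -> set[str]:
    """Gene ids whose interval shares >= 1 base with >= 1 region.

    Regions are (chrom, start, end), half-open. A chromosome that appears in
    the regions but not in the annotation draws a warning, not an error
    (sparse annotations are common); each gene is reported once however many
    regions it overlaps.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    hit: set[str] = set()
    unannotated: set[str] = set()
    for chrom, start, end in regions:
        tree = trees.get(chrom)
        if tree is None:
            unannotated.add(chrom)
            continue
        for iv in tree.overlap(start, end):
            hit.add(iv.data)
    if unannotated:
        warnings.warn(
            f"regions on chromosomes absent from the annotation: "
            f"{sorted(unannotated)}",
            stacklevel=2,
        )
    return hit


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # one row per tested set, sorted by raw_p
    alpha: float
    background_size: int
    query_size: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["bonferroni_p"] <= self.alpha]


def hypergeom_enrich(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    alpha: float = 0.05,
    per_category: bool = True,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation with Bonferroni.

    Each gene set is intersected with the background before testing; sets
    left empty are skipped (logged). ``raw_p = P(X >= k)`` for
    X ~ Hypergeometric(N=len(background), K=set size in background,
    n=len(query)). ``bonferroni_p = min(1, m * raw_p)`` where m counts the
    sets tested in the same category (or all sets when
    ``per_category=False``).
    """
    if not query:
        raise ValueError("query gene set is empty")
    stray = query - background
    if stray:
        raise ValueError(
            f"query genes outside the background universe: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        in_bg = members & background
        if not in_bg:
            logger.info("gene set %s has no background members; skipped", name)
            continue
        K = len(in_bg)
        hits = sorted(in_bg & query)
        k = len(hits)
        raw_p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append(
            {
                "set": name,
                "category": collection.categories[name],
                "hit_count_query": k,
                "hit_count_genome": K,
                "raw_p": min(raw_p, 1.0),
                "hit_genes": ",".join(hits),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        if per_category:
            m = table.groupby("category")["set"].transform("size")
        else:
            m = len(table)
        table["bonferroni_p"] = (table["raw_p"] * m).clip(upper=1.0)
        table = table.sort_values(
            ["raw_p", "set"], kind="mergesort"
        ).reset_index(drop=True)
        table["significant"] = table["bonferroni_p"] <= alpha
    return EnrichmentResult(
        table=table, alpha=alpha, background_size=N, query_size=n
    )
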