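"""QTL co-localization of upregulated TFs and Fisher-exact enrichment.

A gene is QTL-associated when its genomic interval shares at least one base
pair with a QTL confidence interval on the same chromosome (a gene spanning
two QTL yields two association records).  Enrichment of a gene subset
(e.g. chilling-upregulated TFs) is a one-sided "greater" Fisher exact test
on the 2x2 table subset/rest x QTL-associated/not, significant at the
deliberately permissive p < 0.25 used for candidate screening; the enriched
flag additionally requires the subset ratio to exceed the genome-wide
ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

__all__ = [
    "QTLInterval",
    "FisherResult",
    "colocalize_genes",
    "fisher_enrichment",
    "fisher_pvalue",
]


def fisher_pvalue(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    _odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


@dataclass(frozen=True)
class QTLInterval:
    trait: str
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if not self.trait:
            raise ValueError("trait symbol must be nonempty")
        if not self.start < self.end:
            raise ValueError(f"QTL {self.trait}: need start < end")


def colocalize_genes(genes: pd.DataFrame, qtl: pd.DataFrame) -> pd.DataFrame:
    """Overlap gene intervals with QTL intervals (0-based half-open).

    ``genes`` needs columns gene_id, chrom, start, end; ``qtl`` needs
    trait, chrom, start, end.  Returns one row per (gene, QTL) overlap with
    columns gene_id, trait, qtl_chrom, qtl_start, qtl_end.  Genes on
    chromosomes absent from the QTL table simply have no associations;
    malformed records raise a warning and are skipped.
    """
    trees: dict = {}
    for row in qtl.itertuples(index=False):
        QTLInterval(row.trait, str(row.chrom), int(row.start), int(row.end))
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end), row.trait
        )
    qtl_chroms = set(trees)
    known_chroms = qtl_chroms | set(genes["chrom"].astype(str))
    rows = []
    for g in genes.itertuples(index=False):
        chrom = str(g.chrom)
        if chrom not in known_chroms:
            warnings.warn(f"gene {g.gene_id}: unknown chromosome {chrom}", stacklevel=2)
            continue
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(g.start), int(g.end))):
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "trait": hit.data,
                    "qtl_chrom": chrom,
                    "qtl_start": hit.begin,
                    "qtl_end": hit.end,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "trait", "qtl_chrom", "qtl_start", "qtl_end"]
    )


@dataclass(frozen=True)
class FisherResult:
    table: tuple  # ((subset_assoc, subset_non), (rest_assoc, rest_non))
    subset_ratio: float
    genome_ratio: float
    p_value: float
    enriched: bool
    trait: str | None = None


def fisher_enrichment(
    subset,
    universe,
    associations: pd.DataFrame,
    alpha: float = 0.25,
    trait: str | None = None,
) -> FisherResult:
    """One-sided (greater) Fisher exact test for QTL over-representation.

    ``trait=None`` pools all traits; otherwise only that trait's
    associations count.  ``enriched`` requires both subset_ratio >
    genome_ratio (computed over the full universe) and p < alpha.
    """
    subset = frozenset(subset)
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    if not subset <= universe:
        raise ValueError("subset must be contained in the universe")
    assoc = associations
    if trait is not None:
        assoc = assoc[assoc["trait"] == trait]
    assoc_genes = frozenset(assoc["gene_id"]) & universe
    a = len(subset & assoc_genes)
    b = len(subset) - a
    rest = universe - subset
    c = len(rest & assoc_genes)
    d = len(rest) - c
    subset_ratio = a / len(subset) if subset else 0.0
    genome_ratio = len(assoc_genes) / len(universe)
    p = fisher_pvalue(a, b, c, d)
    return FisherResult(
        table=((a, b), (c, d)),
        subset_ratio=subset_ratio,
        genome_ratio=genome_ratio,
        p_value=float(p),
        enriched=bool(subset_ratio > genome_ratio and p < alpha),
        trait=trait,
    )
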