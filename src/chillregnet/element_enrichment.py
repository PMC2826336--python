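"""Cis-element class assignment and per-cluster class enrichment scores.

Discovered motif consensi are matched against a catalog of known plant
cis-element classes (as1/ocs/TGA, ABRE, DRE/CRT, rav1, GCC-box, JAre,
MYB2-box, GARE, pyrimidine box, W-box, MYC2-box) by ungapped IUPAC-aware
alignment on both strands.  Fine element classes are pooled into the broad
scoring categories used for graphing (e.g. DRE/CRT-like and rav1-like pool
into "DRE/CRT/rav1-like"); a cluster's *total enrichment score* for a
category is the sum of occurrence percentages of all motif species of that
category occurring in at least 50% of the cluster's promoters.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from chillregnet.motif_discovery import MotifModel, iupac_to_set, reverse_complement

__all__ = [
    "CatalogEntry",
    "ElementCatalog",
    "ClassEnrichment",
    "MatchResult",
    "load_default_catalog",
    "load_reported_motif_table",
    "match_element_class",
    "class_scores",
    "dominant_classes",
    "iupac_similarity",
    "BROAD_CATEGORY_POOLING",
]

# fine element class -> broad scoring category (figure-style pooling; the
# MYB2 category pools all R2R3-MYB target species)
BROAD_CATEGORY_POOLING = {
    "as1/ocs/TGA-like": "as1/ocs/TGA-like",
    "ABRE-like": "ABRE-like",
    "DRE/CRT-like": "DRE/CRT/rav1-like",
    "rav1-like": "DRE/CRT/rav1-like",
    "rav1b element-like": "DRE/CRT/rav1-like",
    "GCC-box-like": "GCC-box/JAre-like",
    "JAre-like": "GCC-box/JAre-like",
    "JA response element-like": "GCC-box/JAre-like",
    "MYB2-box-like": "MYB2-box-like",
    "MYB1-box-like": "MYB2-box-like",
    "MCB1/MCB2-like": "MYB2-box-like",
    "GARE-like": "GARE/pyrimidine-box-like",
    "GA response element-like": "GARE/pyrimidine-box-like",
    "pyrimidine-box-like": "GARE/pyrimidine-box-like",
    "Pyrimidine box-like": "GARE/pyrimidine-box-like",
    "W-box-like": "W-box-like",
    "MYC2-box-like": "MYC2-box-like",
}


def pool_category(element_class: str) -> str:
    return BROAD_CATEGORY_POOLING.get(element_class, element_class)


@dataclass(frozen=True)
class CatalogEntry:
    element_class: str
    broad_category: str
    pattern: str
    tf_family: str
    source: str = ""

    def __post_init__(self) -> None:
        for sym in self.pattern:
            iupac_to_set(sym)  # raises on invalid IUPAC


@dataclass
class ElementCatalog:
    entries: list

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("catalog must not be empty")
        fam = {}
        for e in self.entries:
            if fam.setdefault(e.element_class, e.tf_family) != e.tf_family:
                raise ValueError(
                    f"element class {e.element_class!r} maps to several TF families"
                )

    @classmethod
    def from_tsv(cls, path) -> "ElementCatalog":
        df = pd.read_csv(path, sep="\t")
        entries = [
            CatalogEntry(
                element_class=r.element_class,
                broad_category=r.broad_category,
                pattern=str(r.iupac_pattern).upper(),
                tf_family=r.tf_family,
                source=getattr(r, "source", ""),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(entries)

    def classes(self) -> list:
        seen = []
        for e in self.entries:
            if e.element_class not in seen:
                seen.append(e.element_class)
        return seen


def load_default_catalog() -> ElementCatalog:
    with resources.as_file(
        resources.files("chillregnet.data") / "cis_element_catalog.tsv"
    ) as p:
        return ElementCatalog.from_tsv(p)


def load_reported_motif_table() -> pd.DataFrame:
    """Packaged table of published per-cluster motif occurrences (reference
    fixture for score computations; columns cluster, motif, element_class,
    tf_class, occurrence_pct, tic, e_value)."""
    with resources.as_file(
        resources.files("chillregnet.data") / "reported_cluster_motifs.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t")


def iupac_similarity(a: str, b: str) -> float:
    """Best ungapped both-strand compatibility fraction over the shorter
    string.  The shorter string slides fully inside the longer; a position
    is compatible when the IUPAC base sets intersect."""
    a, b = a.upper(), b.upper()
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0.0
    for cand in (short, reverse_complement(short)):
        sets = [iupac_to_set(s) for s in cand]
        for off in range(len(long_) - len(cand) + 1):
            hits = sum(
                1
                for j, s in enumerate(sets)
                if s & iupac_to_set(long_[off + j])
            )
            best = max(best, hits / len(cand))
    return best


@dataclass(frozen=True)
class MatchResult:
    element_class: str
    broad_category: str
    tf_family: str
    similarity: float
    secondary_class: str | None = None  # dual report for W-box/as1-type ambiguity


def match_element_class(
    motif, catalog: ElementCatalog, min_similarity: float = 0.75
) -> MatchResult:
    """Assign a motif (or raw consensus string) to its best catalog class.

    Ties break by higher compatibility, then catalog order.  Returns class
    "unassigned" when nothing reaches ``min_similarity``; when two distinct
    classes both match, the runner-up is dual-reported in
    ``secondary_class``.
    """
    consensus = motif.consensus if isinstance(motif, MotifModel) else str(motif)
    scored = []
    for order, entry in enumerate(catalog.entries):
        sim = iupac_similarity(consensus, entry.pattern)
        scored.append((-sim, order, entry, sim))
    scored.sort(key=lambda t: (t[0], t[1]))
    best = scored[0]
    if best[3] < min_similarity:
        return MatchResult("unassigned", "unassigned", "unassigned", best[3])
    entry = best[2]
    secondary = None
    for _negsim, _order, other, sim in scored[1:]:
        if other.element_class != entry.element_class and sim >= min_similarity:
            secondary = other.element_class
            break
    result = MatchResult(
        entry.element_class, entry.broad_category, entry.tf_family, best[3], secondary
    )
    if isinstance(motif, MotifModel):
        motif.element_class = result.element_class
        motif.broad_category = result.broad_category
        motif.tf_family = result.tf_family
        motif.secondary_class = result.secondary_class
    return result


@dataclass(frozen=True)
class ClassEnrichment:
    cluster: str
    broad_category: str
    tf_family: str
    total_score: float
    n_motif_species: int
    motifs: tuple  # consensus strings of contributing species

    def __post_init__(self) -> None:
        if self.n_motif_species < 1:
            raise ValueError("an enrichment needs at least one motif species")


def class_scores(
    cluster: str,
    motifs,
    min_occurrence: float = 50.0,
) -> list:
    """Total enrichment score per broad category for one cluster.

    ``motifs`` is an iterable of objects or mappings carrying
    ``broad_category``/``tf_family``/``occurrence_pct`` (and optionally
    ``consensus``).  Per category the score sums occurrence percentages of
    the motifs at or above ``min_occurrence``; categories with no
    qualifying motif are omitted; output sorted by score descending.
    """
    per_cat: dict = {}
    for m in motifs:
        if isinstance(m, dict):
            cat = m.get("broad_category")
            fam = m.get("tf_family", "")
            occ = m["occurrence_pct"]
            cons = m.get("consensus", "")
        else:
            cat = m.broad_category
            fam = m.tf_family or ""
            occ = m.occurrence_pct
            cons = m.consensus
        if cat in (None, "unassigned") or occ < min_occurrence:
            continue
        entry = per_cat.setdefault(cat, {"fam": fam, "occ": [], "cons": []})
        entry["occ"].append(float(occ))
        entry["cons"].append(cons)
    out = [
        ClassEnrichment(
            cluster=cluster,
            broad_category=cat,
            tf_family=v["fam"],
            total_score=sum(v["occ"]),
            n_motif_species=len(v["occ"]),
            motifs=tuple(v["cons"]),
        )
        for cat, v in per_cat.items()
    ]
    out.sort(key=lambda e: (-e.total_score, -e.n_motif_species, e.broad_category))
    return out


def dominant_classes(enrichments, top: int = 3) -> list:
    """Broad categories ranked by total score (ties: more species, then
    name); the first ``top`` define primary/secondary/tertiary regulators."""
    ranked = sorted(
        enrichments,
        key=lambda e: (-e.total_score, -e.n_motif_species, e.broad_category),
    )
    return [e.broad_category for e in ranked[:top]]


def reported_class_scores(min_occurrence: float = 50.0) -> pd.DataFrame:
    """Class scores recomputed from the packaged published motif table."""
    table = load_reported_motif_table()
    rows = []
    for cluster, grp in table.groupby("cluster"):
        motifs = [
            {
                "broad_category": pool_category(r.element_class),
                "tf_family": r.tf_class,
                "occurrence_pct": r.occurrence_pct,
                "consensus": r.motif,
            }
            for r in grp.itertuples(index=False)
        ]
        for enr in class_scores(cluster, motifs, min_occurrence):
            rows.append(
                {
                    "cluster": cluster,
                    "broad_category": enr.broad_category,
                    "total_score": enr.total_score,
                    "n_motif_species": enr.n_motif_species,
                }
            )
    return pd.DataFrame(rows)
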