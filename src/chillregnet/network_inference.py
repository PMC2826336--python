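"""Cluster <-> TF-class regulatory edges with rank and mediation labels.

An edge from a TF class (broad cis-element category + TF family) to a
co-expression cluster requires (a) the category to be enriched in the
cluster's promoters and (b) at least one upregulated TF of that family
whose induction phase precedes or coincides with the cluster's phase.  The
top three candidates by total enrichment score are ranked
primary/secondary/tertiary; a cluster's oxidative-mediation label follows
its H2O2-responsive member fraction (>= 50% oxidative, 25-50% mixed,
< 25% independent).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

from chillregnet.element_enrichment import dominant_classes

__all__ = [
    "NetworkEdge",
    "infer_edges",
    "classify_mediation",
    "export_network",
    "load_network",
    "FAMILY_ALIASES",
]

RANKS = ("primary", "secondary", "tertiary")

# fine catalog family -> gene-annotation family
FAMILY_ALIASES = {
    "R2R3-MYB": "MYB",
    "R1-MYB": "MYB",
    "ERF": "AP2/ERF",
    "AP2/ERF": "AP2/ERF",
    "bZIP": "bZIP",
    "WRKY": "WRKY",
    "bHLH": "bHLH",
    "NAC": "NAC",
}


@dataclass
class NetworkEdge:
    source_class: str  # broad cis-element category
    tf_family: str
    target_cluster: str
    rank: str | None  # primary/secondary/tertiary or None (unranked)
    total_score: float
    supporting_tfs: tuple = ()
    mediation: str = "independent"
    no_regulator: bool = False


def classify_mediation(h2o2_fraction: float) -> str:
    """Oxidative-mediation label from the H2O2-responsive member fraction
    (a proportion in [0, 1]; bounds inclusive on the left)."""
    if h2o2_fraction >= 0.50:
        return "oxidative"
    if h2o2_fraction >= 0.25:
        return "mixed"
    return "independent"


def infer_edges(clusters, enrichments, tf_calls, tf_families) -> list:
    """Build the ranked edge list.

    Parameters
    ----------
    clusters
        Iterable of ExpressionCluster-like objects (cluster_id, phase,
        h2o2_fraction).
    enrichments
        Mapping cluster_id -> list of ClassEnrichment for that cluster.
    tf_calls
        Up-regulation calls (status="up", with phase) for TF genes.
    tf_families
        Mapping TF gene id -> annotation family (bZIP, AP2/ERF, MYB, WRKY,
        bHLH, NAC).
    """
    tf_phase_by_family: dict = {}
    for call in tf_calls:
        fam = tf_families.get(call.gene)
        if fam is None or call.phase is None:
            continue
        tf_phase_by_family.setdefault(fam, []).append((call.gene, call.phase))

    edges = []
    for cluster in clusters:
        if cluster.phase is None:
            warnings.warn(
                f"cluster {cluster.cluster_id} has no phase; skipped", stacklevel=2
            )
            continue
        cluster_enr = enrichments.get(cluster.cluster_id, [])
        mediation = classify_mediation(cluster.h2o2_fraction)
        candidates = []
        for enr in cluster_enr:
            fam = FAMILY_ALIASES.get(enr.tf_family, enr.tf_family)
            support = tuple(
                g
                for g, ph in sorted(tf_phase_by_family.get(fam, []))
                if ph <= cluster.phase
            )
            if not support:
                continue  # temporal precedence/coincidence violated
            candidates.append((enr, fam, support))
        if not candidates:
            edges.append(
                NetworkEdge(
                    source_class="none",
                    tf_family="none",
                    target_cluster=cluster.cluster_id,
                    rank=None,
                    total_score=0.0,
                    mediation=mediation,
                    no_regulator=True,
                )
            )
            continue
        order = dominant_classes([c[0] for c in candidates], top=len(candidates))
        by_cat = {c[0].broad_category: c for c in candidates}
        for i, cat in enumerate(order):
            enr, fam, support = by_cat[cat]
            edges.append(
                NetworkEdge(
                    source_class=cat,
                    tf_family=fam,
                    target_cluster=cluster.cluster_id,
                    rank=RANKS[i] if i < len(RANKS) else None,
                    total_score=enr.total_score,
                    supporting_tfs=support,
                    mediation=mediation,
                )
            )
    return edges


def _edge_dict(e: NetworkEdge) -> dict:
    return {
        "source_class": e.source_class,
        "tf_family": e.tf_family,
        "target_cluster": e.target_cluster,
        "rank": e.rank,
        "total_score": e.total_score,
        "supporting_tfs": list(e.supporting_tfs),
        "mediation": e.mediation,
        "no_regulator": e.no_regulator,
    }


def export_network(edges, fmt: str = "json", path=None):
    """Serialize edges as a JSON edge list or GraphML.

    With ``path=None`` the serialized document is returned as a string.
    """
    if fmt == "json":
        doc = json.dumps({"edges": [_edge_dict(e) for e in edges]}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
            return None
        return doc
    if fmt == "graphml":
        import io

        import networkx as nx

        g = nx.MultiDiGraph()
        for e in edges:
            if e.no_regulator:
                g.add_node(e.target_cluster, no_regulator=True)
                continue
            src = f"{e.source_class}|{e.tf_family}"
            g.add_edge(
                src,
                e.target_cluster,
                rank=e.rank or "unranked",
                total_score=e.total_score,
                mediation=e.mediation,
            )
        if path is not None:
            nx.write_graphml(g, path)
            return None
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()
    raise ValueError(f"unknown format {fmt!r}")


def load_network(source) -> list:
    """Inverse of :func:`export_network` for the JSON edge list."""
    if hasattr(source, "read"):
        doc = json.load(source)
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    return [
        NetworkEdge(
            source_class=d["source_class"],
            tf_family=d["tf_family"],
            target_cluster=d["target_cluster"],
            rank=d["rank"],
            total_score=d["total_score"],
            supporting_tfs=tuple(d["supporting_tfs"]),
            mediation=d["mediation"],
            no_regulator=d["no_regulator"],
        )
        for d in doc["edges"]
    ]
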