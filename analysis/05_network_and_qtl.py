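"""Regulatory-network edges and QTL co-localization from the pipeline
report, plus recovery of the planted regulator classes.

Reads results/report/ (written by 04) and results/bundle/truth.json,
summarizes the primary/secondary/tertiary edges and mediation labels, and
prints the Fisher-exact QTL enrichment of upregulated TFs.
"""

import json
from pathlib import Path

import pandas as pd

from chillregnet.network_inference import load_network

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    edges = load_network(ROOT / "report" / "network.json")
    truth = json.loads((ROOT / "bundle" / "truth.json").read_text())
    membership = pd.read_csv(ROOT / "report" / "cluster_membership.tsv", sep="\t")

    primary = {e.target_cluster: e for e in edges if e.rank == "primary"}
    gene_cluster = truth["gene_cluster"]
    planted = truth["cluster_elements"]
    hits = n_eval = 0
    for cid, grp in membership.groupby("cluster"):
        labels = [gene_cluster.get(g) for g in grp["gene"] if g in gene_cluster]
        if not labels:
            continue
        majority = max(set(labels), key=labels.count)
        if majority not in planted:
            continue
        n_eval += 1
        edge = primary.get(cid)
        hits += bool(edge and edge.source_class == planted[majority])
    print(f"primary-edge recovery: {hits}/{n_eval} clusters "
          f"({100 * hits / max(n_eval, 1):.0f}%)")

    med = pd.Series([e.mediation for e in primary.values()]).value_counts()
    print("mediation of primary edges:", dict(med))

    qtl = pd.read_csv(ROOT / "report" / "qtl_enrichment.tsv", sep="\t")
    row = qtl.iloc[0]
    print(f"QTL enrichment of upregulated TFs: subset ratio "
          f"{row['subset_ratio']:.3f} vs genome {row['genome_ratio']:.3f}, "
          f"p = {row['p_value']:.3g}, enriched = {bool(row['enriched'])}")


if __name__ == "__main__":
    main()
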