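"""K-means co-expression clustering of upregulated non-TF genes.

Clusters the chilling log2 profiles into 18 groups, derives each group's
binary consensus, phase and H2O2-responsive fraction, and writes the
membership and summary tables to results/.
"""

from pathlib import Path

from chillregnet import coexpression
from chillregnet.expression_calls import call_h2o2_responsive, call_upregulated
from chillregnet.synthetic_data import load_bundle

ROOT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    bundle = load_bundle(ROOT / "bundle")
    up = {c.gene for c in call_upregulated(bundle.chilling)}
    is_tf = dict(zip(bundle.universe["gene_id"], bundle.universe["is_tf"]))
    ntf = sorted(g for g in up if not is_tf.get(g, False))
    clusters = coexpression.kmeans_cluster(
        bundle.chilling.ratios.loc[ntf], k=bundle.config.n_clusters, seed=seed
    )
    h2o2 = call_h2o2_responsive(bundle.h2o2)
    for cl in clusters:
        coexpression.h2o2_fraction(cl, h2o2)
    membership, summary = coexpression.clusters_to_frames(clusters)
    membership.to_csv(ROOT / "cluster_membership.tsv", sep="\t", index=False)
    summary.to_csv(ROOT / "cluster_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    n_oxid = (summary["h2o2_pct"] >= 50).sum()
    print(f"{n_oxid} of {len(clusters)} clusters look oxidative-mediated "
          f"(>= 50% H2O2-responsive members)")


if __name__ == "__main__":
    main()
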