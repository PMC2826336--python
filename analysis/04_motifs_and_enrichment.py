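"""Per-cluster promoter motif discovery and cis-element class scoring.

Runs the ZOOPS-EM discovery on each cluster's promoters, subtracts random
occurrence against non-stress background promoters, matches consensi to
the cis-element catalog, and writes the motif table (cluster / motif /
element class / % (TIC) / e-value) plus the total-enrichment-score table.
"""

from pathlib import Path

from chillregnet.motif_discovery import DiscoveryConfig
from chillregnet.pipeline import PipelineConfig, run_pipeline
from chillregnet.synthetic_data import load_bundle

ROOT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    bundle = load_bundle(ROOT / "bundle")
    cfg = PipelineConfig(
        k=bundle.config.n_clusters,
        discovery=DiscoveryConfig(n_motifs=5, widths=(8,), max_iter=15,
                                  max_seqs=60),
        n_background=150,
        seed=seed,
    )
    result = run_pipeline(bundle, cfg, outdir=ROOT / "report")
    n_assigned = sum(
        1 for ms in result.motifs.values() for m in ms
        if m.element_class not in (None, "unassigned")
    )
    n_total = sum(len(ms) for ms in result.motifs.values())
    print(f"{n_total} motifs kept after background subtraction; "
          f"{n_assigned} matched a catalog element class")
    for cid in sorted(result.enrichments)[:5]:
        top = result.enrichments[cid]
        if top:
            e = top[0]
            print(f"  {cid}: top class {e.broad_category} "
                  f"(score {e.total_score:.0f}, {e.n_motif_species} species)")
    print(f"full report under {ROOT / 'report'}")


if __name__ == "__main__":
    main()
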