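"""Generate the default synthetic study bundle.

Writes a chilling time course (10 points, 0.5-96 h), an H2O2 mimic series
(1/3/6 h), 1,200-nt promoters with planted cis-element classes per
co-expression group, gene coordinates and a QTL map to results/bundle/.
"""

import sys
from pathlib import Path

from chillregnet.synthetic_data import SimulationConfig, generate_study, write_bundle

OUT = Path(__file__).resolve().parents[1] / "results" / "bundle"


def main(seed: int = 0) -> None:
    cfg = SimulationConfig(seed=seed)
    bundle = generate_study(cfg)
    write_bundle(bundle, OUT)
    truth = bundle.truth
    print(f"bundle written to {OUT}")
    print(f"  genes: {cfg.n_genes} ({bundle.universe['is_tf'].sum()} TFs)")
    print(f"  planted up-regulated: {len(truth.up_genes)}, "
          f"down: {len(truth.down_genes)}, H2O2-responsive: {len(truth.h2o2_genes)}")
    print(f"  clusters: {cfg.n_clusters} "
          f"(phase split {cfg.cluster_phase_counts}, planted rate {cfg.planted_rate})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
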