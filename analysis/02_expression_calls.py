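"""Induction/repression calling and the chilling vs H2O2 overlap.

Reads results/bundle/, applies the log2 >= 1.8 (p < 0.05) rules (two
consecutive chilling points; one H2O2 point) and writes the calls table
plus the overlap partition to results/.
"""

from pathlib import Path

import pandas as pd

from chillregnet.expression_calls import (
    call_downregulated,
    call_h2o2_responsive,
    call_upregulated,
    calls_to_frame,
    overlap_sets,
)
from chillregnet.synthetic_data import load_bundle

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = load_bundle(ROOT / "bundle")
    up = call_upregulated(bundle.chilling)
    down = call_downregulated(bundle.chilling)
    h2o2 = call_h2o2_responsive(bundle.h2o2)
    overlap = overlap_sets({c.gene for c in up}, h2o2)

    calls_to_frame(up + down).to_csv(ROOT / "calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"set": "upregulated", "n": len(up)},
            {"set": "downregulated", "n": len(down)},
            {"set": "h2o2_responsive", "n": len(h2o2)},
            {"set": "up_and_h2o2", "n": len(overlap.intersection)},
            {"set": "chilling_only", "n": len(overlap.only_a)},
        ]
    ).to_csv(ROOT / "overlap.tsv", sep="\t", index=False)

    phases = [c.phase for c in up]
    print(f"upregulated: {len(up)} (phase-1/2/3: "
          f"{phases.count(1)}/{phases.count(2)}/{phases.count(3)})")
    print(f"downregulated: {len(down)}")
    print(f"H2O2 overlap: {len(overlap.intersection)} of {len(up)} "
          f"({100 * len(overlap.intersection) / max(len(up), 1):.0f}%)")


if __name__ == "__main__":
    main()
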