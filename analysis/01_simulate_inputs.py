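#!/usr/bin/env python
"""Generate every pipeline input with known ground truth.

Writes, under results/pipeline/: arrest time courses for a 12-gene swap
cohort, native half-lives, a 450-pair synthetic genome (BED6) with true
per-gene transcription/degradation changes and expression profiles, a
2,000-gene two-condition labeling experiment (total/nascent matrices and
ortholog map), and a regulator-target matrix with regulon-coupled
effects.  Downstream drivers (02-04) consume these files.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _demo_config import DEMO_CONFIG, OUTDIR  # noqa: E402

from promcoupling import pipeline  # noqa: E402


def main() -> None:
    cfg = dict(DEMO_CONFIG, stages=["simulate"])
    res = pipeline.run_pipeline(cfg, OUTDIR)
    sim = res["simulate"]
    print(f"simulated inputs written to {OUTDIR}/")
    print(f"  decay cohort: {sim['n_decay_genes']} genes, 4 timepoints, "
          "3 replicates, two strains")
    print(f"  labeling cohort: {sim['n_labeling_genes']} ortholog pairs "
          "(coupled model, beta=2)")
    print("  genome: 150 divergent + 150 convergent + 150 tandem pairs "
          "(coupling 0.7 for divergent)")


if __name__ == "__main__":
    main()
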