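#!/usr/bin/env python
"""Δtotal/Δnew model comparison on the simulated labeling cohort.

Computes centered log2 ratios of total and nascent mRNA over the ortholog
map, estimates half-lives from the nascent fraction, classifies
differential degradation at 1.75-fold (dual criterion), and reports the
class-conditional medians with the model-pattern call.  Also runs the
shuffled-ortholog null and simulates reference cohorts under all three
generative models to show their distinct signatures.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _demo_config import DEMO_CONFIG, OUTDIR  # noqa: E402

from promcoupling import coupling, io, pipeline  # noqa: E402
from promcoupling.synthetic import CouplingScenario  # noqa: E402


def main() -> None:
    cfg = dict(DEMO_CONFIG, stages=["coupling"])
    res = pipeline.run_pipeline(cfg, OUTDIR)["coupling"]
    print((OUTDIR / "coupling_summary.txt").read_text().rstrip())

    print("\nreference signatures (median-shift difference between "
          "degradation classes, D = higher_in_2 - higher_in_1):")
    seed = DEMO_CONFIG["seed"]
    rows = []
    for model, beta in (("independent", 0.0), ("noise", 0.0),
                        ("coupled", 2.0)):
        scen = CouplingScenario(model=model, n_genes=4000, beta=beta,
                                seed=seed)
        rep = coupling.shift_report(coupling.model_distributions(scen))
        rows.append((model, rep.d_new, rep.d_total, rep.pattern_call))
        print(f"  {model:<12} D_new={rep.d_new:+.3f} "
              f"D_total={rep.d_total:+.3f} -> called {rep.pattern_call}")

    import pandas as pd

    io.write_table(
        pd.DataFrame(rows, columns=["model", "d_new", "d_total", "call"]),
        OUTDIR / "model_signatures.tsv", {"seed": seed},
    )
    print(f"\nobserved cohort called: {res['pattern_call']} "
          f"(shuffled-ortholog null: {res['null_call']})")


if __name__ == "__main__":
    main()
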