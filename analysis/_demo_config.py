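"""Shared configuration for the numbered analysis drivers."""

from pathlib import Path

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

DEMO_CONFIG = {
    "seed": 20120923,
    "simulate": {
        "decay": {"n_genes": 12, "model": "independent", "sd_noise": 0.1},
        "genome": {
            "n_divergent": 150, "n_convergent": 150, "n_tandem": 150,
            "coupling_strength": 0.7, "length_coupling_scale": 400.0,
        },
        "labeling": {"n_genes": 2000, "model": "coupled", "beta": 2.0},
        "regulators": {
            "n_genes": 300, "n_regulators": 40, "targets_per_regulator": 60,
        },
    },
}
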