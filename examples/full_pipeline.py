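"""End-to-end synthetic phenotype comparison.

Runs the full chain (ABR thresholds and shifts, latency tables, DPOAE
elevations, cochleogram summaries, group statistics) for a control cohort and
a cohort with a 15 dB conductive attenuation, writing CSV tables and a JSON
report. Scaled-down cohort sizes keep this demo fast; the defaults in
RunConfig reproduce the full study conditions.
"""

import json
from pathlib import Path

from otokit.io import RunConfig
from otokit.pipeline import run_pipeline

out = Path("scratch") if Path("scratch").exists() else Path(".")
cfg = RunConfig(
    out_dir=str(out / "pipeline_demo"),
    seed=1,
    n_subjects_per_group=3,
    dpoae_replicates=5,
)
report = run_pipeline(cfg)
print(json.dumps(report, indent=2, sort_keys=True))
print(
    f"\nreport bundle written to {cfg.out_dir}/ — the flat threshold shift, the\n"
    "equal-level latency delay that shrinks at equal sensation level, and the\n"
    "DPOAE elevation together form the conductive-hearing-loss signature."
)
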