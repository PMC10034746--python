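"""Run the full demonstration pipeline end to end.

Generates an 8-day imaging series (1,000 cells/day), ingests the imzML
exports, registers, extracts cell tables, fits the model suite, and renders
the Markdown report.  Equivalent CLI: `lipidcolony run --demo`.
"""

import json

import lipidcolony as lc

run_dir = lc.run(lc.demo_config("scratch/demo_run", seed=0, n_cells=1000))
metrics = json.loads((run_dir / "models" / "metrics.json").read_text())
print("run directory:", run_dir)
for k, v in metrics.items():
    print(f"  {k}: {v if not isinstance(v, float) else round(v, 3)}")
print("report:", run_dir / "report.md")
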