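"""The end-to-end pipeline: every stage, plain-file outputs, run report.

Equivalent to `chromaggr run --seed 1 --out runs/demo` on the command
line. Each stage hands its result to the next as an inspectable text
file; the report carries checksums so identical seed + config is
verifiably reproducible.
"""

import json
from pathlib import Path

from chromaggr import RunConfig, run_pipeline

out = Path("scratch/demo_run")
report = run_pipeline(RunConfig(out_dir=out, seed=1))

print(f"stages completed: {[s for s in report.stages if s != 'checksums']}")
print(f"warnings: {report.warnings or 'none'}")
print(f"\nfiles under {out}:")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")

summary = json.loads((out / "peak_summary.json").read_text())
print(f"\npeak stage summary: {json.dumps(summary, indent=1)}")
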