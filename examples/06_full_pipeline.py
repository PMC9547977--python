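"""Write a cohort directory and run every stage end-to-end.

Equivalent to the CLI:
    kraswt simulate --seed 1 --out cohort/
    kraswt run --cohort cohort/ --out report/ --seed 123
"""

import json
import tempfile
from pathlib import Path

from kraswt.pipeline import PipelineConfig, run_pipeline
from kraswt.synthetic_data import SimConfig, generate_cohort, write_cohort

workdir = Path(tempfile.mkdtemp())
write_cohort(generate_cohort(SimConfig(seed=1)), workdir / "cohort")
out = run_pipeline(PipelineConfig(cohort_dir=str(workdir / "cohort"),
                                  out_dir=str(workdir / "report"),
                                  seed=123))

manifest = json.loads((out / "manifest.json").read_text())
print("stage outputs:")
for stage, info in manifest["stages"].items():
    extra = {k: v for k, v in info.items() if k not in ("file", "rows")}
    print(f"  {stage:20s} {info.get('file', ''):28s} "
          f"rows={info.get('rows', '-')} {extra or ''}")
print("skipped:", manifest["skipped"] or "none")
print(f"\nreport directory: {out}")
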