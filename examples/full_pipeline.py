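"""Run every pipeline stage end to end on a synthetic cohort.

Equivalent to `tmecrosstalk run-all --config examples/pipeline_config.yaml`;
writes stage outputs and a reproducibility manifest under scratch/demo_run.
"""

import json
from pathlib import Path

from tmecrosstalk.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_yaml(Path(__file__).parent / "pipeline_config.yaml")
manifest = run_pipeline(cfg)
print(json.dumps(manifest, indent=2))
print(f"\noutputs in {cfg.outdir}: tidy TSV/CSV per stage plus manifest.json;")
print("rerunning with the same config reproduces every file byte for byte.")
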