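"""Replay the full ten-patient preset cohort and write the report artifacts.

This is the programmatic equivalent of `tipcall run-all` (which runs the
same analysis through file-backed stages). The run writes report.tsv,
truth.tsv, summary.json, config.yaml and a sha256 manifest; reruns with
the same seed reproduce the manifest byte for byte.
"""

import sys

from tipcall import PipelineConfig
from tipcall.pipeline import run_pipeline

out_dir = sys.argv[1] if len(sys.argv) > 1 else "cohort_run"
config = PipelineConfig()  # seed 1

result = run_pipeline(config, out_dir)

print("summary:", result.summary)
print(f"\nreport ({len(result.report)} validated insertions) -> {out_dir}/report.tsv")
print(result.report.to_string(index=False))
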