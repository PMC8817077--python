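"""Run the complete pipeline end to end and inspect the report bundle.

Simulates raw data to CSV, then executes filter -> reverse-score ->
reliability -> redundancy reduction -> EGA -> bootstrap -> centrality ->
stability, writing a manifest plus machine-readable tables.  Iteration
counts are kept small here so the example finishes in under a minute.
"""

import json
import tempfile
from pathlib import Path

import symptomnet as sn

workdir = Path(tempfile.mkdtemp())
csv = workdir / "responses.csv"
sn.write_responses(sn.generate(sn.default_raw_study_spec(n=1000, seed=5)), csv)

config = sn.PipelineConfig(
    input_csv=str(csv),
    out_dir=str(workdir / "report"),
    boot_iters=50,
    stability_iters=10,
    drop_fractions=(0.0, 0.3, 0.6),
    make_plots=True,
)
results = sn.run_pipeline(config)

summary = json.loads((workdir / "report" / "summary.json").read_text())
print(json.dumps(summary, indent=2))
print()
print("files written to", workdir / "report", ":")
for f in sorted((workdir / "report").iterdir()):
    print(" ", f.name)
print()
print("The manifest pins inputs, configuration and seeds: rerunning with")
print("the same manifest reproduces every table byte for byte.")
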