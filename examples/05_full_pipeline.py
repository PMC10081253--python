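"""One-command demo: the three presets through the full pipeline.

Writes per-cohort CSV tables (metric summaries, real-vs-mock tests, polar
maps, attraction statistics with tests, wall occupancy), figures, and a JSON
manifest recording seeds and file names, under ./pipeline_demo/.

Equivalent shell command:  schoolkit demo --out pipeline_demo --seed 0
"""

import json

from schoolkit.pipeline import demo_config, run_pipeline

config = demo_config("pipeline_demo", seed=0, n_trials=6, duration_s=60.0)
manifest = run_pipeline(config)

print(json.dumps(manifest["cohorts"], indent=2))
print(f"\n{len(manifest['files'])} output files written to pipeline_demo/")
print("Key tables: <cohort>/real_vs_mock_tests.csv (proximity/alignment)")
print("            <cohort>/attraction_tests.csv  (corrected forces vs zero)")
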