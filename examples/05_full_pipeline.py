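"""One-shot reproducible pipeline run over the bundled study inputs.

Writes the full report bundle (site summary, deterministic grid, threshold
table, Monte Carlo summaries, sensitivity ranking, inhalation table, run
manifest) to ./pipeline_output and prints the rendered report.
"""

import warnings

from pahrisk import PipelineConfig, render_report, run_pipeline

cfg = PipelineConfig(seed=0, n_trials=10_000, output_dir="pipeline_output")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_pipeline(cfg)
print(render_report(bundle))
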