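"""Run the whole six-step pipeline from a configuration, end to end.

Equivalent to the CLI's `coxen run-all`; the runner enforces that
validation cohorts are never read before the final prospective step.
"""

import json
import warnings

from coxen import SyntheticConfig, generate, run_pipeline, summarize, write_fixture
from coxen.simulate import fixture_run_config

warnings.filterwarnings("ignore")
fixture = "scratch/example_pipeline_fixture"
write_fixture(generate(SyntheticConfig(seed=1)), fixture)

result = run_pipeline(fixture_run_config(fixture, seed=1))
print(json.dumps(summarize(result), indent=2, default=str))
# Key fields: n_initial_biomarkers (discovery), gate (per-candidate
# suitability), n_concordant_biomarkers (three-way survivors), threshold
# (frozen Youden cut), and per-cohort validation AUC / PPV / log-rank p.
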