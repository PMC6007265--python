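"""One-command end-to-end analysis on a small synthetic cohort.

Simulates behavior and optics, preprocesses, fits all models to both data
types, compares them, and prints the summary report: AIC rankings,
preference-parameter distributions, nested F-tests, psychometric-neurometric
correlations, and the dlPFC-vs-dmPFC prediction comparison.

Equivalent shell command:  socialpref run-all --seed 1 --n-participants 8
"""

from socialpref import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(seed=1, cohort=CohortConfig(n_participants=8))
artifacts = run_pipeline(cfg)
print(artifacts.report_text)
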