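"""Validate an estimator by parameter recovery before trusting it on real data.

Simulates replicate networks where an individual covariate x lowers both
giving and receiving (true slopes -0.7), fits the covariate-adjusted
Social Relations Model to each, and checks that the posterior
concentrates on the generative values. The same run fits the
non-adjusted model to the same data, showing where the unmodelled
covariate ends up: inflated giver/receiver SDs and a spurious positive
giver-receiver correlation.
"""

from srmkit.models import build_spec
from srmkit.scm import ScmConfig
from srmkit.workflow import CI_SAMPLER, StudyConfig, run_study, summarize_report

config = StudyConfig(
    scm=ScmConfig(scm_id=2, seed=1),
    spec=build_spec(2),            # adjusted by x
    comparator=build_spec(1),      # non-adjusted
    n_replicates=2,                # quick demonstration; use 15 for a real check
    master_seed=1,
    sampler=dict(CI_SAMPLER),
)
report = run_study(config)
_, text = summarize_report(report)
print(text)
print()
print("Reading the table: the adjusted model's bG and bR should sit near the")
print("generative -0.7 with ~90% interval coverage; in the non-adjusted")
print("comparator the same signal surfaces as sG, sR above the generative 0.5")
print("and a positive cGR, because x opens a path between giving and receiving.")
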