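"""Turn posterior draws into causal effects on the outcome (rate) scale.

A log-link slope is not an effect size by itself: the implied change in
interaction rate depends on the dyad's baseline. This example fits the
rank-adjusted kinship estimator to one simulated network, then computes
baseline-dependent contrasts (CATE) and counterfactual rates for an
average dyad, and runs a posterior predictive check.
"""

import numpy as np

from srmkit.effects import (
    cate_table,
    counterfactual_pair,
    glm_effect_demo,
    posterior_predictive,
    psi_draws,
)
from srmkit.inference import diagnose, fit
from srmkit.models import build_spec
from srmkit.scm import ScmConfig, simulate

# the multiplicativity lesson in two numbers: the same slope (2) implies
# different outcome-scale effects at intercept 0 vs 1
print(f"slope 2 at intercept 0: effect {glm_effect_demo(0, 2):.1f}; "
      f"at intercept 1: effect {glm_effect_demo(1, 2):.1f}")

net = simulate(ScmConfig(scm_id=4, seed=1))
post = fit(build_spec(4), net.dataset, chains=2, iterations=500, warmup=400, seed=2)
print(diagnose(post).table.to_string(index=False))

psi = psi_draws(post)
print(f"\nbaseline psi levels (10/50/90% quantiles): "
      f"{np.round(psi.levels, 2)}")
table = cate_table(post, psi.levels)
print("kin-vs-nonkin contrast per baseline (interactions per exposure unit):")
print(table.round(3).to_string(index=False))

pair = counterfactual_pair(post, "bRe")
s = pair.summary()
print(f"\naverage dyad counterfactuals: m0 {s['m0_mean']:.3f}, m1 {s['m1_mean']:.3f}, "
      f"relative effect {s['relative_effect_mean']:.2f}x")

print()
print(posterior_predictive(post, net.dataset, seed=0).report())
print("\nThe contrast grows with the baseline psi: the same relatedness slope")
print("means more extra interactions for dyads that already interact a lot.")
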