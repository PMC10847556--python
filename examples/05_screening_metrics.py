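"""Screening evaluation statistics on synthetic predictions.

Demonstrates the evaluation toolkit: rank AUC, exact binomial confidence
intervals, threshold selection under the sensitivity > 50% constraint,
interrater agreement, and the symptomatic-subgroup comparison.
"""

import numpy as np

from pcgscreen import metrics, screening

rng = np.random.default_rng(0)
n = 400
labels = rng.random(n) < 0.1                      # 10% disease prevalence
scores = np.abs(rng.normal(0.6, 0.5, n) + 1.8 * labels)  # graded predictor

print(f"AUC: {metrics.auc(scores, labels):.3f}")

thr = screening.select_threshold(scores, labels)
sens, spec = metrics.sensitivity_specificity(scores, labels, thr)
tp = int(round(sens * labels.sum()))
ci = metrics.exact_binomial_ci(tp, int(labels.sum()))
print(f"threshold {thr:.2f}: sensitivity {sens:.2f} "
      f"(95% CI {ci[0]:.2f}-{ci[1]:.2f}), specificity {spec:.2f}")

# two annotators agreeing on murmur presence
r1 = rng.random(500) < 0.2
r2 = r1 ^ (rng.random(500) < 0.05)
kappa, agree = metrics.kappa_and_agreement(r1, r2)
print(f"Cohen's kappa {kappa:.2f}, percent agreement {100 * agree:.1f}%")

# are symptomatic cases easier to detect?
detected_sym = rng.random(40) < 0.3
missed_sym = rng.random(25) < 0.1
prev_tp, prev_fn, p = screening.symptom_subgroup_test(detected_sym, missed_sym)
print(f"symptomatic prevalence: detected {100 * prev_tp:.0f}% vs "
      f"missed {100 * prev_fn:.0f}% (Fisher p = {p:.3f})")
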