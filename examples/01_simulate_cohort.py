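"""Generate a small synthetic heart-sound cohort and inspect its structure.

The generator emulates an unselected screening cohort: four auscultation
positions per participant, murmur loudness tied to valvular disease
severity, stenosis grade derived from the aortic mean pressure gradient
via the 15/20/40 mm Hg cutoffs, two noisy annotators, and clinical
covariates with realistic missingness.
"""

import numpy as np

from pcgscreen import synth

cfg = synth.CohortConfig(n_participants=50, seed=1)
participants, truth = synth.generate_cohort(cfg)

n_as = sum(p.as_grade >= 1 for p in participants)
n_murmur = sum(truth.true_grades[p.participant_id].max() >= 1 for p in participants)
noisy_recs = sum(r.is_noisy for p in participants for r in p.recordings)

print(f"participants: {len(participants)}")
print(f"aortic stenosis (grade >= 1): {n_as}")
print(f"participants with a true murmur grade >= 1: {n_murmur}")
print(f"noise-flagged recordings: {noisy_recs} of {4 * len(participants)}")

p = next(p for p in participants if p.as_grade >= 1)
print(f"\nexample AS case {p.participant_id}: "
      f"AVPGmean {p.avpg_mean:.1f} mm Hg -> AS grade {p.as_grade}")
print("true murmur grades (aortic, pulmonic, tricuspid, mitral):",
      np.round(truth.true_grades[p.participant_id], 2))
print("annotator grades at the aortic position:",
      p.recordings[0].annotator_grades)

# The AS grade is always the deterministic cutoff function of the gradient,
# and louder murmurs track higher gradients; annotators add grade noise.
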