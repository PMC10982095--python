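"""Classify truth vs. lie with per-feature Gaussian Naive Bayes voting.

Builds a 20-interviewee synthetic corpus with a strong movement effect,
evaluates with leave-one-interviewee-out cross-validation, and compares
all-feature voting with the significance-filtered stat-95 / stat-99 sets.
"""

import bodycues as bc
from bodycues import experiments as ex

config = bc.SyntheticConfig(n_interviewees=20, lie_movement_multiplier=2.0, seed=3)
dataset = ex.build_dataset(bc.generate_corpus(config))

for label, alpha in ex.ALPHA_LABELS.items():
    res = bc.loocv(dataset, alpha=alpha)
    print(
        f"{label:8s} rate {100 * res.detection_rate:6.2f}%  "
        f"mean selected features {res.mean_selection_size():6.1f} / 335"
    )
res = bc.loocv(dataset, alpha=0.05)
print("confusion (% of windows, rows = actual truth/lie, cols = guessed):")
print(res.confusion().round(2))
# A detection rate near 100% is expected here: the planted effect (liars'
# sway and gesture rate doubled) is far stronger than anything in real
# interviews, where published rates are in the 60-65% range.
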