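"""Volume agreement between two observers: ICC(2,1) and the rank-sum test.

Simulates bladder volumes for a 29-patient cohort read by two observers:
true volumes vary between patients, and each observer adds independent
measurement noise.  ICC(2,1) (two-way random effects, absolute agreement,
single measures) quantifies how much of the total variance is genuine
between-patient variation; the Wilcoxon rank-sum test asks whether one
observer systematically measures larger volumes.
"""

import numpy as np

from contourvar import icc_2_1, wilcoxon_rank_sum

rng = np.random.default_rng(0)
n_patients = 29
true_volumes = rng.normal(220.0, 60.0, size=n_patients)        # cm^3
observed = true_volumes[:, None] + rng.normal(0, 15.0, size=(n_patients, 2))

res = icc_2_1(observed)
test = wilcoxon_rank_sum(observed[:, 0], observed[:, 1])

print(f"ICC(2,1)        = {res.icc:.3f}  (good agreement: {res.good}, threshold 0.75)")
print(f"mean squares    : subjects {res.ms_rows:.1f}, raters {res.ms_cols:.1f}, "
      f"error {res.ms_error:.1f}")
print(f"rank-sum W      = {test.statistic:.1f}, p = {test.p_value:.3f} "
      f"({test.method}); significant at 0.05: {test.significant}")
print()
print("An ICC above 0.75 is conventionally read as good volume consistency;")
print("a non-significant p means no evidence of a systematic volume shift")
print("between the observers.")
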