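"""Zero-truncated binomial estimation of the daily calling probability.

Groups heard within 500 m of a post are detected essentially whenever
they call, so their day-by-day calling record is observed directly --
except that a group silent on every survey day is never seen at all.
The zero-truncated binomial accounts for that missing class.
"""

import numpy as np

from gibbonascr import (CallingProbData, fit_calling_probability,
                        proportion_calling_over_m_days)

# 37 calibration groups over 3-day visits: 11 called on all three days,
# 16 on two, 10 on one (75 calling days of a possible 111)
y = np.array([3] * 11 + [2] * 16 + [1] * 10)
n = np.full(37, 3)
data = CallingProbData(np.array([f"G{i}" for i in range(37)], object), y, n)

f = fit_calling_probability(data)
print(f"p(1) = {f.p_hat:.3f}  (95% profile CI {f.ci_low:.3f}-{f.ci_high:.3f})")
# the naive mean y/n = 75/111 = 0.676 overestimates p because all-silent
# groups are excluded; the truncation correction pulls it down.

for m in (1, 2, 3, 4):
    print(f"p({m}) = {proportion_calling_over_m_days(f.p_hat, m):.3f}")
# p(m) is the chance a group calls at least once in an m-day survey: with
# p(1) ~ 0.65, three days already catch ~96% of groups.
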