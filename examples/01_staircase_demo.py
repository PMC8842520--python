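"""Measure one contrast threshold with the paired running-fit staircases.

A simulated 2AFC observer with a known Weibull psychometric function is run
through two interleaved 40-trial running-fit staircases.  Each staircase
starts with one unscored orienting trial, then places every trial at its
current maximum-a-posteriori threshold estimate.  The 80 scored trials are
pooled for the final estimate, and a bootstrap standard error screens the
cell for reliability (SE <= 0.2 dex on the log threshold).
"""

import numpy as np

from perifield import (StaircaseConfig, WeibullPF, bootstrap_se, pf_eval,
                       pf_quantile, run_running_fit)

# an observer whose 81%-correct threshold is about 0.2 Michelson contrast
observer = WeibullPF(m=0.2, beta=3.5, gamma=0.5, lam=0.02)
config = StaircaseConfig(initial_threshold=0.3)
rng = np.random.default_rng(12345)

records, threshold = run_running_fit(config, observer, rng)
se = bootstrap_se(records, config, B=500, rng=rng)

print(f"true 81%-correct threshold : {pf_quantile(observer, 0.81):.4f}")
print(f"recovered threshold        : {threshold:.4f}")
print(f"bootstrap SE (log10 units) : {se:.4f}  "
      f"({'reliable' if se <= 0.2 else 'unreliable'})")
print(f"observer % correct there   : {100 * pf_eval(observer, threshold):.1f}%")

print("\nfirst 10 scored placements of staircase 0:")
placements = [r for r in records if r.staircase_id == 0 and r.scored][:10]
for r in placements:
    print(f"  trial {r.trial_index:2d}  contrast {r.contrast:.4f}  "
          f"{'correct' if r.correct else 'wrong'}")
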