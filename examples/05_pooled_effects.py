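"""Pool lead-specific estimates into one mean effect and classify it.

The random-effects model treats the 13 lead estimates as draws around a
common mean with between-lead variance tau^2 (REML default, DL optional);
the association is labelled by the sign of the pooled mean and whether its
95% CI excludes zero.
"""

import numpy as np

from policymatch import classify_effect, pool_random_effects

rng = np.random.default_rng(5)
truth = np.linspace(-0.1, -0.9, 13)          # a deepening negative effect
estimates = truth + rng.normal(0, 0.1, 13)   # noisy lead-specific ATTs
ses = np.full(13, 0.1)

for method in ("reml", "dl"):
    pooled = pool_random_effects(estimates, ses, "pdmp_mandatory",
                                 "p_any_opioid", method=method)
    print(f"{method:>4}: mean={pooled.mean_effect:+.3f} "
          f"CI=[{pooled.ci_low:+.3f}, {pooled.ci_high:+.3f}] "
          f"tau2={pooled.tau2:.4f} k={pooled.k} -> {classify_effect(pooled)}")
# tau2 > 0 reflects genuine variation of the effect across leads (the ramp);
# the label drives the shading of the policy-by-outcome summary grid.
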