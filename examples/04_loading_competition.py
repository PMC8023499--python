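"""Compete origins for a limiting MCM pool under the three loading models.

Each origin has an ORC activity (how fast it recruits free MCM-DH units)
and a capacity (how many it can hold). With MCM in excess every model
loads every origin to capacity; the models only separate when the pool
is reduced: the pure ORC-activity model cuts every origin by the same
proportion, while the hybrid model starves slow-loading origins first.
"""

import numpy as np
from scipy import stats

from mcmkit.experiment import endogenous_pool, toy_origin_map
from mcmkit.loading import (
    LoadingConfig,
    origins_to_arrays,
    retained_fraction,
    simulate_loading,
)

_, origins = toy_origin_map(seed=4)
act, cap = origins_to_arrays(origins)
n0 = endogenous_pool(origins)
print(f"{len(origins)} origins, summed capacity {cap.sum():.0f} MCM-DH, "
      f"endogenous pool {n0} (in excess)")

rng = np.random.default_rng(0)
full, _ = simulate_loading(act, cap, LoadingConfig(pool=n0, t_g1=90.0), rng=rng)
red, _ = simulate_loading(act, cap, LoadingConfig(pool=int(0.07 * n0), t_g1=90.0),
                          rng=rng)
ret = retained_fraction(full, red)
ok = np.isfinite(ret)
rho = stats.spearmanr(act[ok], ret[ok]).statistic
print(f"hybrid model, pool reduced to 7%: total occupancy retained "
      f"{red.sum() / full.sum() * 100:.0f}%")
print(f"  rank correlation(ORC activity, retained fraction) = {rho:.2f}")

c_inf = np.full(act.size, np.inf)
full_a, _ = simulate_loading(act, c_inf,
                             LoadingConfig(pool=2_000, t_g1=1e12,
                                           variant="orc_activity"), rng=rng)
red_a, _ = simulate_loading(act, c_inf,
                            LoadingConfig(pool=140, t_g1=1e12,
                                          variant="orc_activity"), rng=rng)
ret_a = retained_fraction(full_a, red_a)
ok = np.isfinite(ret_a)
rho_a = stats.spearmanr(act[ok], ret_a[ok]).statistic
print(f"pure ORC-activity model, pool reduced to 7%: "
      f"rank correlation = {rho_a:.2f}")
print("-> a positive correlation under the hybrid model (and none under "
      "proportional reduction) is the signature separating the two.")
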