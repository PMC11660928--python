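"""Compute replication timing indices from simulated 4-fraction counts.

Simulates Repli-seq bin counts over a synthetic timing landscape, runs the
normalization -> smoothing -> RTI pipeline, and compares the recovered
per-bin timing with the planted truth.
"""

import numpy as np
from scipy.stats import spearmanr

import replitime as rt

cfg = rt.RepliSimConfig(seed=1)
profiles, grid, truth, kinds = rt.simulate_repliseq(cfg)
print(f"simulated {len(profiles)} replicates over {len(grid)} bins of 50 kb")

normed = rt.quantile_normalize(profiles)
rti_reps = [rt.compute_rti(rt.loess_smooth(p, span_bp=300_000)) for p in normed]
mean_rti = rt.replicate_mean_rti(rti_reps)

ok = ~np.isnan(mean_rti.rti)
rho = spearmanr(mean_rti.rti[ok], truth[ok]).statistic
print(f"defined bins: {ok.sum()}/{len(grid)}")
print(f"Spearman correlation with planted timing: {rho:.3f}")
print("\nfirst five bins (RTI 0 = earliest, 1 = latest replication):")
for i in range(5):
    print(
        f"  {grid.chroms[i]}:{grid.starts[i]:>9,}-{grid.ends[i]:<9,}"
        f"  true t={truth[i]:.2f}  estimated RTI={mean_rti.rti[i]:.2f}"
    )
# A high rank correlation means the weighted-fraction index orders the
# genome by replication time essentially as constructed.
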