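"""Model-free signatures of priority and trial-to-trial memory quality.

On synthetic wager-experiment data: error and circle radius both decrease
with priority; after per-participant standardization the two correlate
positively within every priority; and stratified permutation tests show the
coupling survives controls for stimulus location and delay.
"""

import numpy as np
import pandas as pd

from vpalloc import DesignConfig, ModelSpec, behavior, generate_experiment

spec = ModelSpec(experiment=2, strategy="flexible")
theta = {"Jbar_total": 3.0, "tau": 0.5, "p_high": 0.44, "p_med": 0.31, "lam": 5.0}
ss = np.random.SeedSequence(21)
trials = pd.concat(
    [
        generate_experiment(
            spec, theta, DesignConfig(), rng_seed=c.generate_state(1)[0] % 2**31, participant=i
        )
        for i, c in enumerate(ss.spawn(6))
    ],
    ignore_index=True,
)

summary = behavior.priority_summary(trials)
print(summary.round(3).to_string(index=False))
print(f"error monotone in priority : {summary.attrs['monotone_error']}")
print(f"radius monotone in priority: {summary.attrs['monotone_radius']}")

pooled, _ = behavior.within_priority_correlation(trials)
print("\nwithin-priority standardized Spearman correlations:")
print(pooled.round(3).to_string(index=False))

for cov in ("location", "delay"):
    nulls = behavior.permutation_null(trials, cov, n_perm=1000, rng_seed=5)
    obs = np.array([nd.observed_rho for nd in nulls])
    med = np.array([nd.null_median for nd in nulls])
    res = behavior.signed_rank_vs_null(obs, med)
    print(
        f"\n{cov}-stratified null: mean null median = {med.mean():+.3f}, "
        f"mean observed = {obs.mean():+.3f}, signed-rank p = {res.pvalue:.2g}"
    )
print("\nObserved correlations sit far above the stratified nulls: the")
print("error-radius coupling reflects shared precision fluctuations, not")
print("location- or delay-driven artifacts.")
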