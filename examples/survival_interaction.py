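"""Treatment-by-methylation interaction on progression-free survival.

Fits Cox models with a score-by-treatment interaction, screens CpGs for
predictive (arm-dependent) effects, and derives the expected-survival
surface S(t | score) per treatment arm.
"""

import numpy as np
import pandas as pd

import ddrmeth as dm

cfg = dm.SimConfig(seed=6)
cfg.hazard_params.interaction_coef = -0.2851  # planted predictive effect
rng = np.random.default_rng(0)
n = 400
score = pd.Series(rng.normal(0, 1, n), index=[f"pt{i}" for i in range(n)])
tab, _ = dm.simulate_survival(cfg, score, rng=rng)

fit = dm.cox_fit(tab, "score + arm + score:arm", null_formula="score + arm")
row = fit.terms.loc["score:arm"]
print(f"interaction: coef = {row['coef']:.4f}, HR = {row['hr']:.4f} "
      f"(planted {cfg.hazard_params.interaction_coef})")
print(f"LRT vs no-interaction model: stat = {fit.lrt_stat:.2f}, "
      f"p = {fit.lrt_p:.4f}")

km = dm.km_by_cutoffs(tab, score)
for arm, info in km["arms"].items():
    print(f"log-rank across score tertile groups, arm {arm}: "
          f"p = {info['logrank_p']:.4f}")

surface = dm.expected_survival_surface(
    fit, score_grid=np.array([-1.0, 0.0, 1.0]), time_grid=np.array([24.0])
)
print("S(24 months | score) per arm:")
for arm, sf in surface.items():
    print(f"  {arm}: {sf.iloc[0].round(3).to_dict()}")
# A negative interaction means higher methylation scores improve survival
# specifically in the TMZ arm - the predictive-marker signature.
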