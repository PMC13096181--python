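"""Bias statistics: popularity deviations, quadrants, scaling, count models.

Uses the published ten-genus observed/expected popularity table as input
for the deviation arithmetic, then fits the scaling and negative-binomial
models on synthetic data with known coefficients.
"""

import math

import numpy as np

from beebias.stats import (
    classify_quadrants,
    deviation_table,
    nb_glm,
    richness_effort_scaling,
)
from beebias.synth import gen_nb_recovery

observed = {
    "Apis": 44431, "Bombus": 7720, "Megachile": 1184, "Osmia": 1001,
    "Xylocopa": 1256, "Melipona": 1190, "Andrena": 1030,
    "Lasioglossum": 697, "Tetragonula": 423, "Trigona": 939,
}
expected = {
    "Apis": 28860, "Bombus": 9970, "Megachile": 4522, "Osmia": 4343,
    "Xylocopa": 4294, "Melipona": 2332, "Andrena": 1560,
    "Lasioglossum": 1331, "Tetragonula": 1259, "Trigona": 1402,
}
table = deviation_table(observed, expected)
print("popularity-scaled deviations (observed - expected, % of expected):")
print(table.to_string(index=False))
# Apis sits ~15.6k papers (+54%) above its public-interest expectation;
# every other focal genus sits below it.

rng = np.random.default_rng(7)
genera = [f"g{i}" for i in range(40)]
effort = {g: float(rng.integers(0, 1000)) for g in genera}
centrality = {g: float(rng.normal()) for g in genera}
qa = classify_quadrants(effort, centrality)
print(f"\npolicy groups (median split): {qa.group_sizes} "
      f"(sum = {sum(qa.group_sizes.values())} genera)")

richness = {g: float(v) for g, v in zip(genera, rng.integers(20, 5000, size=40))}
articles = {g: r**0.673 * float(rng.lognormal(0, 0.3)) for g, r in richness.items()}
fit = richness_effort_scaling(articles, richness)
print(f"\nrichness-effort scaling: slope={fit.slope:.3f} "
      f"(95% CI {fit.ci[0]:.3f}-{fit.ci[1]:.3f}, adj R2={fit.adj_r2:.3f}, HC3 s.e.)")
# a slope < 1 means publications grow sublinearly with genus richness.

y, X, offset, truth = gen_nb_recovery(beta_managed=math.log(2.86), theta=2.0, n=2000, seed=8)
nb = nb_glm(y, X, offset=offset, offset_description="log yearly total")
print(f"\nnegative-binomial managed premium: IRR={nb.irr['managed']:.2f} "
      f"(95% CI {nb.ci_low['managed']:.2f}-{nb.ci_high['managed']:.2f}), "
      f"theta={nb.theta:.2f}; true IRR={math.exp(truth['beta_managed']):.2f}")
# the IRR is the multiplicative excess of papers for managed genera at
# fixed exposure; the model recovers the planted premium of 2.86.
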