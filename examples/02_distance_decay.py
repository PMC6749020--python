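"""Distance-decay of community similarity in a forest soil.

Rarefaction-averages a simulated forest community, computes pairwise
1 - Canberra similarity and regresses it on log10 geographic distance,
with significance from a Mantel test — the core spatial-turnover analysis.
"""

import soilbeta as sb
from soilbeta import distances, matrix_stats, tables

cfg = sb.ScenarioConfig.desk(seed=1)
forest = sb.simulate_site(cfg, "forest", seed=1)

avg = tables.rarefaction_average(forest.tables["RNA"], cfg.rarefaction_depth,
                                 n_reps=50, seed=0)
sim = distances.canberra(avg).to_similarity()
geo = distances.geographic(avg)
fit = matrix_stats.decay_fit(sim, geo, n_perm=999, seed=0)

print(f"mean pairwise similarity : {sim.condensed().mean():.3f}")
print(f"decay slope              : {fit.slope:.4f} per decade of distance")
print(f"Mantel r                 : {fit.mantel_r:.3f}")
print(f"Mantel p ({fit.n_pairs} pairs)     : {fit.mantel_p:.4f}")
print(f"draw trend line?         : {fit.significant}")

print("\nA negative slope with Mantel p < 0.05 means nearby soil cores host "
      "more similar bacterial communities than distant ones — the spatial "
      "structure that land conversion erases. The same call on a disturbed "
      "site returns a flat, non-significant fit.")
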