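"""Attribute homogenization to its mechanism by removal-and-recompute.

Runs the full mechanism report on a bloom scenario: identifies newcomer
and bloomer candidate sets for both molecules, removes each from the
converted site's raw table, re-equalizes sampling extent by rarefaction,
and asks whether similarity falls back toward the forest baseline.
"""

import soilbeta as sb

cfg = sb.ScenarioConfig.desk(seed=1)
forest, target = sb.simulate_pair("bloom", cfg, seed=1)

report = sb.mechanism_report(forest.tables, target.tables,
                             depth=cfg.rarefaction_depth, n_reps=50,
                             seed=0, n_perm=499)
print(report.summary_frame().to_string(index=False, float_format="%.3f"))

print("\nA mechanism 'contributes' when removing its taxa significantly "
      "lowers mean pairwise similarity (Tukey HSD) and leaves the community "
      "no longer significantly more similar than the forest. Here the "
      "bloomers carry the homogenization; the handful of spurious newcomers "
      "do not.")
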