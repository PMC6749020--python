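"""Identify "bloomer" taxa with the negative-binomial Wald test.

Compares raw counts of a converted (bloom) site against the forest and
reports taxa with a positive log2 fold change at BH-adjusted p < 0.05 —
the resident taxa whose relative abundance surged after conversion.
"""

import soilbeta as sb
from soilbeta import tables
from soilbeta.mechanisms import identify_bloomers

cfg = sb.ScenarioConfig.desk(seed=1)
forest, bloomsite = sb.simulate_pair("bloom", cfg, seed=1)

forest_raw, target_raw = tables.align_taxa(
    [forest.tables["RNA"], bloomsite.tables["RNA"]])
bloomers = identify_bloomers(forest_raw, target_raw,
                             min_sample_depth=cfg.rarefaction_depth)

print(f"taxa tested              : {target_raw.n_taxa}")
print(f"significant bloomers     : {len(bloomers.taxa)}")
print(f"share of target community: {bloomers.mean_rel_abund:.1%}")
print(f"occurrence freq (forest) : {bloomers.occurrence_reference.mean():.2f}")
print(f"occurrence freq (target) : {bloomers.occurrence_target.mean():.2f}")

print("\nBloomers collectively dominate the converted community and occur in "
      "nearly every core there, while being patchier in the forest — exactly "
      "the range-expansion profile that drives biotic homogenization.")
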