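# soilbeta

Spatially explicit beta-diversity analysis for paired RNA/DNA soil
microbial communities, built to diagnose **biotic homogenization** after
land-use change and to attribute it to its mechanism — the arrival of
*newcomer* taxa (biotic invasion) versus the *bloom* of resident taxa
(range expansion).

The package targets the classic chronosequence design: a forest reference
and one or more converted sites (e.g. burned, plantation), each sampled at
the 13 corners of nested quadrats (100, 10, 1, 0.1 m) so that pairwise
distances span three orders of magnitude, with each soil core profiled
twice — by 16S rRNA transcripts (the active, "RNA-inferred" community) and
by the rRNA gene (the "DNA-inferred" community, which also carries
inactive and relic DNA).

## What it computes

Given OTU tables (classic TSV or BIOM), sample metadata (site, molecule,
x/y in meters) and a soil-chemistry table:

* **Sampling-effort equalization** — the mean of `n` rarefactions at a
  fixed depth per sample (default 100 × 3790), dropping samples below the
  depth.
* **Community similarity** — 1 − Canberra distance, with the Canberra sum
  averaged over non-double-zero taxa so values lie in [0, 1]:
  `d(i,j) = (1/NZ) Σ_k |x_ik − x_jk| / (x_ik + x_jk)`.
* **Environmental similarity** — 1 − Gower dissimilarity over the
  chemistry suite, after greedily pruning collinear variables
  (R² > 0.6, p < 0.05).
* **Spatial turnover** — distance-decay regression of pairwise similarity
  on log10 geographic distance, with Mantel / partial-Mantel permutation
  significance (add-one p-values, vectorized nulls), a slope-difference
  randomization (`diffslope`), and PERMANOVA (pseudo-F over squared
  distances) for land-type effects.
* **Differential abundance** — a compact negative-binomial GLM Wald test
  (median-of-ratios size factors, Cox–Reid adjusted ML dispersions shrunk
  to a mean–dispersion trend, BH correction); taxa with positive log2
  fold change and adjusted p < 0.05 are *bloomers*.
* **Mechanism attribution** — newcomers (detected in a converted site but
  in no forest sample) and bloomers are removed from the raw table, the
  community is re-rarefied, and similarity plus distance-decay are
  recomputed; a mechanism "contributes" when its removal significantly
  lowers mean similarity and leaves the site no more similar than the
  forest (Tukey HSD, α = 0.05).
* **A synthetic study generator** — log-normal abundances filtered through
  multivariate Gaussian niches on spatially autocorrelated soil gradients;
  an RNA layer with amplified environmental responsiveness; a DNA layer
  mixing in a spatially flat relic pool; land conversion as a directional
  niche-axis shift plus unstructured nutrient variance; optional injected
  newcomers and amplified bloomers. Every analysis stage is testable
  against known truth without any sequencing data.

## Worked example

Simulate a forest site and measure its spatial turnover
(`examples/02_distance_decay.py`):

```python
import soilbeta as sb
from soilbeta import distances, matrix_stats, tables

cfg = sb.ScenarioConfig.desk(seed=1)
forest = sb.simulate_site(cfg, "forest", seed=1)
avg = tables.rarefaction_average(forest.tables["RNA"], cfg.rarefaction_depth,
                                 n_reps=50, seed=0)
sim = distances.canberra(avg).to_similarity()
fit = matrix_stats.decay_fit(sim, distances.geographic(avg), n_perm=999, seed=0)
```

prints

```
mean pairwise similarity : 0.611
decay slope              : -0.0357 per decade of distance
Mantel r                 : 0.793
Mantel p (66 pairs)     : 0.0030
draw trend line?         : True
```

i.e. community similarity falls by ~0.036 for every tenfold increase in
distance between cores, and the association is significant under 999
sample relabelings — nearby forest soils host measurably more similar
bacterial communities. Running the mechanism report on a converted site
(`examples/04_mechanism_attribution.py`) then shows the converted
community *more* similar than the forest (0.68 vs 0.61), with removal of
the 24 detected bloomer taxa — but not of the newcomers — pulling it back
down (verdict `contributes = True`).

The other examples cover study simulation and I/O
(`01_simulate_study.py`) and bloomer identification
(`03_differential_abundance.py`). An end-to-end pipeline with a YAML
config and a thin CLI is also included:

```bash
soilbeta all --seed 1 --out run_out        # simulate + analyze everything
soilbeta report --summary run_out/summary.json
```

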