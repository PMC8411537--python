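# larvakin

Comparative kinematics of *Drosophila* larval crawling and its relation
to habitat temperature and trait evolution.

Larvae of different *Drosophila* species crawl differently: some bend
often and advance slowly, others run fast and straight.  `larvakin`
re-implements, as a tested and reusable pipeline, the analysis chain
that quantifies this divergence across species and relates it to the
temperature of each species' habitat:

1. **Kinematics** — from tracker output (per-frame centroid position and
   body bend angle at 5 frames/s, 0.13 mm/pixel), compute per-larva
   statistics: the *bend probability* (fraction of frames with
   |bend angle| > 20°), the *crawling speed* (median centroid speed over
   non-bending frames, mm/s), the crawling distance per minute, and
   backward-crawling bouts.  Species are summarised by median ± s.e.m.
2. **Divergence clustering** — each species' pooled (speed, |angle|)
   points are binned on a fixed 40 × 70 grid (speed 0–4 mm/s by
   0.1 mm/s, angle 0–140° by 2°; 2800 cells) and compared with the
   symmetrised Kullback–Leibler divergence
   JS(p,q) = ½[KL(p,q) + KL(q,p)] (nats), then clustered hierarchically.
3. **Habitat temperature** — min/mean/max climate rasters (ESRI ASCII)
   masked by habitat regions yield Tave and Tmax (histogram modes) and
   Tmin (the *warmest peak* of the minimum-temperature histogram, a
   robust summary when the global mode lies below 0 °C).
4. **Statistics** — Pearson correlations with Fisher-z 95% CIs,
   regression confidence bands, Kruskal–Wallis, Mann–Whitney U,
   one-way ANOVA, Bonferroni correction.
5. **Trait evolution** — Bayesian inference of a multivariate Brownian
   motion on a fixed rooted phylogeny with relaxed-clock branch rates:
   tip traits Z (n species × k log-transformed traits) are matrix-normal
   with row covariance C(r) (phylogenetic covariance with per-branch
   rates r_b, UCED/UCG priors) and column covariance
   Σ = σ² diag(√v) R diag(√v) (mean-1 relative trait rates v, trait
   correlation matrix R under an LKJ(1) prior).  Blockwise
   Metropolis–Hastings yields posterior means and 95% HPD intervals for
   branch rates, trait rates and correlations.
6. **Synthetic data** — generators for run-and-bend larval tracks,
   climate rasters with planted temperature peaks, Tmin-linked species
   panels, and Brownian traits with known ground truth, so every stage
   has a parameter-recovery test.

## Worked example

Generate a synthetic 11-species panel whose bend rate falls and run
speed rises with the assigned habitat Tmin, run the whole pipeline, and
check what it recovers:

```python
from larvakin.pipeline import run_panel_study

res = run_panel_study(seed=1)
print(f"r(Tmin, bend probability) = {res.r_tmin_bend.r:.3f}, "
      f"95% CI {res.r_tmin_bend.ci95}")
print(f"r(Tmin, crawling speed)   = {res.r_tmin_speed.r:.3f}")
print("first dendrogram merge:", set(res.first_merge_pair))
print("most similar planted pair:", set(res.truth_closest_pair))
```

prints

```
r(Tmin, bend probability) = -0.999, 95% CI (-0.9996392177162639, -0.9942472507234821)
r(Tmin, crawling speed)   = 0.956
first dendrogram merge: {'sp03', 'sp02'}
most similar planted pair: {'sp03', 'sp02'}
```

i.e. the extraction-plus-correlation chain recovers the planted
negative Tmin–bend and positive Tmin–speed relationships, and the JS
dendrogram's first merge is exactly the pair of species whose planted
behavioural distributions are closest.

The same stages are available from the shell:

```sh
larvakin simulate panel --seed 1 --out panel/
larvakin kinematics --tracks panel/sp00.csv --out kin/
larvakin cluster --tracks-dir panel/ --out clust/
larvakin phylo --tree tree.nwk --traits traits.tsv --seed 1 --out phylo/
```

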