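# divspace

**Productivity–biodiversity relationships across a continuous biodiversity
space.**

How plant diversity changes along the productivity gradient depends on what
"diversity" means: whether rare and dominant species count equally, whether
species are weighted by how similar they are, and whether similarity is
read from functional traits or from a phylogeny. `divspace` implements a
complete, testable pipeline for exploring this systematically: plot-level
community surveys and satellite-sensed productivity (NDVI) are related
across a three-parameter family of diversity measures, compared against
abundance-preserving null models, and the fitted response curves are
classified by shape. Because suitable survey, trait, and phylogeny data
are rarely openly available, the package ships a first-class synthetic-data
generator that embeds known response shapes, so every stage of the analysis
can be validated end-to-end against ground truth.

## The biodiversity space

Diversity is computed as a similarity-sensitive Hill number (Leinster &
Cobbold). For relative abundances *p* and a species-similarity matrix *Z*
(unit diagonal, entries in [0, 1]),

```
D_q(p, Z) = ( Σ_i p_i (Zp)_i^(q−1) )^(1 / (1−q)),      q ∉ {1, ∞}
D_1       = exp( −Σ_i p_i ln (Zp)_i )
D_∞       = 1 / max_{i: p_i>0} (Zp)_i
```

an *effective number of species*. Three parameters span the space:

* **q ∈ [0, ∞]** — dominance weight. q = 0 ignores abundances (richness
  when Z = I); q = 2 with similarity gives Rao\* = 1/(1 − Rao's Q);
  q = ∞ is the Berger–Parker limit.
* **a ∈ [0, 1]** — similarity type. Trait-based (functional dendrogram,
  UPGMA on standardized log SLA / height / seed mass) and phylogenetic
  cophenetic distances are blended as
  `FPDist = (a·FDist² + (1−a)·PDist²)^½` with *a* the trait weight, then
  converted to similarity by Z = 1 − scaled distance.
* **δ ∈ (0, ∞]** — similarity scale, via Pagel's transform of node depths
  *d → d^δ* of the depth-1 ultrametric tree. δ < 1 emphasizes deep
  between-clade splits, δ > 1 fine between-sister differences, and δ = ∞
  collapses the tree to a rake: all species equally distinct (taxonomic
  diversity).

Around this core the package provides NDVI time-series proxies (seasonal
GAM → mean interannual NDVI as productivity; growing-season mean absolute
residual as land-use intensity), quality filtering and binning of community
plots with spatially constrained bootstraps, checkerboard-swap null models
that preserve richness, occurrence frequencies, and per-site abundance
multisets, a signed "density bias" statistic comparing observed and null
diversity at high productivity, and GAM-based classification of response
curves into {ns, concave−, concave+, increasing, decreasing}.

## Worked example

Run a synthetic scenario that embeds a unimodal (concave−) richness
response and a monotonically increasing trait-diversity response, and
recover both from the fitted curves:

```python
import divspace as dv

result = dv.run_scenario(dv.ScenarioConfig(seed=5))
print(result.summary.to_string(index=False))
```

```
  a  delta   q      shape       r2
0.0    1.0 0.0   concave- 0.889049
0.0    1.0 2.0   concave- 0.792751
0.0    inf 0.0   concave- 0.919615
0.0    inf 2.0   concave- 0.810874
1.0    1.0 0.0   concave- 0.730171
1.0    1.0 2.0 increasing 0.870884
1.0    inf 0.0   concave- 0.919615
1.0    inf 2.0   concave- 0.810874
```

Each row is one corner of biodiversity space. At the taxonomic corner
(δ = ∞, q = 0: plain species richness) the relationship is classified
concave− — richness peaks at intermediate productivity — with R² ≈ 0.92.
At the trait-diversity point (a = 1, δ = 1, q = 2: abundance-weighted
functional diversity, Rao\*) the relationship is increasing, matching the
shapes the generator embedded. Rows with δ = ∞ coincide across *a*
because the rake tree makes trait and phylogenetic information
indistinguishable.

The same analysis is available from the shell:

```bash
divspace synth --out scenario/ --seed 5       # write all inputs as CSV/Newick/YAML
divspace ndvi --series scenario/ndvi.csv --out proxies.csv
divspace fit --scenario-seed 5 --out fits/
```

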