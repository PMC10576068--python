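# coverphylo

Community-phylogenetic analysis of cover-crop-based weed suppression.

Cover crops suppress weeds, but do they suppress *related* weeds more
strongly?  If ecological niches are conserved along a phylogeny, a cover
crop should compete hardest with weed species close to it on the tree,
filtering the weed community toward phylogenetically distant survivors.
`coverphylo` implements the statistics needed to ask that question of a
replicated field experiment (sites x years x blocks x treatments), plus a
synthetic experiment generator with known ground truth so every stage of
the pipeline can be validated end to end.

## What it computes

**Abundance-weighted interspecific MPD.**  For a community with relative
biomass weights $p_i$ on a patristic distance matrix $d_{ij}$ (derived
from the phylogenetic variance–covariance matrix as
$d_{ij} = C_{ii} + C_{jj} - 2C_{ij}$):

$$\mathrm{MPD} = \frac{\sum_{i \ne j} p_i p_j d_{ij}}{\sum_{i \ne j} p_i p_j}$$

Conspecific pairs ($i = j$) are excluded; the value is invariant to
rescaling all biomasses and, on constant-distance communities, to species
richness.

**Relativized cover-crop-to-weed distance.**  With the cover taxa (and
their measured biomass) added to a weed community,

$$\Delta \mathrm{MPD}(\text{community}) = \mathrm{MPD}(\text{cover} + \text{weeds}) - \mathrm{MPD}(\text{weeds})$$

$$\mathrm{MPD}_{\text{relativized}} = \Delta\mathrm{MPD}(\text{weeds in cover plot}) - \Delta\mathrm{MPD}(\text{weeds in paired control plot})$$

Positive values mean the weeds surviving under the cover crop are
phylogenetically *overdispersed* relative to it (related weeds were
preferentially suppressed); negative values mean clustering.  The control
term removes the baseline distance between the chosen cover species and
the resident weed flora, which would otherwise bias the comparison.

**Community-structure tests.**  From-scratch sequential-SS PERMANOVA
(site, treatment, site:treatment) on Bray–Curtis dissimilarities of
ln(1+biomass)-transformed weed communities, with free or within-stratum
permutations; beta-dispersion homogeneity checks in the principal-
coordinates embedding; per-site suppression summaries; one-sample and
block-paired t-tests on the MPD statistics.

**Synthetic experiments.**  A seeded Yule-tree and zero-inflated biomass
generator emulating the study design (2 sites x 2 years x 4 blocks x 5
treatments including a two-species mixture and a tilled control), with
suppression multiplier $m(d) = \exp(-\beta_0 - \beta_1 e^{-d/\varphi})$
acting on both occurrence and abundance.  The generating truth is returned
alongside every dataset for recovery tests.

## Worked example

```python
import coverphylo as cp

params = cp.default_params(tree_seed=11, data_seed=11)
tree = cp.simulate_study_tree(params)
table, truth = cp.simulate_experiment(params, tree=tree)
D = cp.patristic_distances(tree)

sup = cp.suppression_summary(table)
print(sup[["site", "treatment", "mean_biomass", "suppression_pct"]].round(1))

rel = cp.relativize_by_pairing(table, D)
vals = rel.loc[rel["defined"], "relativized"]
t = cp.one_sample_test(vals)
print(f"pooled relativized MPD: mean={t.estimate:.4f}, t={t.t_statistic:.2f}, "
      f"df={t.df}, p={t.p_value:.3f}")
```

prints

```
 site     treatment  mean_biomass  suppression_pct
site1        canola         445.6             79.3
site1    cereal_rye         432.9             79.9
site1       control        2150.7              0.0
site1   hairy_vetch         416.0             80.7
site1 rye_vetch_mix         407.8             81.0
site2        canola         617.3             73.0
site2    cereal_rye         491.5             78.5
site2       control        2286.9              0.0
site2   hairy_vetch         492.4             78.5
site2 rye_vetch_mix         408.5             82.1

pooled relativized MPD: mean=0.0545, t=1.48, df=62, p=0.143
```

Every cover treatment suppresses ~73–82% of the ~2.2 t/ha control weed
biomass (the generator's default baseline, $1 - e^{-\beta_0}$ with
$\beta_0 = 1.6$, is ~80%).  The pooled relativized MPD is positive — weeds
trend overdispersed relative to the cover crops — but with the default
moderate relatedness effect this single realization is not significant at
$\alpha = 0.05$.

The same pipeline runs from the shell on real data:

```bash
coverphylo simulate --out-dir demo            # or bring your own inputs
coverphylo all --biomass demo/biomass.csv --tree demo/tree.nwk \
    --seed 1 --n-perm 999 --out-dir demo/results
```

Field data enter as a delimited biomass table (site, year, block, plot,
treatment, taxon, role, biomass; optional quadrat and units columns), a
rooted Newick tree, and an optional `observed_name,tree_name` sister-taxon
substitution table.

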