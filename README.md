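# airway-biogeo

Biogeography analysis of paired airway bacterial microbiota for
asthma research: given 16S OTU tables from protected bronchial brushes
(BB), induced sputum (IS), oral washes (OW) and nasal brushes (NB)
collected from the same adults, the package quantifies how well each
less-invasive sample type reflects the bronchial community, which taxa
the bronchi share with the oral and nasal niches, and how nasal genera
such as *Moraxella* and *Corynebacterium* relate to clinical and
inflammatory markers of atopic asthma.

It is aimed at microbiome researchers who have an OTU count table, a
rooted phylogeny over the OTUs, a Greengenes-style taxonomy and
subject-level clinical metadata — or who want to prototype such an
analysis on the built-in synthetic paired-cohort generator, which
emulates a 45-subject cohort (22 atopic asthmatics, 12 atopic
non-asthmatics, 11 healthy controls; BB/IS/OW triplets for all, NB for
a 27-subject subset) with planted biogeographic and clinical structure.

## What it computes

* **Rarefied alpha diversity.** Counts are multiply rarefied to a common
  depth D (default 26,185 reads, R = 10 draws); per sample the package
  reports richness S, Shannon H = −Σ pᵢ log₂ pᵢ, root-inclusive Faith
  phylogenetic diversity PD, and Pielou evenness J = H / log₂ S, each
  averaged over the ensemble, with paired Wilcoxon contrasts across
  sample types.
* **Phylogenetic beta diversity.** Unweighted UniFrac
  d(A,B) = Σ_unique bₑ / Σ_either bₑ over tree edges e, and normalized
  weighted UniFrac Σ bₑ |p_A(e) − p_B(e)| / Σⱼ dⱼ (p_Aj + p_Bj),
  averaged over the rarefaction ensemble; classical PCoA; intra-subject
  paired distances; a linear mixed-effects likelihood-ratio test of
  sample type on PC1 (random subject intercept); and a permutation
  Mantel test comparing the nasal vs oral phylogenetic contribution to
  the bronchial community.
* **Shared-taxon partitioning.** Per subject, every detected OTU is
  assigned to one region of the presence/absence Venn partition over
  that subject's sites; shared richness and Faith-PD fractions of the
  BB community, ≥20%-of-subjects shared-genus frequency distributions,
  and per-subject genus-profile Pearson correlations between sites.
* **Dominance and clinical associations.** Dominant genus = argmax of
  genus relative abundance; Fisher/chi-square contingency comparisons
  of dominance frequencies; half-LOD cytokine imputation with a
  20%-detection filter; Spearman association scans between prevalent
  (≥3%) genera and clinical covariates with Benjamini–Hochberg control
  (q ≤ 0.2).
* **Three-model differential abundance.** Per taxon, Poisson, negative
  binomial and zero-inflated negative binomial regressions with log
  link, group covariate and log-depth offset
  (log μᵢ = β₀ + β₁ groupᵢ + log depthᵢ); AIC model selection, Wald
  test on β₁, BH correction at q < 0.10.

## Worked example

Generate a synthetic cohort and run the whole pipeline:

```sh
airway-biogeo simulate-and-run --out demo/ --seed 5 --n-taxa 60
# report -> demo/report/index.json
```

or from Python:

```python
from airway_biogeo.simulate import SimulationParams, simulate_cohort
from airway_biogeo.core_io import PipelineConfig
from airway_biogeo.report import run_all

table, taxonomy, phylogeny, clinical, truth = simulate_cohort(
    SimulationParams(seed=1))
report = run_all(table, taxonomy, phylogeny, clinical,
                 PipelineConfig(seed=1))
print(report["profile_correlations"].query("scope == 'all'"))
```

On the seed-1 cohort this prints per-site-pair medians of the
per-subject genus-profile Pearson correlations — `BB-IS` median r =
0.95, `BB-OW` 0.88, `BB-NB` −0.11 — i.e. the bronchial genus profile
tracks sputum closely, the oral wash somewhat less, and the nasal brush
not at all, which is the planted biogeographic structure (bronchial
communities are mostly oral-sourced with a small nasal contribution).
The same run yields mean intra-subject unweighted UniFrac distances to
BB of 0.33 (IS), 0.57 (OW) and 0.82 (NB) in asthmatics, a Spearman
rho of 0.75 between nasal *Moraxella* relative abundance and BAL
eosinophils in asthmatics (the planted inflammation link), and 14 of
71 NB taxa flagged by the three-model scan at q < 0.10, including the
planted *Staphylococcus*-analog enrichment.

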