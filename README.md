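# symptomnet

Psychometric network analysis of symptom questionnaires: estimate a
regularised partial-correlation network over ordinal items, detect symptom
communities, and quantify how well the structure replicates under
resampling.

The package implements the exploratory-graph-analysis (EGA) workflow used
to study demoralisation and depression in medically ill populations — the
Demoralization Scale-II (16 items, scored 0–4) administered alongside the
PHQ-9 (9 items, scored 0–3) — but every stage works on any ordinal
questionnaire given item metadata.

## What it computes

**Network estimation.** Items are modelled with a Gaussian graphical model:
given the item correlation matrix *S*, the precision matrix Θ is estimated
by the graphical lasso,

  Θ̂ = argmax  log det Θ − tr(SΘ) − λ Σᵢ≠ⱼ |θᵢⱼ|,

with the penalty λ chosen along a logarithmic path by the extended Bayesian
information criterion, EBIC = −2ℓ(Θ) + E·log n + 4γ·E·log p (E = number of
edges, γ = 0.5 by default). Edges are partial correlations
p_ij = −θ̂ᵢⱼ/√(θ̂ᵢᵢθ̂ⱼⱼ): the association between two symptoms after
controlling for all others.

**Dimensionality.** Communities of the weighted network are found with the
walktrap algorithm (random-walk distances, agglomerative merging,
maximum-modularity cut) on absolute edge weights. Each community is read as
one latent symptom dimension.

**Preprocessing.** Complete-case filtering, metadata-driven reverse
scoring, Cronbach's α and McDonald's ω (one-factor ML, bootstrap CI), and
redundancy reduction: item pairs whose weighted topological overlap (wTO)
is extreme are flagged, and conceptually overlapping sets are merged into
latent composite nodes (for the DS-II/PHQ-9 instrument this reduces 25
items to 22 nodes).

**Replicability.** A non-parametric bootstrap reruns the whole chain per
resample and reports: the distribution of the number of communities, a
median network, the *structural consistency* of each community (proportion
of replicates reproducing its exact item set), per-item *stability*
profiles, and case-/node-dropping stability of node-strength centrality
summarised by the CS coefficient.

**Ground-truth simulation.** A seeded generator draws ordinal responses
from a correlated-factor graded-response model (thresholds calibrated to
published item moments), with optional injected redundant pairs — so every
stage can be validated against known truth.

## Worked example

```python
import symptomnet as sn

raw = sn.generate(sn.default_raw_study_spec(n=1463, seed=42))  # 25 items
m = sn.combine_items(raw, sn.STUDY_COMPOSITES)                 # -> 22 nodes
result = sn.ega(m)
for c in range(1, result.partition.n_communities + 1):
    print(c, sorted(result.partition.items_in(c)))
```

prints four symptom communities:

```
selected penalty lambda = 0.2054, 75 edges, modularity Q = 0.63
4 communities detected:
  community 1: death, ds_cope, ds_hopeless, ds_pointless, ds_role, helpless, worthless
  community 2: ds_control, ds_hurt, ds_irritable, ds_regret, phq_failure
  community 3: ds_distress, ds_isolated, ds_trapped
  community 4: phq_appetite, phq_concentrate, phq_down, phq_interest, phq_motor, phq_sleep, phq_tired
```

Community 1 gathers the hopelessness/worthlessness core together with
death ideation, communities 2–3 the emotionality and entrapment items, and
community 4 the somatic-depressive PHQ-9 items — the four-dimensional
structure the generator encodes. Bootstrapping the same matrix
(`sn.boot_ega(m, n_iter=100, seed=7)`) reproduces k = 4 in 100/100
replicates with structural consistency 1.00 for every community, and the
case-dropping curve stays above a 0.90 mean correlation up to a 60% drop
(CS coefficient 0.6).

The `examples/` directory holds one short script per capability
(simulation, reliability, redundancy, EGA, bootstrap, centrality, full
pipeline); each prints the numbers above with a line on how to read them.
A thin CLI wraps the same stages:

```sh
symptomnet simulate --n 1463 --seed 42 --out responses.csv
symptomnet pipeline --input responses.csv --out-dir report/
```

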