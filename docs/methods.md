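# Methods

This note documents the statistical model behind `symptomnet`, the choices
made where conventions diverge, and what the synthetic-data validation does
and does not establish.

## Data model and preprocessing

The empirical input is an n × p matrix of ordinal questionnaire responses
with per-item metadata (scale, admissible range, reverse flag). Rows with
any missing item are removed (complete-case analysis; no imputation), and
positively worded items are reverse scored as x → min + max − x before any
correlation is computed. Scoring is driven entirely by metadata: the
shipped DS-II/PHQ-9 metadata marks the "value to others", "coping" and
"self-worth" items as reversed, and the flag set is user-configurable
because item polarity differs across translations.

Item correlations are Pearson by default (Spearman optional). Pearson on
0–4 ordinal scores is the conventional choice for these instruments;
polychoric correlations are not implemented, so all downstream partial
correlations inherit the usual ordinalization attenuation (see
"Simulation" below for how the tests account for this).

## Reliability

Cronbach's α is the classical variance-ratio form. McDonald's ω (total) is
computed from a one-factor maximum-likelihood fit on standardised items:
ω = (Σ|λᵢ|)² / ((Σ|λᵢ|)² + Σψᵢ). Absolute loadings make ω invariant to
item reflection. Heywood cases are clamped to zero uniqueness with a
warning. The 95% CI is a percentile bootstrap over subjects (default 1000
replicates). ω-hierarchical and categorical ω are out of scope.

## Network estimation

The precision matrix solves

  max_Θ≻0  log det Θ − tr(SΘ) − λ Σ_{i≠j} |θᵢⱼ|

with an unpenalised diagonal. The solver is block coordinate descent
(Friedman-style: each column update is a lasso solved by coordinate
descent), JIT-compiled, with exact zeros from soft thresholding. Outer
convergence is declared when no working-covariance entry moves more than
`tol` (default 1e-8); non-convergence and non-PD results are fatal, never
silent. λ = 0 is special-cased to the closed-form MLE S⁻¹. The same kernel
accepts a per-edge penalty matrix, which provides the support-restricted
ML refit (classical covariance selection) used during model selection.

### Penalty selection

Candidates lie on a 100-point logarithmic grid from λ_max = max|sᵢⱼ|
(empty network) down to λ_max/10. Each candidate is scored by
EBIC = −2ℓ + E log n + 4γ E log p with γ = 0.5.

One deliberate departure from the most common implementation: the EBIC is
evaluated on the **support-restricted ML refit** of each candidate edge
set, not on the penalised estimate itself ("relaxed" selection). Scoring
the penalised fit couples selection to shrinkage: as n grows, the
likelihood gain from un-shrinking strong true edges dominates the per-edge
log n penalty, the criterion decreases monotonically along the path, and
the selector runs to the densest grid end (we observed exactly this on
chain-graph data at n = 5000, where the penalised-score variant recovered
the true edge set in 1/20 seeds versus 20/20 for relaxed selection, with
the false-positive edge rate at n = 1000 still ≤ 5%). The refit is used
only for scoring; the returned network is the conventional penalised fit
at the winning λ, so edge weights remain shrunken partial correlations.
The penalised-score variant stays available (`refit_selection=False`).
Exact EBIC ties go to the sparser fit.

### Communities

Walktrap (t = 4 random-walk steps) runs on absolute partial correlations —
transition probabilities require non-negative weights — and the
maximum-modularity cut of the merge dendrogram is returned, with isolated
nodes as singletons and deterministic community labels in order of first
appearance. Two caveats are built in:

* **Unidimensionality.** On data generated by a single factor, walktrap
  tends to return a spurious split whose modularity is near zero (Q ≈ 0.02
  in our checks, versus Q ≈ 0.5 for genuinely clustered study-like data).
  `ega` therefore collapses any multi-community solution with Q below
  `min_modularity` (default 0.05) to one community. The threshold is a
  pragmatic separator between those two regimes, not a tuned constant.
* **Global optimality.** The max-modularity cut is only over partitions in
  the dendrogram. On modular graphs this routinely attains the exhaustive
  global optimum (the test suite verifies equality to 1e-12 on clique,
  chain, ring and planted-block fixtures up to 8 nodes), but on
  structureless random graphs no such guarantee exists and we verified
  counterexamples; community detection on such graphs is not a supported
  use.

Layouts are Fruchterman–Reingold (seeded, deterministic), used only for
plotting.

## Redundancy reduction

wTOᵢⱼ = (Σ_{u≠i,j} aᵢᵤaⱼᵤ + aᵢⱼ) / (min(kᵢ, kⱼ) + 1 − aᵢⱼ) on absolute
weights. Flagging is by upper quantile (default 0.95) of the off-diagonal
wTO distribution, or mean + 2·SD; both thresholds are configurable and
deliberately simple. Which flagged pairs actually measure the same
construct is a conceptual judgement that cannot be automated, so merging
is an explicit user step via composite specifications. Composites are
either the mean of standardised members or a one-factor latent score
(Thurstone regression method; for two-item sets the factor model is not
identified and the symmetric τ-equivalent solution λ = √r is used, making
the score proportional to the members' mean).

## Bootstrap replication

Non-parametric only: each of the `n_iter` replicates resamples n rows with
replacement and reruns correlation → EBIC-glasso → walktrap. Per-replicate
seeds derive deterministically from the master seed, so results are
independent of execution order. Failed replicates are logged and excluded;
more than 20% failures aborts.

Replicate communities are matched to the original partition by maximising
total shared items (assignment problem on the contingency table, solved
optimally); unmatched replicate communities count toward an "extra"
column. Item stability is the proportion of replicates in which an item's
(aligned) community is each original community. Structural consistency of
community c is the proportion of replicates in which the replicate
community aligned to c contains exactly c's item set — a definition under
which consistency can never exceed the smallest member item stability,
and this implication is asserted on every run. The median network is the
elementwise median of replicate edge weights. The community-count CI is
reported both as mean ± 1.96 SD and as 2.5/97.5 percentiles.

## Centrality and its stability

Node strength sᵢ = Σⱼ|pᵢⱼ|. Community loadings: the raw loading of node i
on community c sums i's absolute edges into c with the sign of the
dominant edge restored; each column is standardised by the square root of
the summed absolute raw loadings of the community's own members,
mimicking the factor-loading scale. Case-dropping stability subsamples
(1−f)·n rows **without** replacement per iteration (dropping, not
resampling), re-estimates, and correlates node strengths with the
full-sample values (Pearson over nodes; Spearman optional); node-dropping
removes random node subsets instead. At f = 0 the correlation is exactly
1 by identity and is recorded without re-estimation. Fractions leaving
fewer than 10 rows per node (or fewer than 3 nodes) are skipped with a
warning. The CS coefficient is the largest drop fraction at which ≥ 95%
of subsamples correlate ≥ 0.7 with the full sample (both thresholds
configurable).

## Simulation (ground truth)

The generator draws latent factors from N(0, Φ), forms item latents
Λf + unique noise normalised to unit total variance, and discretises each
through fixed increasing thresholds (graded-response style, preserving the
strong skew of symptom items; rounding cannot). Redundant pairs share a
fraction (default 0.5) of their unique variance. Thresholds are solved so
the analytic ordinal mean (Σₖ(1 − Φ(tₖ + δ)) in a rounded-normal
parametrisation) equals the published reference moment of each item
exactly.

The default study stand-in has 22 items in four communities of sizes
7/5/3/7, primary loadings 0.65, cross-loadings 0.10 between the
hope/meaning and entrapment communities, factor correlations 0.45 within
the demoralisation block and 0.30 with the depressive block; the raw
25-item variant expands the three composites into member pairs with
injected redundancy. The true cross-loading and factor-correlation
magnitudes of the real patient population are unknown — these are
calibration choices, fixed once. The original patient data are not
publicly available, so published results on them serve only as
output-format references.

**What passing tests show — and not.** Synthetic subjects are i.i.d., the
factor model is exactly correct, missingness (when enabled) is uniform
MCAR, and marginal skew matches published moments. Real data violate all
of these to some degree (sampling heterogeneity, local dependence,
informative missingness), and real community structure is less clean:
expect lower structural consistency and replication percentages on
clinical samples than the near-ceiling values the generator produces.

## Problem sizes and determinism

The test suite and the acceptance script use study-scale but bounded runs:
n = 1463 subjects, 50 seeds for recovery rates, 200 bootstrap replicates,
100 case-drop iterations per fraction, 20 seeds for support recovery at
n = 5000. Operational defaults in the CLI/pipeline are larger (10,000
bootstrap, 2,500 case-drop iterations). All randomness flows from
explicit seeds; pipeline outputs are byte-reproducible from the manifest.

## Known limitations

Pearson-on-ordinal attenuation (no polychoric); ω assumes a single common
factor per scale; no parametric bootstrap, no edge-weight CIs, no directed
or mixed models, no alternative community algorithms; conceptual
redundancy confirmation is manual by design.
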