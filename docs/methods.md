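# Methods

## Scoring model

The input is a sparse ligand × pocket matrix of raw affinity scores
(`GlobSum`-style, treated as opaque reals), a manifest splitting ligands
into *query* compounds and a panel of *inactive* reference drugs, and a
pocket → PDB entry → gene annotation table.  For each query ligand `m` and
pocket `p` with an observed score:

* `Zscore_poc(m,p)` standardizes the score against the inactive-panel
  scores observed on pocket `p`;
* `Zscore_mol(m,p)` standardizes it against ligand `m`'s scores over all
  pockets;
* `ZZscore = Zscore_poc + Zscore_mol` is the ranking metric.

Conventions, all recorded in the metadata sidecar written next to every
scored-pairs table:

* **Sample sd (ddof = 1)** in both standardizations.  With a 10-drug panel
  the sample sd exceeds the population sd by ≈ 5%, so the choice is not
  cosmetic; sample sd is the default of the statistical environments these
  pipelines are scripted in.  There is no configuration switch for this —
  the convention is part of the score's definition here.
* **The query's own score is never part of the inactive background**; the
  panel consists of inactive drugs only.
* **The focal pocket's score is part of the ligand's pocketome
  background** (the background is "all pockets", with no leave-one-out).
  At pocketome scale (hundreds to tens of thousands of pockets) the
  focal term's influence on mean and sd is negligible; excluding it would
  complicate the definition without changing rankings.
* **Degenerate backgrounds yield undefined scores, not infinities.**  A
  pocket with fewer than two inactive scores, or a background with zero
  spread, produces a NaN component; such pairs are flagged, counted in the
  metadata, and excluded from ranking and filtering.  Only finite scores
  are ever ranked.
* Inactive ligands themselves can be scored on request (for ROC-style
  simulator work); their pocket background then includes themselves by
  default, with a leave-one-out option.

As a consequence of the double normalization, each query ligand's
`Zscore_mol` values over a complete matrix have mean 0 and sample sd 1
exactly (up to round-off), and the ZZscore ranking is invariant under any
global affine transform of the raw matrix and under additive ligand or
pocket effects.

## Target selection

Thresholds are inclusive (≥) on all three quantities.  Presets: *relaxed*
= (ZZscore 2.0, addends 0.8), *stringent* = (ZZscore 2.0, addends 1.0).
Because the stringent bounds dominate the relaxed ones, stringent output
is a subset of relaxed output pairwise and gene-wise — the monotonicity the
test suite asserts structurally.

Pocket-level filtering happens first; a gene is called for a ligand iff at
least one of its annotated pockets passes all thresholds.  The alternative
— aggregating best components across different pockets of a gene — is
rejected: a gene should not pass on the strength of one pocket's
`Zscore_poc` and another's `Zscore_mol`, since binding happens at a single
pocket.  The reported best pocket is the passing pocket with maximal
ZZscore, ties broken lexicographically by pocket id so outputs are
deterministic.  Passing pockets without a gene annotation are excluded and
counted.  Gene symbols are uppercased and trimmed at ingest, and all set
operations compare case-insensitively; no translation between naming
schemes (UniProt-style vs HGNC-style) is attempted.

## Ordered over-representation analysis

For a per-ligand target list ranked by decreasing best ZZscore, every
prefix of length ℓ = 1…L is tested with the exact hypergeometric upper
tail (overlap with the gene set, prefix size ℓ, universe N); the reported
p is the minimum over prefixes, with the smallest achieving prefix.  This
follows the incremental ordered-query semantics of g:Profiler's `gost`;
its proprietary g:SCS correction is *not* replicated — correction is
plain Benjamini–Hochberg across the tested sets at their best prefixes,
consistent with choosing "fdr" as the correction method.  No internal
multiplicity correction is applied across prefixes, matching the
ordered-query semantics as documented; the minimum-over-prefixes p is
therefore an optimistic per-set statistic and is only compared across sets
corrected the same way.  The default universe is every gene present in the
pocket annotation table — the genes reachable when all pockets are
considered — and can be overridden.

## Preranked GSEA

The running enrichment score is the classic weighted KS-like statistic
with weight exponent q (default 1): hits add `|w|^q / Σ_hits |w|^q`,
misses subtract `1/(N−K)`; ES is the signed maximum-|deviation| value of
the running sum, which conserves to zero at the end of the list.  Ranking
ties are broken lexicographically by gene symbol.  The leading edge
("core enrichment") is the set members at or before the peak (after, for
negative ES).

The null is gene-label permutation: ES values of uniformly random same-size
gene subsets of the ranked list (phenotype permutation does not exist for
preranked input).  NES is **sign-stratified**: ES divided by the mean of
same-sign permuted ES, keeping the sign.  A raw mean over the near-symmetric
null sits close to zero and would make the ratio numerically unstable;
stratification is also what makes positive and negative scores comparable
in magnitude.  The permutation p uses the add-one estimator
`(1 + #{same-sign null ≥ |ES|}) / (1 + #{same-sign null})`, so p is never
exactly zero, and BH adjustment runs across sets.  A set is flagged
significant when adjusted p < α (default 0.05) and NES > 0.  When no
same-sign null value exists the NES is reported as NaN with p = 1.

Randomness: a single integer seed feeds numpy's PCG64 generator; results
are bit-reproducible across runs and platforms.  The default permutation
count is 10 000.  The vectorized null path (batched running-sum matrices,
chunked to bound memory at a few million doubles) is checked against the
scalar scorer distributionally in the tests; the scalar scorer itself
accumulates strictly left to right so that it agrees bit-for-bit with a
definitional position-scan oracle.

## Synthetic pocketome

`score(m,p) = μ + a_m + b_p + ε_mp` with independent Gaussian ligand
effects `a ~ N(0, σ_a²)`, pocket effects `b ~ N(0, σ_b²)` and noise
`ε ~ N(0, σ_ε²)`; planted true interactions add `δ·σ_ε` to chosen
(query, pocket) cells, and a configurable fraction of entries is deleted
at random.  Defaults: 2 query ligands, 10 inactive drugs, 500 pockets,
μ = 50, σ_a = σ_b = σ_ε = 1, δ = 6, no missingness — a small
two-enantiomer study design with nuisance effects of the same scale as
the noise.  One synthetic gene per pocket by default (unambiguous
recovery bookkeeping); a many-pockets-per-gene mode exercises the gene
collapse.  Gene-set collections are built as one planted set (the planted
genes padded with random genes) plus random decoys.

What the simulator emulates: additive row/column confounding, missing
observations, planted high-affinity pairs, gene-level truth.  What it does
not: heavy-tailed or skewed docking-score distributions, correlated pocket
families (paralogs, multiple pockets of one structure), chemistry-driven
similarity between ligands, or any relationship between pocket geometry
and score.  Passing tests therefore demonstrate that the statistical
machinery behaves as specified under the additive model, not that the
thresholds are well calibrated for real docking output.

### What recovery under this model does — and does not — guarantee

Two distributional facts about the default conditions are worth stating
plainly, because the test suite asserts them honestly:

* Both z-scores are standardized to ≈ unit variance and share the noise
  term `ε_mp`, so they are positively correlated (ρ ≈ 0.45 at the default
  scales).  The probability that a *null* pair clears the stringent regime
  is therefore the joint upper tail P(both ≥ 1) ≈ 6% — of that order for
  any additive-Gaussian parameterization (≈ 2.5% even at ρ = 0).  The
  stringent regime controls the false-positive *rate* at the few-percent
  level, not below 1%; with 2 ligands × 500 pockets this yields dozens of
  false calls, which is why precision in the worked example is far from 1
  while recall is 1.
* A planted effect of δ = 6σ_ε translates to a ZZscore boost of about
  `δ/√(σ_a²+σ_ε²) + δ/√(σ_b²+σ_ε²)` ≈ 8, further shrunk when several
  planted outliers inflate their ligand's own background sd.  The minimum
  over ~10 planted pairs and the maximum over ~490 null pairs then overlap
  with appreciable probability: *complete* rank separation of planted from
  unplanted pairs fails on roughly a third of seeds at the default
  conditions, even though threshold-based recall is robustly 1.0.  Recall,
  not perfect separation, is the guarantee the method provides at this
  effect size.

Recovery metrics: gene-level precision `TP/(TP+FP)` (defined as 1.0 when
there are no calls) and recall `TP/(TP+FN)`.

## Numerical and interface choices

* Missing affinities are first-class absences, never imputed as zero.
* Long TSV (`ligand_id`, `pocket_id`, `score`) is the canonical affinity
  layout; wide (pockets × ligands) is a convenience reader.  Writers emit
  shortest-exact float representations so round-trips are bit-exact.
* The hypergeometric tail is evaluated by `scipy.stats.hypergeom.sf` and
  BH by `statsmodels.stats.multitest`; both are cross-checked in the test
  suite against brute-force combinatorial oracles.
* Problem sizes in the test and acceptance runs (hundreds of pockets,
  100-replicate calibration at 1 000 permutations, 100-seed null sweeps at
  500 pockets) are chosen so the full analytic contracts are exercised at
  desk scale; all scale linearly if rerun larger.
* Exit codes of the CLI: 0 success, 2 configuration error, 3 data error.

## Known limitations

* The ordered-query ORA approximates `gost` (BH instead of g:SCS); counts
  of significant pathways will differ from g:Profiler on the same input.
* The minimum-over-prefixes p-value is not corrected across prefixes.
* No attempt is made to model, or correct for, genes represented by many
  pockets (a gene with more pockets gets more chances to pass); the
  many-to-one simulator mode exists precisely to study this.
* Pocket-shape plausibility checks (flagging geometrically irregular
  pockets) are a manual, structure-viewing step outside this package's
  scope.
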