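# Methods

## The model

`maxmif` prioritizes candidate cancer driver genes by integrating two signals
that are individually weak: somatic mutation recurrence and proximity to other
mutated genes in a protein–protein interaction (PPI) network.

**Mutation score.** Somatic calls are binarized into a gene × sample indicator
matrix M(i,j). Each gene receives

    M(i) = Σ_{k ∈ K_i} 1/N_k          (K_i = samples where i is mutated,
                                        N_k = mutated genes in sample k)

so every sample distributes a total weight of exactly 1 over its mutated
genes. This neutralizes the dominance of hypermutated samples: a mutation
observed in a quiet genome (small N_k) is worth more than one buried among
thousands. Genes never observed mutated get the background mutation score
BMS = 1/N_max (N_max = largest per-sample burden), which is by construction
no larger than any mutated gene's score; it keeps unmutated network genes in
the ranking rather than silently dropping them, which matters for small
cohorts.

**Pairwise impact.** For an edge (i,j) with standardized weight W(i,j) ∈ (0,1]
the interaction distance is r_ij = 1/W(i,j) and the mutational impact function
is the gravity-style product

    MIF(i,j) = M(i)·M(j)/r_ij² = M(i)·M(j)·W(i,j)².

**Gene score.** A gene is scored by the strongest impact it shares with any
neighbor,

    S_MaxMIF(i) = max_{j ∈ J_i} MIF(i,j),

falling back to M(i)²/r_max² for genes with no network neighbors (r_max is
the largest interaction distance in the network; the fallback is what the
gene would score against a copy of itself at the network's weakest link, and
is provably ≤ any MIF with a neighbor of score ≥ M(i) at distance ≤ r_max).
A mean-over-neighbors variant (`scorer="mean"`) and a network-free mutation
frequency baseline (`scorer="frequency"`, ranking by |K_i|) are provided for
comparison.

## Assumptions and conventions

- Weights are standardized once, at load, by dividing by the largest retained
  raw weight; self-loops are removed **before** standardization (if a
  self-loop carried the maximum raw weight this ordering changes results; we
  consider a self-loop an artifact, not evidence). Zero or negative input
  weights are rejected rather than clamped, since W = 0 would put a gene at
  infinite distance.
- Duplicate undirected edges collapse to the maximum raw weight (the
  strongest reported evidence wins).
- The default scoring universe is the union of mutation-data genes and
  network genes. Both fallback branches exist precisely for the asymmetric
  cases: network-only genes carry the BMS, mutation-only genes use the
  isolated-gene fallback. `mutated_only` and `network_only` policies are
  available where comparability with other tools requires them.
- Ties in the ranking break by descending mutation score, then ascending
  gene ID — deterministic, reproducible output. The best-neighbor argmax
  breaks ties toward the smaller gene ID.
- Gene identifiers are opaque strings; no identifier remapping is attempted.

## Evaluation

- **ROC/AUC** against a reference gene set, with all non-reference universe
  genes treated as negatives. The AUC uses midrank tie handling (equal to the
  normalized Mann–Whitney U); genes absent from the scoring universe are
  excluded, and `n_positives_in_universe` is reported so the gap to the full
  reference is visible.
- **Paired DeLong test** for comparing two score vectors over the same
  universe, implemented with midrank placement values and a two-sided normal
  p-value. A zero-variance difference with equal AUCs returns p = 1 by
  convention. The implementation is cross-checked in the test suite against a
  paired bootstrap and against R pROC's `roc.test(method="delong")`.
- **F1 vs. rank** for cutoffs 1..500 by default. Recall divides by the FULL
  reference-set size, even when some reference genes are outside the scoring
  universe — this deliberately caps attainable recall so methods with
  different universes are compared on equal footing. F1 is defined as 0 where
  precision + recall = 0.
- **Cumulative recovery** at cutoffs {20, 50, 100, 200, 500}.

## Robustness protocol

Three perturbation scenarios, each applied `repeats` times with per-repeat
seed `base_seed + r` (so repeats are independent yet each reproducible in
isolation, and a single repeat equals a manual run at the base seed):

1. **Sample subsampling** — keep a uniform fraction (reference levels 0.5 and
   0.1) of samples; burdens and N_max are recomputed on the subset.
2. **Edge subsampling** — keep a uniform fraction of edges; weights are *not*
   re-standardized (that would confound the perturbation with a global
   rescale) but r_max is recomputed, since the isolated-gene fallback refers
   to the current network.
3. **Weight noise** — add independent N(0, sd) noise (reference levels 0.1
   and 0.2) to every weight, clamped from below at 1e-20 so all distances
   stay finite; no upper clamp (MIF remains well-defined for W > 1).

Each repeat re-ranks and re-evaluates; the summary reports per-repeat AUCs,
their mean and quantiles, mean cumulative recovery, and the unperturbed
baseline.

## Synthetic benchmark

The generator produces cohort + network + reference-set triples with planted
ground truth, emulating the two features of real tumor cohorts the method
targets:

- a **long-tailed gene frequency spectrum**: passenger gene at frequency rank
  g mutates with per-sample probability ∝ g^(−shape) (default shape 1.5),
  scaled so the expected passenger burden is 30 mutated genes per sample — a
  realistic exome-scale figure; a handful of passengers are mutated in most
  samples while most mutated passengers appear in ≤2 samples;
- **dispersed per-sample burdens**: a lognormal per-sample multiplier
  (sd 0.5, mean 1) emulates the orders-of-magnitude burden variation across
  tumors;
- a **scale-free background network** (preferential attachment, m = 3,
  ~6000 edges over 2000 genes) with Uniform(0,1] weights, into which the 20
  drivers are wired as a connected module whose adjacent edges draw weights
  from N(0.8, 0.1) — drivers are preferentially connected to each other and
  hence to mutated neighbors.

Drivers mutate at a flat per-sample rate of 0.15. Planting couples *both*
signals the score integrates — elevated mutation score and strong proximity
to other mutated genes — which is the regime the method is designed for; a
benchmark with only one signal would not separate MaxMIF from the frequency
baseline. Default sizes (2000 genes × 200 samples, 20 drivers, 10 generator
seeds for benchmark averages, 10 robustness repeats) were chosen as the
package's standard desk-scale benchmark; all are parameters of
`SyntheticSpec` / the scripts.

What passing the benchmark does **not** show: the generator has no mutation
signatures, no copy-number or expression signal, no curated-database
structure in the network, and its reference set is the planted truth (up to
an optional contamination fraction). Results on it demonstrate correctness
and the intended relative behavior of the scorers, not clinical performance
on cohort data.

## Numerical choices

- Scores are plain float64 sums; the all-pairs oracle tests require
  agreement to a relative 1e-12, which only allows for associativity-level
  float differences.
- The DeLong degenerate case (zero variance, nonzero AUC difference) raises
  rather than fabricating a p-value.
- `round(fraction · n)` with a floor of 1 sets subsample sizes; fraction 1.0
  is an exact identity (order preserved).
- Generator streams for matrix / network / reference set are derived from
  `SeedSequence([seed, stream])` so the three artifacts are independent but
  jointly reproducible.

## Known limitations

- Scoring considers direct neighbors only; no propagation/diffusion, so a
  driver two hops from any mutated gene gains nothing from the network.
- The frequency baseline and the mean-MIF variant share the tie-break with
  the max scorer, which can matter at the very top of sparse rankings.
- MAF ingestion distinguishes coding from noncoding genes only via the
  run-level `nonsilent_only` flag, since no annotation source is bundled.
- Reference cancer gene sets (CGC and similar) are licensed resources and are
  not distributed; users supply their own plain-text lists.
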