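# maxmif

Cancer driver gene prioritization by integrating somatic mutation data with
weighted protein–protein interaction (PPI) networks.

Distinguishing the few driver genes that confer a growth advantage from the
many passenger genes mutated along the way is hard because of the long-tail
phenomenon: a handful of genes are mutated in most tumors while most mutated
genes appear in only one or two — so ranking by raw mutation frequency is
both swamped by frequently mutated passengers and blind to rare drivers.
`maxmif` scores each gene by the strongest gravity-style *mutational impact*
it shares with a network neighbor, pulling rarely mutated genes with strongly
mutated interactors to the top of the list. It is aimed at computational
cancer-genomics groups who have a cohort of somatic calls (MAF or binary
matrix), a weighted functional network (HumanNet/STRING-style edge list), and
one or more reference cancer gene lists to validate against.

## Method

With M(i,j) the binarized mutation indicator, N_k the number of mutated genes
in sample k, and K_i the samples where gene i is mutated:

    M(i)        = Σ_{k∈K_i} 1/N_k         (BMS = 1/N_max if K_i = ∅)
    MIF(i,j)    = M(i)·M(j)/r_ij²,  r_ij = 1/W(i,j)
    S_MaxMIF(i) = max_{j∈J_i} MIF(i,j)    (M(i)²/r_max² if J_i = ∅)

Every sample contributes a total weight of 1 regardless of its burden; edge
weights W are standardized to (0,1] by the largest weight; J_i is the
neighbor set of i. Genes are ranked by S_MaxMIF. A mean-over-neighbors
variant and a frequency-only baseline are included, along with the standard
evaluation stack (ROC/AUC, paired DeLong test, F1-vs-rank with full-set
recall, cumulative recovery) and a perturbation-robustness protocol
(sample/edge subsampling, Gaussian weight noise). See `docs/methods.md` for
details and design rationale.

## Worked example

Simulate a planted-driver cohort (2000 genes × 200 samples, 20 drivers wired
into a strongly weighted network module), rank genes, and evaluate:

```sh
maxmif simulate --n-genes 2000 --n-samples 200 --n-drivers 20 --seed 1 --out sim/
maxmif score --matrix sim/matrix.tsv --network sim/network.tsv --out scored/
maxmif evaluate --ranking scored/ranking.tsv --reference sim/reference.txt --out eval/
```

`scored/ranking.tsv` begins:

```
rank  gene      s_maxmif  mutation_score  best_neighbor
1     PSG00004  14.5086   11.3987         PSG00010
2     PSG00010  14.5086    3.4959         PSG00004
3     DRV014     6.1394    3.0016         DRV018
4     DRV018     6.1394    2.2900         DRV014
5     DRV003     4.4043    1.8065         DRV014
```

Two hypermutated passengers that happen to interact top the list (their
mutation scores 11.4 and 3.5 multiply across one strong edge), but the
planted drivers fill the ranks behind them via their module edges — each
driver's best neighbor is another driver. `eval/evaluation.json` reports:

```json
{
  "auc": 0.9985,
  "recovery": {"20": 17, "50": 20, "100": 20, "200": 20, "500": 20},
  "max_f1": 0.909,
  "n_positives_in_universe": 20,
  "n_reference_total": 20
}
```

AUC 0.9985 means a planted driver outscores a random passenger 99.85% of the
time; 17 of the top 20 and all 20 of the top 50 candidates are true drivers.
The frequency baseline (`--scorer frequency`) reaches only 5 of 20 at rank
20 on the same instance — the frequent passengers fool it. Robustness:

```sh
maxmif robustness --matrix sim/matrix.tsv --network sim/network.tsv \
    --reference sim/reference.txt --perturb samples --level 0.5 \
    --repeats 10 --seed 0 --out rob/
# mean AUC 0.9985 (baseline 0.9985) over 10 repeats
```

Halving the cohort leaves the mean AUC essentially unchanged.

Real data plug in the same way: `--maf cohort.maf` for TCGA-style MAF input
(nonsilent variants retained by default), a 3-column `gene_a  gene_b  weight`
TSV for the network, and one gene ID per line for each reference set.

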