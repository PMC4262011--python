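# discretus

Tools for asking how *discrete* species are on time-calibrated gene trees:
delimit clusters with a single-threshold mixed Yule/coalescent model,
measure within- and between-cluster variation, compute neutrality
statistics, estimate net diversification rates, and test rate constancy
with under-sampling corrections — plus a simulator that generates the
sampling structures the analyses assume, so the whole pipeline is testable
offline.

## What's inside

| module | purpose |
| --- | --- |
| `discretus.io_core` | FASTA/Newick IO, haplotype collapsing, raw p-distances, validated ultrametric trees |
| `discretus.gmyc` | single-threshold two-class (diversification vs. coalescent) delimitation with LR test |
| `discretus.discreteness` | per-cluster nucleotide diversity, TMRCA, nearest-neighbor raw/patristic distances |
| `discretus.popgen` | Tajima's D, Fu & Li D\*/F\*, Fu's Fs, Ramos-Onsins & Rozas R2 per delimited species |
| `discretus.diversification` | species-tree pruning, pooled birth-death ML + LR validation, gamma statistic, Monte-Carlo and imputation corrections |
| `discretus.compare` | rank-sum tests, Cohen's d, noncentral-t power, dataset-blocked permutation comparison |
| `discretus.synthetic_data` | birth-death species trees, coalescent-within-species gene trees, Jukes-Cantor alignments, scenario presets |
| `discretus.workflow` | per-dataset glue used by the CLI and the tests |

## CLI

```bash
# simulate a bundle of datasets (trees + alignments + metadata + truth)
discretus simulate --preset sexual_like --seed 1 --out scenario/

# validate a tree/alignment/metadata triple
discretus io validate --tree T.nwk --aln A.fasta --meta M.tsv

# species delimitation
discretus gmyc --tree scenario/sexual_like_1/gene_tree.nwk \
    --out fit.json --partition partition.tsv

# per-species discreteness metrics and neutrality statistics
discretus metrics --dataset scenario/sexual_like_1 --out metrics.tsv
discretus popgen  --dataset scenario/sexual_like_1 --out popgen.tsv

# diversification rates, LR test, gamma with corrections, LTT export
discretus divrate --trees trees/ --groups groups.tsv --out rates.json \
    --gamma-out gamma.tsv --ltt-out ltt.tsv --mccr-reps 1000 --seed 42

# group comparisons over a tidy metrics table
discretus compare --metrics metrics.tsv --by clade --block dataset
```

`groups.tsv` is a two-column TSV (`tree`, `group`) naming Newick files in
the `--trees` directory.

The blocked-permutation comparison is a documented stand-in for
mixed-effects modeling, not an equivalent of it; its output says so.

## Notes on conventions

- Haplotype identity is exact string equality after uppercasing; gaps and
  ambiguity codes count as differing characters.
- p-distances use pairwise deletion of gap/`N` sites; neutrality
  statistics use complete deletion and are computed on sequences
  (haplotypes expanded by multiplicity).
- Trees must be rooted, binary and ultrametric within a relative
  tolerance (default `1e-6`); they are rejected, not rescaled.
- The delimitation LR test defaults to 2 degrees of freedom (threshold
  profiled); 3 is available via `fit_gmyc(..., df=3)` and `--df`.
- Birth-death fits screen the extinction fraction with a one-sided
  boundary likelihood-ratio rule by default; pass
  `eps_selection="ml"` for raw maximum likelihood.
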