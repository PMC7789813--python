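# exoref

Reference-gene discovery for exosome expression data.

Given a gene×sample (or miRNA×sample) count matrix and a sample design
(case groups vs healthy controls), `exoref` reproduces an unbiased
candidate-reference screening and stability-ranking pipeline:

1. **Normalize** counts to TPM (gene lengths required) or CPM; qPCR Ct
   tables are converted to abundances as 2^−Ct.
2. **Screen** each case group against the controls with a
   negative-binomial Wald test (median-of-ratios size factors,
   trend-moderated method-of-moments dispersion); features with p > 0.1 in
   *every* group are called non-differentially expressed.
3. **Filter** the universal non-DE set for expression above the pooled
   transcriptome average in both cases and controls, then keep the top N
   by expression.
4. **Score stability** by the coefficient of variation (CV) and the
   average pairwise-variation value M (standard deviation of pairwise
   log2 expression ratios, averaged per feature), optionally adding a
   group-aware (NormFinder-style) score.
5. **Rank** candidates by the sum of their CV and M ranks, and score
   multi-feature reference combinations by the geometric mean of member M
   values (AV), either over consecutive rank blocks or exhaustively.

A synthetic-data module generates negative-binomial count matrices with
heterogeneous library sizes and *planted* stable features (high
expression, no group effect, low dispersion), so the full pipeline is
testable end to end with known ground truth.

## CLI

```sh
# simulate a dataset (counts.tsv, design.tsv, truth.tsv, lengths.tsv)
exoref simulate --seed 42 --out-prefix sim/

# screening cascade -> per-feature table + candidate list
exoref screen --counts sim/counts.tsv --design sim/design.tsv \
              --lengths sim/lengths.tsv --p-threshold 0.1 --top-n 10 \
              --out screen.tsv

# stability scoring and rank-sum aggregation
exoref stability --matrix tpm.tsv --design sim/design.tsv \
                 --scorers cv,m,normfinder --out stability.tsv

# combination stability (rank blocks or exhaustive)
exoref combos --stability stability.tsv --size 3 --out combos.tsv

# full pipeline from a YAML config
exoref run --config config.yaml
```

Minimal `config.yaml`:

```yaml
mode: mRNA            # mRNA | miRNA | qPCR
counts: sim/counts.tsv
lengths: sim/lengths.tsv
design: sim/design.tsv
p_threshold: 0.1
top_n: 10             # default: 10 mRNA, 6 miRNA
combo_sizes: [3]      # default: [3] mRNA, [2] miRNA
out_dir: out/
```

All matrices are TSV, features as rows and samples as columns; the design
table has columns `sample`, `group`, `condition` (`case`/`control`); Ct
tables may be wide or long (`feature,sample,ct`).

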