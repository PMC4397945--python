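# bayestx

Bayesian reference-based transcriptome assembly from paired-end spliced
RNA-seq alignments.

`bayestx` builds per-locus splice graphs from a SAM/BAM file, enumerates
candidate transcripts by exhaustive path search with iterative
coverage-threshold pruning, and infers which candidates are expressed with a
Gibbs sampler under a spike-and-slab model: a truncated-Bernoulli prior over
binary expression indicators combined with symmetric-Dirichlet abundances
and a Dirichlet-multinomial assignment of fragments to candidates. The
fraction of post-burn-in iterations in which a candidate has positive
abundance is its *confidence*; the final assembly keeps candidates with
confidence above 0.5 and an expected fragment count of at least 12, and is
written as GTF.

A self-contained simulator draws loci, expression states, abundances and
fragments from the same generative model and emits SAM plus truth
annotation, so the whole package can be built and tested offline.

## Command line

```bash
# simulate a toy dataset (SAM + truth GTF + truth table)
bayestx simulate --out-dir sim --seed 1 --n-loci 5 --fragments-per-locus 1000

# assemble
bayestx assemble --bam sim/simulated.sam --output assembly.gtf \
    --library-type fr-firststrand --seed 1 --report report.json

# score the assembly against the truth annotation
bayestx evaluate --predicted assembly.gtf --truth sim/truth.gtf
```

`assemble` accepts `--library-type {unstranded,fr-firststrand,fr-secondstrand}`,
`--pi` / `--gamma` to override the sparsity and Dirichlet hyperparameters
(by default pi is estimated per locus by greedy set cover and gamma is 1),
`--frag-mu` / `--frag-sigma` to bypass the robust fragment-length estimation,
`--max-candidates`, `--confidence-threshold`, `--min-expected-count`,
`--threads`, and `--config file.yaml` (CLI flags win over the config file).
Results are deterministic for a fixed `--seed`, independent of `--threads`.

## Library layout

| module                  | responsibility                                         |
| ----------------------- | ------------------------------------------------------ |
| `bayestx.alignment_io`  | SAM/BAM loading, read filters, fragment strand         |
| `bayestx.splice_graph`  | locus clustering, strand resolution, splice-graph DAGs |
| `bayestx.candidates`    | path enumeration with pruning, pre-mRNA candidate, junction filter, graph merging |
| `bayestx.fragment_model`| fragment-length estimation, effective lengths, likelihood matrix |
| `bayestx.inference`     | sparsity prior estimation, Gibbs sampler, exact enumeration oracle |
| `bayestx.assembly`      | posterior summaries, thresholds, GTF reading/writing   |
| `bayestx.simulate`      | generative-model simulator and intron-chain matching   |
| `bayestx.cli`           | end-to-end orchestration and subcommands               |

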