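# hlabayesnt

Bayesian HLA genotyping and germline/somatic mutation calling from
paired normal/tumor sequencing reads.

HLA class I and II genes are hyperpolymorphic, surrounded by highly
similar paralogous genes and pseudogenes, and often covered only thinly
in whole-genome data. Standard variant callers built around a single
linear reference miss genotypes and mutations there. This package
re-genotypes the HLA region directly against an allele reference panel
and calls germline and somatic variation jointly from the normal and the
tumor sample, so that tumor reads inform the germline haplotypes and
vice versa. It is intended for method developers and computational
biologists working on cancer immunogenomics who need an inspectable,
testable implementation with an exactness-validated sampler.

## Model

For one locus with panel alleles `t_1..t_K` (aligned into a common MSA
coordinate system of length `N`, with allele-frequency priors `p_t`),
the latent state is

* `R` — two genotype reference picks plus `nu_d` decoy picks (decoys
  absorb reads that truly come from paralogs),
* `S^(n)`, `S^(t)` — matched normal and tumor haplotype sequences over
  `{A,C,G,T,N,-}`; `p(S^(n)|R)` allows germline deviations (rarer at
  originally sequenced reference bases than at imputed ones, rarer on
  genotype haplotypes than on decoys) and `p(S^(t)|S^(n))` allows
  somatic substitutions, indels, and Ns at small per-position rates,
* `F` — per-haplotype read-generating propensities (log-normal priors;
  decoys are biased low),
* `G` — the normal-cell fraction of the tumor sample (log-normal
  prior): tumor reads may be emitted by a *normal* haplotype,
* `V` — per-column validity flags restricting where each decoy may
  explain reads (Markov-chain prior; genotype rows are always valid),
* `I` — per-read-pair origin indicators with prior
  `p(I_i = m) ∝ max_{n∈r_i} V_{m,n} · F_m` (times `G` for normal-origin
  tumor reads).

Reads enter in MSA coordinates with per-base Phred qualities; emissions
use the mismatch probability `q = 10^(-b/10)`. The posterior

```
p(R, S^(n), S^(t), F, G, V, I | X^(n), X^(t))
  ∝ p(X^(n)|S^(n),I) p(X^(t)|S^(n),S^(t),I)
    p(S^(t)|S^(n)) p(S^(n)|R) p(R)
    p(I^(n)|F,V) p(I^(t)|F,G,V) p(F) p(G) p(V)
```

is sampled by MCMC: Gibbs scans for sequences, reference picks, and
indicators; Metropolis-Hastings for `F` and `G`; a Wolff-style cluster
move for validity flags; decoy-swap, tumor-phase-swap, and blocked
type+sequence moves against multimodality; multistart initialization and
parallel tempering. Genotypes are called by counting sampled allele
pairs; mutations by counting per-column disagreements (reference vs.
normal = germline, normal vs. tumor = somatic) with a posterior support
threshold.

Upstream, reads overlapping the extended HLA region
(chr6:28,477,797-33,448,354 on GRCh37; chr6:28,510,120-33,480,577 on
GRCh38) are scored against every panel allele (length reward plus
quality-weighted mismatch and affine gap penalties), assigned to at most
one locus by an absolute-score and a best-vs-second-locus margin
criterion, and realigned into MSA columns via their best allele.

## Worked example

Simulate a small paired normal/tumor data set and genotype it:

```
hlabayesnt simulate --out demo --n-alleles 12 --msa-length 200 \
    --coverage-normal 25 --coverage-tumor 50 --n-somatic 1 --seed 11
hlabayesnt genotype --panel demo/panel_msa.txt \
    --paralog-panel demo/paralog_msa.txt \
    --frequencies demo/frequencies.tsv \
    --normal-fastq demo/normal_R1.fastq demo/normal_R2.fastq \
    --tumor-fastq demo/tumor_R1.fastq demo/tumor_R2.fastq \
    --out demo/reports --seed 1 --sweeps 300 --burn-in 160
```

which prints

```
genotype: A*01:01 / A*01:02 (support 1.00); 3 mutation call(s); reports in demo/reports
```

The genotype line gives the modal sampled allele pair and the fraction
of posterior draws supporting it (here the planted truth,
`A*01:01/A*01:02`, at full support). The three mutation calls are the
two planted germline substitutions and the planted somatic
substitution; `demo/reports/mutations.tsv` lists each with its MSA
column, projected allele position, class, and posterior support, e.g.

```
locus  column  allele_pos  ref  alt  kind          class     support  feature  haplotype
A      98      98          A    C    substitution  germline  1.0000   exon     1
```

`demo/reports/` also contains `genotype.tsv`, consensus haplotype
FASTA, and the MCMC trace; the planted truth for comparison is in
`demo/truth.json`.

The same workflow is available as library calls
(`reference_panel.synthesize_panel` / `parse_msa`,
`read_pipeline.build_locus_read_set`, `sampler.run_mcmc`,
`calls.call_genotype` / `call_mutations`); see `docs/methods.md` for the
model and parameter details.

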