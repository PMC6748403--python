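# Methods

This note documents the model, the numerical and design choices, the
synthetic data generator, and the known limitations.

## Model

### Read emissions

Reads are realigned into MSA coordinates, so a read covers a contiguous
column span and at each covered column shows a base, a gap, or `N`. The
per-position emission `p(x | s, q)` of read symbol `x` from haplotype
symbol `s`, with the Phred-derived mismatch probability
`q = 10^(-b/10)`, is:

| haplotype `s` | read `x` | probability |
|---|---|---|
| base | same base | `(1 - π_ed - π_eN)(1 - q)` |
| base | other base | `(1 - π_ed - π_eN) · q/3` |
| base | gap | `π_ed` |
| base | `N` | `π_eN` |
| gap | base | `π_ei / 4` |
| gap | gap | `1 - π_ei - π_eN` |
| gap | `N` | `π_eN` |
| `N` | base | `(1 - π_ed - π_eN) / 4` |
| `N` | gap | `π_ed` |
| `N` | `N` | `π_eN` |

`π_ed`, `π_ei`, `π_eN` are the spurious-deletion, spurious-insertion,
and N-call rates of the sequencer. Every row sums to one (tested by
enumeration). Read insertions relative to the MSA have no column of
their own; they are kept aside, attached to the preceding column, and do
not enter the likelihood — a deliberate simplification that keeps the
covered-position set a plain column interval.

### Sequence priors

The somatic prior `p(S^(t)_{m,n} | S^(n)_{m,n})` and the germline prior
`p(S^(n)_{m,n} | R_{m,n})` share one categorical structure
parameterized by (substitution, deletion, insertion, N) probabilities:
from a base, identity keeps the remaining mass, each other base gets
`π_sub/3`, gap gets `π_del`, `N` gets `π_N`; from a gap, each base gets
`π_ins/4` and the gap keeps the rest; from an `N`, bases are uniform
with the deletion/N mass reserved. The germline probability set is
selected per position by (genotype row vs. decoy) x (originally
sequenced vs. imputed reference base), with the constraint — validated
at configuration load — that imputed positions and decoys are at least
as permissive as their counterparts.

### Defaults

None of the probability constants are dictated by data in this release;
they are design values, all overridable via YAML:

| group | default | rationale |
|---|---|---|
| read errors `π_ed, π_ei` | 1e-3 | typical short-read indel error scale |
| read `π_eN` | 1e-4 | N calls are rare after base calling |
| somatic `π_s,*` | 1e-4 each | somatic events are rare per position |
| germline, genotype rows, original | 1e-3 each | novel alleles differ from their nearest panel allele at few sites |
| germline, imputed positions | x10 | imputation mistakes are likelier than real variants |
| germline, decoy rows | x10 | decoys must track paralogous sequence |
| `F` prior, genotype rows | LN(0, 0.5²) | both haplotypes produce reads at similar rates |
| `F` prior, decoys | LN(-2.5, 0.5²) | see below |
| `G` prior | LN(-1.5, 1²) | normal contamination around 0.2, weakly informative |
| validity `π_vo, π_ve` | 0.01, 0.99 | decoy validity comes in long runs |
| decoys `ν_d` | 2 | one per plausible contaminating paralog class |
| filter `θ` (paired) | score > 0, margin > 10 | margin dominates; see filtering |
| filter `θ` (single-end) | 20 / 20 | stricter without a mate |

The decoy `F` prior deserves its own paragraph. A decoy whose `F` can
drift to the genotype-row scale for a trivial prior cost can impersonate
a missing second allele: "homozygous + decoy carries the other
haplotype" then matches or beats the true heterozygote in posterior
mass and genotyping collapses — the sampler reconstructs the haplotype
perfectly but files it under the wrong label. With location -2.5 and
scale 0.5, running a decoy at `F ≈ 1` costs roughly 12 log units while
the intended regime (`F ≈ 0.15-0.2`, absorbing the ~10% paralog read
fraction) stays cheap. This is the package's sharpest prior; loosening
it is the quickest way to reintroduce heterozygote collapses, and
tightening it further would suppress genuine paralog absorption.

## Sampler

One sweep runs: a per-position Gibbs scan of all `S^(n)` then `S^(t)`
symbols (exact conditionals combining germline, somatic, and the
sufficient statistics of currently assigned reads); a Gibbs scan of all
reference picks; a joint Gibbs redraw of all indicators; MH updates of
each `F_m` and of `G` (log-normal random walks — symmetric in the log,
with the Jacobian included so the chain targets the density of the
parameter itself); and a Wolff-style cluster move per decoy validity
row. Every fifth sweep adds the multimodality moves:

* **decoy swap** — exchange a sequence interval (both normal and tumor
  content) between a genotype row and a decoy, refresh the two reference
  picks and all indicators from their conditionals, and accept with the
  reference- and indicator-marginalized ratio. Half of the interval
  proposals use the decoy's longest valid run so that a whole haplotype
  stranded on a decoy can migrate in one move (the interval distribution
  depends only on `V`, which the swap preserves, so the kernel stays
  symmetric).
* **tumor-phase swap** — exchange a tumor-only interval between a
  genotype row and any other row with tumor indicators refreshed and
  marginalized. This dissolves two specific traps: a heterozygous site
  phased oppositely in the normal and tumor samples (which reads as two
  reciprocal somatic substitutions), and somatic content adopted by a
  decoy (whose permissive germline prior accepts a new indel about 100x
  more readily than the somatic prior does).
* **somatic reset** — redraw a window of one tumor row from the somatic
  prior with indicators refreshed; the proposal density cancels against
  the prior, leaving a pure marginal-evidence ratio. This removes
  spurious tumor-only deviations that survive read reassignment.
* **blocked type+sequence move** — propose a row's reference pick and
  matched sequences from a ladder conditioned on coverage-masked
  sequences (positions covered by no read count as `N`, hence carry no
  weight), refresh all indicators, and accept with the marginalized
  ratio; the reverse ladder density is evaluated under the proposal's
  own coverage mask. This is the move that jumps between genotype modes.

Every acceptance ratio was derived so the kernel leaves the exact
posterior invariant, and each move class is checked against brute-force
posterior enumeration on tiny loci (the acceptance suite runs five such
configurations at 1e5 sweeps each).

Burn-in heuristics — copying references over the haplotype sequences
with an immediate indicator refresh, and pushing reads with more than 15
mismatches against both genotype references onto a decoy — run only
inside the multistart pilots (8 pilots of 50 sweeps by default,
alternating heuristics on and off; pilots are additionally seeded from
the alleles most voted for by per-mate best alignments). The best pilot
by log posterior seeds a parallel-tempering ladder (geometric,
T = 1..3.375 by default) whose unit-temperature chain supplies the
retained samples. The production ladder runs pure MCMC, so every
retained draw is a posterior draw. All randomness flows from one seed
through per-chain generator streams; runs are byte-reproducible.

Tempering scales all log-conditionals by the inverse temperature,
including the marginalized quantities inside acceptance ratios;
adjacent-rung exchanges use the standard
`(β_a - β_b)(E_b - E_a)` ratio on the untempered log posterior.

## Filtering stage

Mates are aligned locally (affine gaps, BWA-like scores 2/-4, gap
-6/-1) to every gap-stripped panel allele; alignments scoring below 30
count as unmapped. The HR score of an alignment is a per-column sum:
`+α_r` per aligned read base, `α_N` for columns containing `N`, affine
deletion/insertion penalties (first gap column charges the opening
penalty), and `log10(q)` per substituted base — so a Phred-30 mismatch
costs 3 score units against a +1/base reward. A pair is kept for a locus
only if its summed per-mate maxima clear an absolute threshold and beat
the best other locus by a margin; the margin criterion is what rejects
paralog reads, which align well everywhere but best at their own locus.
The retained read is realigned into MSA columns through its best-scoring
allele.

## Synthetic data

The generator mirrors the model's causal story: genotype drawn from the
allele-frequency prior, germline substitutions on the two haplotypes,
clonal or subclonal somatic events in the tumor, fragments drawn
uniformly with Phred-calibrated substitution errors, a configurable
fraction of fragments from a diverged paralog, and tumor purity mixing
normal fragments into the tumor sample. The reference scenario
(`simulate.default_scenario`) uses a 20-allele panel of 250 columns at
2% divergence with one paralog at 20%, two germline substitutions,
30x/60x coverage at Phred 30 with 80-bp paired reads, purity 0.8, 10%
paralog contamination, and one clonal somatic substitution plus one
clonal 2-bp deletion (expected VAF 0.4). Planted events are placed at
least 80 columns from the locus ends — inside fully covered sequence,
as real exonic hotspots are — and at least 10 columns apart so each is
separately observable. Locus size and chain lengths in the validation
experiments are set so a full 40-replicate study runs in minutes on one
core.

What the generator does **not** emulate: sequencer-specific error
profiles and quality-score miscalibration, coverage biases (GC,
mappability), multi-locus interference beyond a single paralog,
structural variation beyond small indels, and the nomenclature depth of
a real allele database. Passing the recovery tests therefore
demonstrates correctness of the inference given the model's own
generative assumptions at realistic depths — not robustness to every
artifact of production sequencing data.

## Calling

Genotypes: unordered sampled allele pairs are pooled (label switching),
truncated to the requested nomenclature field, and the modal pair is
reported with its sample fraction as support. Mutations: per haplotype
and column, the support of an alternative symbol is the fraction of
draws in which the target sequence shows that symbol while the source
differs; a source softened to `N` (the sampler's way of expressing
residual uncertainty at a mutated site) still counts toward support, and
the reported reference symbol comes from the informative draws. Adjacent
same-kind indel columns merge into one left-aligned event whose support
is the minimum over its columns; events are also projected onto
gap-stripped coordinates of the modal called allele. The default support
threshold is 0.8. A genotype call is flagged as a potential novel allele
when the consensus normal haplotype matches no panel allele over the
exonic columns.

Indel calls inherit the placement ambiguity of alignment: a deletion
inside a repeat may be reported shifted by a column or two relative to
the planted position (the resulting sequence is identical); consumers
comparing against a truth set should compare left-normalized events.

## Numerical notes

All probability machinery is in log space; categoricals are sampled by
max-shifted exponentiation (no underflow up to 1e4 columns). MSA columns
are 1-based at every public boundary (reports, TSVs, `RealignedRead`)
and 0-based internally. Hamming-distance ties during imputation break
by ascending allele name; distances are normalized by the count of
mutually known columns and donors are consulted in distance order until
every unknown cell is filled. The hot loops (emission matrices, read
statistics, Gibbs scans) are numba-compiled, take an explicit numpy
`Generator`, and are shared between the production sampler and the
per-move public API, so the exactness tests exercise the same code the
pipeline runs.

## Limitations

* Single-locus inference: loci are genotyped independently after the
  shared filtering step; no joint modeling across loci.
* Class II loci inherit whatever incompleteness the panel has; heavily
  imputed panels dilute the germline prior's discrimination.
* `G` (normal contamination) is identified only through somatic
  differences; in mutation-free samples its posterior follows the
  prior.
* Very short or low-complexity loci can defeat the margin criterion if
  the paralog panel is not supplied to the filter.
* The sampler's exactness is verified on enumerable loci; at production
  scale, convergence is assisted but not guaranteed — the multistart +
  tempering defaults were chosen to pass 20/20-replicate recovery
  studies at desk scale, and harder instances may need longer chains.
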