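"""Turning posterior samples into genotype, germline, and somatic calls.

Genotyping counts sampled allele pairs (unordered, pooled over label
switching) and reports the modal pair with its sample fraction as
support.  Mutation calling compares, per haplotype and MSA column, the
reference allele against the sampled normal haplotype (germline) or the
normal against the tumor haplotype (somatic); a call is emitted when the
fraction of samples agreeing on the same alternative symbol reaches the
support threshold.  Adjacent gap columns merge into single left-aligned
indel events.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from hlabayesnt.alphabet import GAP, N as N_SYM, SYMBOLS, decode
from hlabayesnt.reference_panel import AlleleMSA
from hlabayesnt.sampler import PosteriorSamples

__all__ = [
    "GenotypeCall",
    "MutationCall",
    "call_genotype",
    "call_mutations",
    "write_reports",
    "truncate_allele",
]

#: Default support threshold for reporting a mutation.
DEFAULT_SUPPORT_THRESHOLD = 0.8


def truncate_allele(name: str, resolution: str) -> str:
    """Truncate an allele name to first/second/third field resolution."""
    n_fields = {"first": 1, "second": 2, "third": 3}[resolution]
    locus, _, rest = name.partition("*")
    fields = rest.split(":")
    return f"{locus}*{':'.join(fields[:n_fields])}"


@dataclass
class GenotypeCall:
    """The modal sampled allele pair of one locus."""

    locus: str
    alleles: tuple
    support: float
    resolution: str = "third"
    pair_supports: dict = field(default_factory=dict)
    novel_allele: bool = False


@dataclass
class MutationCall:
    """One called variant, in MSA and projected allele coordinates."""

    locus: str
    column: int          # 1-based MSA column (leftmost for indels)
    allele_pos: int      # 1-based position on the called allele sequence
    kind: str            # substitution | insertion | deletion
    ref: str
    alt: str
    mutation_class: str  # germline | somatic
    support: float
    feature: str = ""
    haplotype: int = 0


def call_genotype(samples: PosteriorSamples, locus: str = "",
                  resolution: str = "third",
                  msa: AlleleMSA = None) -> GenotypeCall:
    """Modal unordered genotype pair across retained samples.

    ``resolution`` truncates allele names to the requested field before
    counting.  When ``msa`` is supplied, the call is flagged as a novel
    allele if the consensus normal haplotype differs from every panel
    allele at some exonic column.
    """
    if samples.n_samples < 1:
        raise ValueError("no retained samples")
    counts: dict = {}
    for a, b in samples.genotype_pairs():
        key = tuple(sorted((truncate_allele(a, resolution),
                            truncate_allele(b, resolution))))
        counts[key] = counts.get(key, 0) + 1
    total = samples.n_samples
    supports = {k: v / total for k, v in counts.items()}
    best = max(supports, key=lambda k: (supports[k], k))
    novel = False
    if msa is not None:
        novel = bool(flag_novel_alleles(samples, msa).any())
    return GenotypeCall(locus=locus or (msa.locus if msa else ""),
                        alleles=best, support=supports[best],
                        resolution=resolution, pair_supports=supports,
                        novel_allele=novel)


def _consensus(seqs: np.ndarray) -> np.ndarray:
    """Columnwise modal symbol of an ``(n_samples, N)`` symbol matrix."""
    out = np.empty(seqs.shape[1], dtype=np.uint8)
    for col in range(seqs.shape[1]):
        out[col] = np.bincount(seqs[:, col], minlength=6).argmax()
    return out


def flag_novel_alleles(samples: PosteriorSamples, msa: AlleleMSA) -> np.ndarray:
    """Per genotype haplotype: does its consensus differ from every panel
    allele at some exonic column?"""
    exonic = np.array([str(f).startswith("exon") for f in msa.feature_map])
    out = np.zeros(2, dtype=bool)
    for m in range(2):
        cons = _consensus(samples.S_n[:, m, :])
        matches_any = False
        for k in range(msa.n_alleles):
            if (cons[exonic] == msa.rows[k][exonic]).all():
                matches_any = True
                break
        out[m] = not matches_any
    return out


def _allele_position(msa: AlleleMSA, allele_idx: int, column: int) -> int:
    """1-based gap-stripped position of a 1-based MSA column on an allele
    (the preceding base position if the allele is gapped there)."""
    row = msa.rows[allele_idx][:column]
    pos = int((row != GAP).sum())
    return max(pos, 1)


def call_mutations(samples: PosteriorSamples, msa: AlleleMSA,
                   mutation_class: str = "somatic",
                   support_threshold: float = DEFAULT_SUPPORT_THRESHOLD) -> list:
    """Call per-column variants supported by the posterior samples.

    Germline calls compare the sampled reference allele row against the
    normal haplotype; somatic calls compare normal against tumor.  Per
    haplotype and column, the support of the modal (ref, alt) combination
    with differing symbols is its sample fraction; calls at or above the
    threshold are kept.  Runs of adjacent same-kind calls merge into one
    event (support of a merged event is the minimum over its columns);
    events involving ``N`` are not reported.
    """
    if mutation_class not in ("germline", "somatic"):
        raise ValueError("mutation_class must be 'germline' or 'somatic'")
    S = samples.n_samples
    if S < 1:
        raise ValueError("no retained samples")
    panel_rows = np.array([msa.rows[k] for k in range(msa.n_alleles)])
    calls = []
    for m in range(2):
        if mutation_class == "germline":
            refs = panel_rows[samples.R_idx[:, m]]
            alts = samples.S_n[:, m, :]
        else:
            refs = samples.S_n[:, m, :]
            alts = samples.S_t[:, m, :]
        diff = refs != alts
        per_col = {}
        for col in np.flatnonzero(diff.any(axis=0)):
            cand = diff[:, col] & (alts[:, col] != N_SYM)
            if not cand.any():
                continue
            alt_sym = int(np.bincount(alts[cand, col], minlength=6).argmax())
            # support: samples whose alternative agrees and whose source
            # symbol differs (a source N counts as "not carrying the alt",
            # so a variant partly hidden behind N keeps its support)
            support = float(((alts[:, col] == alt_sym)
                             & (refs[:, col] != alt_sym)).mean())
            if support < support_threshold:
                continue
            informative = (refs[:, col] != alt_sym) & (refs[:, col] != N_SYM)
            if not informative.any():
                continue
            ref_sym = int(np.bincount(refs[informative, col],
                                      minlength=6).argmax())
            if ref_sym == GAP and alt_sym == GAP:
                continue
            if alt_sym == GAP:
                kind = "deletion"
            elif ref_sym == GAP:
                kind = "insertion"
            else:
                kind = "substitution"
            per_col[int(col)] = (kind, ref_sym, alt_sym, float(support))
        # merge adjacent same-kind indel columns, left-aligned
        consensus_allele = int(np.bincount(samples.R_idx[:, m]).argmax())
        used = set()
        for col in sorted(per_col):
            if col in used:
                continue
            kind, ref_sym, alt_sym, support = per_col[col]
            ref, alt = SYMBOLS[ref_sym], SYMBOLS[alt_sym]
            end = col
            if kind in ("deletion", "insertion"):
                while end + 1 in per_col and per_col[end + 1][0] == kind:
                    end += 1
                    used.add(end)
                    k2, r2, a2, s2 = per_col[end]
                    ref += SYMBOLS[r2]
                    alt += SYMBOLS[a2]
                    support = min(support, s2)
                if kind == "deletion":
                    alt = "-"
                else:
                    ref = "-"
                    alt = alt.replace("-", "")
            calls.append(MutationCall(
                locus=msa.locus, column=col + 1,
                allele_pos=_allele_position(msa, consensus_allele, col + 1),
                kind=kind, ref=ref.replace("-", "") or "-", alt=alt,
                mutation_class=mutation_class, support=support,
                feature=str(msa.feature_map[col]), haplotype=m))
    calls.sort(key=lambda c: (c.column, c.haplotype))
    return calls


# ---------------------------------------------------------------------------
# reports

def write_reports(genotype: GenotypeCall, mutations: list,
                  samples: PosteriorSamples, out_dir,
                  msa: AlleleMSA = None) -> dict:
    """Write genotype, mutation, consensus, and trace files.

    Byte-stable for identical inputs.  Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genotype": os.path.join(out_dir, "genotype.tsv"),
        "mutations": os.path.join(out_dir, "mutations.tsv"),
        "consensus": os.path.join(out_dir, "consensus.fasta"),
        "trace": os.path.join(out_dir, "trace.tsv"),
    }
    with open(paths["genotype"], "w") as fh:
        fh.write("locus\tallele1\tallele2\tsupport\tresolution\t"
                 "novel_allele\n")
        a, b = genotype.alleles
        fh.write(f"{genotype.locus}\t{a}\t{b}\t{genotype.support:.4f}\t"
                 f"{genotype.resolution}\t{int(genotype.novel_allele)}\n")
    with open(paths["mutations"], "w") as fh:
        fh.write("locus\tcolumn\tallele_pos\tref\talt\tkind\tclass\t"
                 "support\tfeature\thaplotype\n")
        for c in mutations:
            fh.write(f"{c.locus}\t{c.column}\t{c.allele_pos}\t{c.ref}\t"
                     f"{c.alt}\t{c.kind}\t{c.mutation_class}\t"
                     f"{c.support:.4f}\t{c.feature}\t{c.haplotype + 1}\n")
    with open(paths["consensus"], "w") as fh:
        for m in range(2):
            for tag, seqs in (("normal", samples.S_n), ("tumor", samples.S_t)):
                cons = decode(_consensus(seqs[:, m, :])).replace("-", "")
                fh.write(f">haplotype{m + 1}_{tag}\n{cons}\n")
    samples.write_trace_tsv(paths["trace"])
    return paths
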