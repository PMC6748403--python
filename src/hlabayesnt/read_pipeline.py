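"""Read extraction, per-allele scoring, locus assignment, and realignment.

The pipeline takes reads overlapping the extended HLA region of the human
reference, scores every mate against every panel allele with an
alignment-derived score (the HR score), assigns each read pair to at most
one locus by an absolute-score criterion plus a margin criterion against
the best other locus (paralogous loci produce near-ties, which the margin
criterion rejects), and finally realigns retained reads into the MSA
column coordinates consumed by the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from hlabayesnt.alphabet import GAP, N, decode, encode
from hlabayesnt.config import HyperParameters
from hlabayesnt.reference_panel import AlleleMSA

__all__ = [
    "Mate",
    "ReadPair",
    "AlignmentToType",
    "HRScoreMatrix",
    "RealignedRead",
    "LocusReadSet",
    "HLA_REGIONS",
    "extract_region_reads",
    "align_read_to_allele",
    "hr_score",
    "score_reads",
    "assign_reads_to_loci",
    "realign_to_msa",
    "build_locus_read_set",
    "write_realigned_tsv",
    "read_realigned_tsv",
]

#: 1-based inclusive coordinates of the extended HLA region on chromosome 6.
HLA_REGIONS = {
    "GRCh37": (28_477_797, 33_448_354),
    "GRCh38": (28_510_120, 33_480_577),
}


@dataclass
class Mate:
    """One sequenced mate: bases over ``ACGTN`` plus per-base Phred scores."""

    sequence: str
    qualities: np.ndarray

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and quality lengths differ")


@dataclass
class ReadPair:
    id: str
    mates: list
    sample: str = "normal"  # "normal" | "tumor"

    @property
    def is_paired(self) -> bool:
        return len(self.mates) == 2


@dataclass
class AlignmentToType:
    """A local alignment of one mate against one gap-stripped allele.

    ``aligned_read`` and ``aligned_ref`` are equal-length padded strings;
    ``mismatch_probs`` holds the Phred-derived mismatch probability
    ``10**(-b/10)`` at read-base columns and NaN at read-gap columns.
    ``ref_start``/``ref_end`` delimit the aligned allele span (0-based,
    end-exclusive); likewise ``read_start``/``read_end`` for the mate.
    """

    aligned_read: str
    aligned_ref: str
    mismatch_probs: np.ndarray
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    score: float


# ---------------------------------------------------------------------------
# extraction

def extract_region_reads(alignment_file, build: str = "GRCh37") -> list:
    """Collect read pairs overlapping the extended HLA region of a BAM/SAM.

    Primary records overlapping the region (1-based inclusive bounds per
    ``HLA_REGIONS``) are re-paired by name; an unmapped mate stored at its
    mapped mate's coordinate is retained.  Requires a position-sorted,
    indexed file for BAM; SAM files are scanned sequentially.
    """
    import pysam

    if build not in HLA_REGIONS:
        raise ValueError(f"unknown genome build {build!r}")
    start, end = HLA_REGIONS[build]
    if isinstance(alignment_file, str):
        mode = "r" if alignment_file.endswith(".sam") else "rb"
        af = pysam.AlignmentFile(alignment_file, mode)
    else:
        af = alignment_file
    contig = None
    for cand in ("chr6", "6"):
        if cand in af.references:
            contig = cand
            break
    if contig is None:
        raise ValueError("no chromosome 6 contig in alignment file")
    if af.has_index():
        records = af.fetch(contig, start - 1, end)
    else:
        records = (r for r in af
                   if r.reference_name == contig
                   and r.reference_start is not None
                   and r.reference_start < end
                   and (r.reference_end or r.reference_start + 1) > start - 1)
    groups: dict = {}
    order: list = []
    for rec in records:
        if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
            continue
        if rec.query_name not in groups:
            groups[rec.query_name] = []
            order.append(rec.query_name)
        seq = rec.query_sequence
        quals = rec.query_qualities
        if quals is None:
            quals = np.full(len(seq), 30, dtype=np.int64)
        if rec.is_reverse:
            seq = _revcomp(seq)
            quals = np.asarray(quals)[::-1].copy()
        groups[rec.query_name].append(Mate(seq, np.asarray(quals)))
    return [ReadPair(id=name, mates=groups[name][:2]) for name in order]


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# alignment and scoring

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_read_to_allele(mate: Mate, allele_seq: str,
                         h: HyperParameters = None):
    """Locally align one mate to a gap-stripped allele sequence.

    Returns an :class:`AlignmentToType`, or ``None`` (unmapped) when the
    best local alignment scores below ``h.min_alignment_score`` or either
    sequence is empty.  Deterministic: the aligner's first optimal
    alignment is used.
    """
    if h is None:
        h = HyperParameters()
    if len(mate.sequence) == 0 or len(allele_seq) == 0:
        return None
    try:
        alns = _ALIGNER.align(allele_seq, mate.sequence)
        aln = alns[0]
    except (ValueError, IndexError, OverflowError):
        return None
    if aln.score < h.min_alignment_score:
        return None
    ref_aln, read_aln = str(aln[0]), str(aln[1])
    coords = aln.coordinates
    ref_start, ref_end = int(coords[0][0]), int(coords[0][-1])
    read_start, read_end = int(coords[1][0]), int(coords[1][-1])
    q = np.full(len(read_aln), np.nan)
    pos = read_start
    mism = 10.0 ** (-mate.qualities / 10.0)
    for col, ch in enumerate(read_aln):
        if ch != "-":
            q[col] = mism[pos]
            pos += 1
    return AlignmentToType(
        aligned_read=read_aln, aligned_ref=ref_aln, mismatch_probs=q,
        ref_start=ref_start, ref_end=ref_end,
        read_start=read_start, read_end=read_end, score=float(aln.score))


def hr_score(a, h: HyperParameters) -> float:
    """Column-summed HR score of one mate-allele alignment.

    Each column earns a length reward (``alpha_reward`` per read base, 0
    per read gap) plus a penalty: ``alpha_n`` if either symbol is ``N``;
    gap open/extension penalties for deletion (read gap) or insertion
    (allele gap) runs, where the first column of a run is charged the
    opening penalty; a quality-weighted mismatch penalty ``log10(q) =
    -b/10`` for a substituted base; 0 for a match.  The unmapped marker
    (``None``) scores ``-inf``.
    """
    if a is None:
        return -math.inf
    score = 0.0
    in_del = in_ins = False
    for col, (x, t) in enumerate(zip(a.aligned_read, a.aligned_ref)):
        if x != "-":
            score += h.alpha_reward
        if x == "N" or t == "N":
            score += h.alpha_n
            in_del = x == "-"
            in_ins = t == "-"
        elif x == "-":
            score += h.alpha_del_ext if in_del else h.alpha_del_open
            in_del, in_ins = True, False
        elif t == "-":
            score += h.alpha_ins_ext if in_ins else h.alpha_ins_open
            in_del, in_ins = False, True
        else:
            if x != t:
                score += math.log10(a.mismatch_probs[col])
            in_del = in_ins = False
    return score


@dataclass
class HRScoreMatrix:
    """HR scores of every (pair, mate, locus, allele) plus cached alignments.

    ``mate_scores[(pair_index, mate_index)][locus]`` is the per-allele
    score vector (``-inf`` for unmapped).  Locus scores sum each mate's
    best per-allele score.
    """

    pairs: list
    loci: list
    mate_scores: dict = field(default_factory=dict)
    alignments: dict = field(default_factory=dict)

    def locus_score(self, pair_index: int, locus: str) -> float:
        pair = self.pairs[pair_index]
        total = 0.0
        for j in range(len(pair.mates)):
            total += float(np.max(self.mate_scores[(pair_index, j)][locus]))
        return total

    def best_allele(self, pair_index: int, mate_index: int, locus: str) -> int:
        """Index of the best-scoring allele (ties break low)."""
        scores = self.mate_scores[(pair_index, mate_index)][locus]
        return int(np.argmax(scores))


def score_reads(pairs: list, panels: dict, h: HyperParameters) -> HRScoreMatrix:
    """Score every mate of every pair against every allele of every locus."""
    loci = list(panels)
    out = HRScoreMatrix(pairs=pairs, loci=loci)
    allele_seqs = {
        locus: [msa.ungapped_sequence(i) for i in range(msa.n_alleles)]
        for locus, msa in panels.items()
    }
    for pi, pair in enumerate(pairs):
        for j, mate in enumerate(pair.mates):
            per_locus = {}
            for locus in loci:
                seqs = allele_seqs[locus]
                scores = np.full(len(seqs), -np.inf)
                for k, aseq in enumerate(seqs):
                    aln = align_read_to_allele(mate, aseq, h)
                    if aln is None:
                        continue
                    scores[k] = hr_score(aln, h)
                    out.alignments[(pi, j, locus, k)] = aln
                per_locus[locus] = scores
            out.mate_scores[(pi, j)] = per_locus
    return out


def assign_reads_to_loci(scores: HRScoreMatrix, h: HyperParameters):
    """Partition read pairs among loci by the two threshold criteria.

    A pair is assigned to locus ``l`` iff its locus score exceeds the
    absolute threshold and beats the best other locus by the margin
    threshold (paired-end thresholds, or the stricter single-end ones for
    unpaired reads).  Returns ``(assigned, unassigned)`` where ``assigned``
    maps locus name to a list of pair indices.
    """
    assigned = {locus: [] for locus in scores.loci}
    unassigned = []
    for pi, pair in enumerate(scores.pairs):
        s = {locus: scores.locus_score(pi, locus) for locus in scores.loci}
        best = max(s, key=lambda l: s[l])
        others = [v for l, v in s.items() if l != best]
        margin = s[best] - max(others) if others else math.inf
        if pair.is_paired:
            th_s, th_d = h.theta_paired_score, h.theta_paired_diff
        else:
            th_s, th_d = h.theta_single_score, h.theta_single_diff
        if s[best] > th_s and margin > th_d:
            assigned[best].append(pi)
        else:
            unassigned.append(pi)
    return assigned, unassigned


# ---------------------------------------------------------------------------
# realignment

@dataclass
class RealignedRead:
    """One mate expressed in MSA column coordinates.

    ``start`` is the 1-based first covered MSA column; ``symbols`` holds
    integer-coded symbols over the inclusive covered span (gaps explicit);
    ``mismatch_probs`` aligns with ``symbols`` (NaN at gap positions).
    Read insertions relative to the MSA are kept aside in ``insertions``
    (column -> inserted bases), attached to the preceding column.
    """

    id: str
    mate_index: int
    sample: str
    start: int
    symbols: np.ndarray
    mismatch_probs: np.ndarray
    best_allele: int
    insertions: dict = field(default_factory=dict)

    @property
    def end(self) -> int:
        """1-based last covered MSA column (inclusive)."""
        return self.start + len(self.symbols) - 1

    @property
    def covered(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


def realign_to_msa(aln: AlignmentToType, msa: AlleleMSA, best_allele: int,
                   read_id: str = "", mate_index: int = 0,
                   sample: str = "normal") -> RealignedRead:
    """Translate a mate-to-allele alignment into MSA column coordinates.

    Allele base positions map to the MSA columns they occupy; read bases
    and read gaps land on those columns.  MSA columns where the best
    allele itself is gapped read as gaps.  Insertions in the read relative
    to the allele have no column of their own and are attached to the
    preceding column (discarded before the first).
    """
    if aln is None:
        raise ValueError("cannot realign an unmapped mate")
    base_cols = np.flatnonzero(msa.rows[best_allele] != GAP)
    if aln.ref_end > len(base_cols):
        raise ValueError("alignment extends past allele sequence")
    start_col = int(base_cols[aln.ref_start])
    end_col = int(base_cols[aln.ref_end - 1])
    span = end_col - start_col + 1
    symbols = np.full(span, GAP, dtype=np.uint8)
    probs = np.full(span, np.nan)
    insertions: dict = {}
    ref_pos = aln.ref_start
    prev_col = None
    for col_idx, (x, t) in enumerate(zip(aln.aligned_read, aln.aligned_ref)):
        if t != "-":
            col = int(base_cols[ref_pos]) - start_col
            if x != "-":
                symbols[col] = encode(x)[0]
                probs[col] = aln.mismatch_probs[col_idx]
            ref_pos += 1
            prev_col = col
        else:  # insertion in the read relative to the allele
            if x != "-" and prev_col is not None:
                key = prev_col + start_col + 1  # 1-based preceding column
                insertions[key] = insertions.get(key, "") + x
    return RealignedRead(id=read_id, mate_index=mate_index, sample=sample,
                         start=start_col + 1, symbols=symbols,
                         mismatch_probs=probs, best_allele=best_allele,
                         insertions=insertions)


@dataclass
class LocusReadSet:
    """Realigned reads of one locus, grouped by pair and split by sample."""

    locus: str
    n_columns: int
    normal_pairs: list = field(default_factory=list)
    tumor_pairs: list = field(default_factory=list)

    @property
    def n_normal(self) -> int:
        return len(self.normal_pairs)

    @property
    def n_tumor(self) -> int:
        return len(self.tumor_pairs)


def build_locus_read_set(pairs: list, panels: dict, h: HyperParameters,
                         locus: str = None) -> dict:
    """Run scoring, locus assignment, and realignment for a set of pairs.

    Returns a mapping ``locus -> LocusReadSet``; pairs failing the
    threshold criteria are dropped.  When ``locus`` is given, only that
    locus's read set is returned (still scored against all panels so the
    margin criterion applies).
    """
    scores = score_reads(pairs, panels, h)
    assigned, _ = assign_reads_to_loci(scores, h)
    out = {}
    for loc, indices in assigned.items():
        if locus is not None and loc != locus:
            continue
        msa = panels[loc]
        rs = LocusReadSet(locus=loc, n_columns=msa.n_columns)
        for pi in indices:
            pair = scores.pairs[pi]
            mates = []
            for j in range(len(pair.mates)):
                k_star = scores.best_allele(pi, j, loc)
                aln = scores.alignments.get((pi, j, loc, k_star))
                if aln is None:
                    continue
                mates.append(realign_to_msa(
                    aln, msa, k_star, read_id=pair.id, mate_index=j,
                    sample=pair.sample))
            if not mates:
                continue
            if pair.sample == "tumor":
                rs.tumor_pairs.append(mates)
            else:
                rs.normal_pairs.append(mates)
        out[loc] = rs
    if locus is not None:
        return {locus: out[locus]}
    return out


# ---------------------------------------------------------------------------
# serialization

def write_realigned_tsv(read_set: LocusReadSet, path) -> None:
    """Serialize a locus read set (1-based columns, Phred-style quals)."""
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tsample\tbest_allele\tstart\tend\t"
                 "symbols\tmismatch_probs\n")
        for group in (read_set.normal_pairs, read_set.tumor_pairs):
            for mates in group:
                for r in mates:
                    probs = ",".join(
                        "" if np.isnan(p) else f"{p:.6g}"
                        for p in r.mismatch_probs)
                    fh.write(f"{r.id}\t{r.mate_index}\t{r.sample}\t"
                             f"{r.best_allele}\t{r.start}\t{r.end}\t"
                             f"{decode(r.symbols)}\t{probs}\n")


def read_realigned_tsv(path, locus: str, n_columns: int) -> LocusReadSet:
    rs = LocusReadSet(locus=locus, n_columns=n_columns)
    groups: dict = {}
    order: list = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            (rid, mate, sample, k, start, _end, syms, probs) = \
                line.rstrip("\n").split("\t")
            p = np.array([np.nan if x == "" else float(x)
                          for x in probs.split(",")])
            r = RealignedRead(id=rid, mate_index=int(mate), sample=sample,
                              start=int(start), symbols=encode(syms),
                              mismatch_probs=p, best_allele=int(k))
            key = (rid, sample)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(r)
    for key in order:
        if key[1] == "tumor":
            rs.tumor_pairs.append(groups[key])
        else:
            rs.normal_pairs.append(groups[key])
    return rs
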