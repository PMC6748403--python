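"""The joint model: read likelihoods and every prior factor.

Latent state for one locus comprises reference picks ``R`` (two panel
alleles plus ``n_decoys`` decoy picks), matched normal/tumor haplotype
sequences ``S^(n)``/``S^(t)`` in MSA coordinates, per-haplotype read
propensities ``F``, the normal-cell fraction ``G`` of the tumor sample,
per-column validity flags ``V`` for decoys, and per-read-pair origin
indicators ``I``.  The unnormalized log posterior is the sum of

* Phred-aware emission likelihoods of the normal and tumor reads given the
  haplotype each pair is assigned to (tumor reads may come from a normal
  haplotype, reflecting contamination),
* a per-position somatic prior ``p(S^(t) | S^(n))``,
* a per-position germline prior ``p(S^(n) | R)`` whose deviation
  probabilities depend on whether the haplotype is a decoy and whether the
  reference base was imputed,
* the allele-frequency prior on ``R`` (uniform for decoys),
* categorical indicator priors proportional to ``F`` (times ``G`` for
  normal-origin tumor reads) masked by validity,
* log-normal priors on ``F`` and ``G`` and a Markov-chain prior on decoy
  validity flags.

All probability arithmetic is in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from hlabayesnt.alphabet import GAP, N, N_BASES, encode
from hlabayesnt.config import HyperParameters, lognormal_logpdf
from hlabayesnt.read_pipeline import LocusReadSet
from hlabayesnt.reference_panel import AlleleFrequencyTable, AlleleMSA

__all__ = [
    "ModelState",
    "PackedReads",
    "emission_logprob",
    "build_emission_tables",
    "build_somatic_table",
    "build_germline_tables",
    "read_set_loglik",
    "somatic_prior_logp",
    "germline_prior_logp",
    "type_prior_logp",
    "indicator_prior_logp",
    "scalar_priors_logp",
    "log_posterior",
]

# emission kinds: how the Phred-derived mismatch probability enters
KIND_NONE, KIND_LOG1MQ, KIND_LOGQ3 = 0, 1, 2


# ---------------------------------------------------------------------------
# probability tables

def build_emission_tables(h: HyperParameters):
    """Constant and quality-kind tables of the read emission model.

    Returns ``(const, kind)``, both ``(6, 6)`` indexed ``[seq, read]``.
    The emission log-probability of read symbol ``x`` from haplotype
    symbol ``s`` with mismatch probability ``q`` is ``const[s, x]`` plus
    ``log(1-q)`` (kind 1, matching base), ``log(q/3)`` (kind 2,
    substituted base), or nothing (kind 0).
    """
    const = np.full((6, 6), -np.inf)
    kind = np.zeros((6, 6), dtype=np.uint8)
    c_base = math.log(1.0 - h.err_del - h.err_n)
    for s in range(N_BASES):
        for x in range(N_BASES):
            const[s, x] = c_base
            kind[s, x] = KIND_LOG1MQ if x == s else KIND_LOGQ3
        const[s, GAP] = math.log(h.err_del)
        const[s, N] = math.log(h.err_n)
    for x in range(N_BASES):
        const[GAP, x] = math.log(h.err_ins / 4.0)
        const[N, x] = math.log((1.0 - h.err_del - h.err_n) / 4.0)
    const[GAP, GAP] = math.log(1.0 - h.err_ins - h.err_n)
    const[GAP, N] = math.log(h.err_n)
    const[N, GAP] = math.log(h.err_del)
    const[N, N] = math.log(h.err_n)
    return const, kind


def _event_table(p_sub, p_del, p_ins, p_n):
    """6x6 log table of a per-position deviation categorical ``[src, dst]``.

    From a base: identity keeps ``1 - p_sub - p_del - p_n``, each other
    base gets ``p_sub / 3``, gap ``p_del``, ``N`` ``p_n``.  From a gap:
    each base ``p_ins / 4``, gap keeps the rest, ``N`` ``p_n``.  From an
    ``N``: uniform over bases with the deletion/N mass reserved.
    """
    t = np.full((6, 6), -np.inf)
    stay = 1.0 - p_sub - p_del - p_n
    for s in range(N_BASES):
        for d in range(N_BASES):
            t[s, d] = math.log(stay) if d == s else math.log(p_sub / 3.0)
        t[s, GAP] = math.log(p_del)
        t[s, N] = math.log(p_n)
    for d in range(N_BASES):
        t[GAP, d] = math.log(p_ins / 4.0)
        t[N, d] = math.log((1.0 - p_del - p_n) / 4.0)
    t[GAP, GAP] = math.log(1.0 - p_ins - p_n)
    t[GAP, N] = math.log(p_n)
    t[N, GAP] = math.log(p_del)
    t[N, N] = math.log(p_n)
    return t


def build_somatic_table(h: HyperParameters) -> np.ndarray:
    """Log table of ``p(S^(t)_{m,n} | S^(n)_{m,n})``."""
    return _event_table(h.som_sub, h.som_del, h.som_ins, h.som_n)


def build_germline_tables(h: HyperParameters) -> np.ndarray:
    """Log tables of ``p(S^(n)_{m,n} | R_{m,n})``.

    Shape ``(2, 2, 6, 6)`` indexed ``[decoy][imputed][ref][seq]``.
    """
    out = np.empty((2, 2, 6, 6))
    for d in range(2):
        for i in range(2):
            out[d, i] = _event_table(*h.germline[d, i])
    return out


def _sym_code(symbol) -> int:
    if isinstance(symbol, str):
        return int(encode(symbol)[0])
    return int(symbol)


def emission_logprob(read_symbol, seq_symbol, q: float,
                     h: HyperParameters) -> float:
    """Log-probability of observing one read symbol from one haplotype symbol.

    ``q`` is the Phred-derived mismatch probability of the read base
    (ignored when the read symbol is a gap or ``N``).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    x, s = _sym_code(read_symbol), _sym_code(seq_symbol)
    const, kind = build_emission_tables(h)
    v = const[s, x]
    if kind[s, x] == KIND_LOG1MQ:
        v += math.log1p(-q) if q < 1 else -math.inf
    elif kind[s, x] == KIND_LOGQ3:
        v += math.log(q / 3.0) if q > 0 else -math.inf
    return float(v)


# ---------------------------------------------------------------------------
# state and packed reads

@dataclass
class ModelState:
    """All latent parameters of one locus.

    Haplotype index convention: rows ``0`` and ``1`` are the two genotype
    haplotypes, rows ``2 .. n_decoys+1`` are decoys.  ``S_n``/``S_t`` have
    shape ``(n_decoys+2, N)``.  ``I_n[i]`` indexes into the normal rows;
    ``I_t[i]`` additionally may take ``n_decoys+2 + m`` meaning the tumor
    haplotype of row ``m`` (values below that mean a normal-origin read in
    the tumor sample).
    """

    R_idx: np.ndarray
    S_n: np.ndarray
    S_t: np.ndarray
    F: np.ndarray
    G: float
    V: np.ndarray
    I_n: np.ndarray
    I_t: np.ndarray

    def __post_init__(self):
        self.R_idx = np.asarray(self.R_idx, dtype=np.int64)
        self.S_n = np.asarray(self.S_n, dtype=np.uint8)
        self.S_t = np.asarray(self.S_t, dtype=np.uint8)
        self.F = np.asarray(self.F, dtype=float)
        self.V = np.asarray(self.V, dtype=np.uint8)
        self.I_n = np.asarray(self.I_n, dtype=np.int64)
        self.I_t = np.asarray(self.I_t, dtype=np.int64)
        n_rows, ncol = self.S_n.shape
        if self.S_t.shape != (n_rows, ncol) or self.V.shape != (n_rows, ncol):
            raise ValueError("S_t / V shape mismatch")
        if len(self.R_idx) != n_rows or len(self.F) != n_rows:
            raise ValueError("R_idx / F length mismatch")
        if (self.F <= 0).any() or self.G <= 0:
            raise ValueError("F and G must be positive")
        if (self.V[:2] != 1).any():
            raise ValueError("nondecoy validity flags must all be 1")
        if self.I_n.size and not ((0 <= self.I_n) & (self.I_n < n_rows)).all():
            raise ValueError("normal indicator out of range")
        if self.I_t.size and not ((0 <= self.I_t) & (self.I_t < 2 * n_rows)).all():
            raise ValueError("tumor indicator out of range")

    @property
    def n_rows(self) -> int:
        return self.S_n.shape[0]

    @property
    def n_decoys(self) -> int:
        return self.n_rows - 2

    @property
    def n_columns(self) -> int:
        return self.S_n.shape[1]

    def copy(self) -> "ModelState":
        return ModelState(self.R_idx.copy(), self.S_n.copy(), self.S_t.copy(),
                          self.F.copy(), self.G, self.V.copy(),
                          self.I_n.copy(), self.I_t.copy())

    def to_tsv(self, path) -> None:
        """Debug snapshot: one row per haplotype with sequences and scalars."""
        from hlabayesnt.alphabet import decode

        with open(path, "w") as fh:
            fh.write(f"#G\t{self.G:.8g}\n")
            fh.write(f"#I_n\t{','.join(map(str, self.I_n))}\n")
            fh.write(f"#I_t\t{','.join(map(str, self.I_t))}\n")
            fh.write("row\tR_idx\tF\tS_n\tS_t\tV\n")
            for m in range(self.n_rows):
                fh.write(f"{m}\t{self.R_idx[m]}\t{self.F[m]:.8g}\t"
                         f"{decode(self.S_n[m])}\t{decode(self.S_t[m])}\t"
                         f"{''.join(map(str, self.V[m]))}\n")


class _SampleReads:
    """Flat arrays for one sample's mates: the kernel-facing layout."""

    def __init__(self, pairs, n_columns):
        starts, lens, pair_of_mate = [], [], []
        syms, l1q, lq3, best = [], [], [], []
        for pi, mates in enumerate(pairs):
            for r in mates:
                if r.start < 1 or r.end > n_columns:
                    raise ValueError(
                        f"read {r.id} covers columns outside [1, {n_columns}]")
                starts.append(r.start - 1)
                lens.append(len(r.symbols))
                pair_of_mate.append(pi)
                best.append(r.best_allele)
                syms.append(r.symbols)
                q = np.nan_to_num(r.mismatch_probs, nan=0.5)
                q = np.clip(q, 1e-10, 1.0 - 1e-10)
                l1q.append(np.log1p(-q))
                lq3.append(np.log(q / 3.0))
        self.n_pairs = len(pairs)
        self.n_mates = len(starts)
        self.start = np.array(starts, dtype=np.int64)
        self.length = np.array(lens, dtype=np.int64)
        self.pair_of_mate = np.array(pair_of_mate, dtype=np.int64)
        self.best_allele = np.array(best, dtype=np.int64)
        self.off = np.r_[0, np.cumsum(self.length)].astype(np.int64)
        self.sym = (np.concatenate(syms).astype(np.uint8)
                    if syms else np.empty(0, np.uint8))
        self.l1q = np.concatenate(l1q) if l1q else np.empty(0)
        self.lq3 = np.concatenate(lq3) if lq3 else np.empty(0)


class PackedReads:
    """A :class:`~hlabayesnt.read_pipeline.LocusReadSet` densified for the model."""

    def __init__(self, read_set: LocusReadSet):
        self.locus = read_set.locus
        self.n_columns = read_set.n_columns
        self.normal = _SampleReads(read_set.normal_pairs, read_set.n_columns)
        self.tumor = _SampleReads(read_set.tumor_pairs, read_set.n_columns)

    @property
    def n_normal(self) -> int:
        return self.normal.n_pairs

    @property
    def n_tumor(self) -> int:
        return self.tumor.n_pairs


def _as_packed(reads) -> PackedReads:
    return reads if isinstance(reads, PackedReads) else PackedReads(reads)


# ---------------------------------------------------------------------------
# likelihood and priors

def _mate_loglik(sr: _SampleReads, mate: int, row: np.ndarray,
                 const: np.ndarray, kind: np.ndarray) -> float:
    o0, o1 = sr.off[mate], sr.off[mate + 1]
    cols = np.arange(sr.start[mate], sr.start[mate] + sr.length[mate])
    s = row[cols]
    x = sr.sym[o0:o1]
    v = const[s, x].copy()
    k = kind[s, x]
    v[k == KIND_LOG1MQ] += sr.l1q[o0:o1][k == KIND_LOG1MQ]
    v[k == KIND_LOGQ3] += sr.lq3[o0:o1][k == KIND_LOGQ3]
    return float(v.sum())


def read_set_loglik(reads, state: ModelState, h: HyperParameters) -> float:
    """Total emission log-likelihood of both samples given assignments."""
    pr = _as_packed(reads)
    const, kind = build_emission_tables(h)
    n_rows = state.n_rows
    total = 0.0
    for mate in range(pr.normal.n_mates):
        m = int(state.I_n[pr.normal.pair_of_mate[mate]])
        total += _mate_loglik(pr.normal, mate, state.S_n[m], const, kind)
    for mate in range(pr.tumor.n_mates):
        m = int(state.I_t[pr.tumor.pair_of_mate[mate]])
        row = state.S_n[m] if m < n_rows else state.S_t[m - n_rows]
        total += _mate_loglik(pr.tumor, mate, row, const, kind)
    return total


def somatic_prior_logp(state: ModelState, h: HyperParameters) -> float:
    """Log prior of the tumor haplotypes given the normal haplotypes."""
    table = build_somatic_table(h)
    return float(table[state.S_n, state.S_t].sum())


def germline_prior_logp(state: ModelState, msa: AlleleMSA,
                        h: HyperParameters) -> float:
    """Log prior of the normal haplotypes given their reference alleles."""
    tables = build_germline_tables(h)
    total = 0.0
    for m in range(state.n_rows):
        r = msa.rows[state.R_idx[m]]
        imp = msa.imputed_mask[state.R_idx[m]].astype(np.intp)
        d = int(m >= 2)
        total += float(tables[d, imp, r, state.S_n[m]].sum())
    return total


def type_prior_logp(state: ModelState, freqs: AlleleFrequencyTable,
                    msa: AlleleMSA) -> float:
    """Log prior of the reference picks: frequencies for the genotype rows,
    uniform over the panel for decoys."""
    total = 0.0
    for m in (0, 1):
        total += math.log(freqs.probability(msa.allele_names[state.R_idx[m]]))
    total += -state.n_decoys * math.log(msa.n_alleles)
    return total


def _pair_validity(sr: _SampleReads, V: np.ndarray) -> np.ndarray:
    """(n_pairs, n_rows) boolean: does pair i cover a valid column of row m."""
    n_rows = V.shape[0]
    out = np.zeros((sr.n_pairs, n_rows), dtype=bool)
    for mate in range(sr.n_mates):
        pi = sr.pair_of_mate[mate]
        lo = sr.start[mate]
        hi = lo + sr.length[mate]
        out[pi] |= V[:, lo:hi].any(axis=1)
    return out


def indicator_prior_logp(state: ModelState, reads,
                         h: HyperParameters) -> float:
    """Log prior of all read-origin indicators.

    Per read the prior is a normalized categorical with weight ``F_m``
    (times ``G`` for a normal-origin candidate of a tumor read), zeroed
    for candidates with no valid column on the read's span.
    """
    pr = _as_packed(reads)
    n_rows = state.n_rows
    total = 0.0
    valid_n = _pair_validity(pr.normal, state.V)
    for i in range(pr.n_normal):
        w = np.where(valid_n[i], state.F, 0.0)
        z = w.sum()
        if z == 0 or w[state.I_n[i]] == 0:
            raise ValueError(f"normal pair {i} has no valid candidate")
        total += math.log(w[state.I_n[i]] / z)
    valid_t = _pair_validity(pr.tumor, state.V)
    for i in range(pr.n_tumor):
        w = np.concatenate([
            np.where(valid_t[i], state.F * state.G, 0.0),
            np.where(valid_t[i], state.F, 0.0),
        ])
        z = w.sum()
        if z == 0 or w[state.I_t[i]] == 0:
            raise ValueError(f"tumor pair {i} has no valid candidate")
        total += math.log(w[state.I_t[i]] / z)
    return total


def scalar_priors_logp(state: ModelState, h: HyperParameters) -> float:
    """Log priors of ``F``, ``G``, and the validity flags.

    Non-decoy validity rows are fixed at 1 and contribute nothing; decoy
    rows follow a two-state Markov chain whose first position behaves as
    if preceded by an invalid position.
    """
    total = 0.0
    for m in range(state.n_rows):
        if m < 2:
            total += lognormal_logpdf(state.F[m], h.freq_mu_ref,
                                      h.freq_sigma_ref)
        else:
            total += lognormal_logpdf(state.F[m], h.freq_mu_decoy,
                                      h.freq_sigma_decoy)
    total += lognormal_logpdf(state.G, h.contam_mu, h.contam_sigma)
    if (state.V[:2] != 1).any():
        raise ValueError("nondecoy validity flags must all be 1")
    lo, le = math.log(h.valid_open), math.log(h.valid_ext)
    lno, lne = math.log(1 - h.valid_open), math.log(1 - h.valid_ext)
    for m in range(2, state.n_rows):
        prev = 0
        for v in state.V[m]:
            if prev == 1:
                total += le if v == 1 else lne
            else:
                total += lo if v == 1 else lno
            prev = v
    return total


def log_posterior(state: ModelState, reads, msa: AlleleMSA,
                  freqs: AlleleFrequencyTable, h: HyperParameters) -> float:
    """Unnormalized log posterior: the sum of all nine factors."""
    pr = _as_packed(reads)
    return (read_set_loglik(pr, state, h)
            + somatic_prior_logp(state, h)
            + germline_prior_logp(state, msa, h)
            + type_prior_logp(state, freqs, msa)
            + indicator_prior_logp(state, pr, h)
            + scalar_priors_logp(state, h))
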