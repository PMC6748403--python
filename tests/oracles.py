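"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles — explicit probability
tables and exhaustive enumeration — without calling the package's model
or sampler code paths, so it can serve as an independent check of both.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

BASES = (0, 1, 2, 3)
N_SYM, GAP = 4, 5


# ---------------------------------------------------------------------------
# scalar probability tables (written out longhand)

def emission_prob(x, s, q, h):
    """p(read symbol x | haplotype symbol s, mismatch prob q)."""
    if s in BASES:
        if x == s:
            return (1 - h.err_del - h.err_n) * (1 - q)
        if x in BASES:
            return (1 - h.err_del - h.err_n) * q / 3.0
        if x == GAP:
            return h.err_del
        return h.err_n
    if s == GAP:
        if x in BASES:
            return h.err_ins / 4.0
        if x == GAP:
            return 1 - h.err_ins - h.err_n
        return h.err_n
    # s == N
    if x in BASES:
        return (1 - h.err_del - h.err_n) / 4.0
    if x == GAP:
        return h.err_del
    return h.err_n


def event_prob(src, dst, p_sub, p_del, p_ins, p_n):
    if src in BASES:
        if dst == src:
            return 1 - p_sub - p_del - p_n
        if dst in BASES:
            return p_sub / 3.0
        if dst == GAP:
            return p_del
        return p_n
    if src == GAP:
        if dst in BASES:
            return p_ins / 4.0
        if dst == GAP:
            return 1 - p_ins - p_n
        return p_n
    if dst in BASES:
        return (1 - p_del - p_n) / 4.0
    if dst == GAP:
        return p_del
    return p_n


def somatic_prob(sn, st, h):
    return event_prob(sn, st, h.som_sub, h.som_del, h.som_ins, h.som_n)


def germline_prob(r, sn, decoy, imputed, h):
    p = h.germline[int(decoy), int(imputed)]
    return event_prob(r, sn, p[0], p[1], p[2], p[3])


def v_chain_prob(row, h):
    """Prior of one decoy validity row (first position preceded by 0)."""
    p = 1.0
    prev = 0
    for v in row:
        if prev == 1:
            p *= h.valid_ext if v == 1 else 1 - h.valid_ext
        else:
            p *= h.valid_open if v == 1 else 1 - h.valid_open
        prev = v
    return p


# ---------------------------------------------------------------------------
# tiny-fixture posterior enumeration

class TinyRead:
    """A read for enumeration fixtures: symbols over a column span."""

    def __init__(self, start0, symbols, q):
        self.start0 = start0
        self.symbols = list(symbols)
        self.q = q

    @property
    def cols(self):
        return range(self.start0, self.start0 + len(self.symbols))


def enumerate_posterior(panel_rows, panel_imp, p_t, normal_reads,
                        tumor_reads, h, F, G, n_decoys=0,
                        enumerate_V=False):
    """Exhaustive posterior over (R, V, I) with S summed per column.

    ``panel_rows``: list of symbol-code tuples; ``normal_reads`` /
    ``tumor_reads``: lists of :class:`TinyRead` (each read pair has one
    mate).  F, G are conditioned on.  Returns a dict of marginals:

    * ``genotype``: unordered (k1, k2) -> probability,
    * ``S_n`` / ``S_t``: pooled per-column symbol marginals over the two
      genotype haplotypes, shape ``(N, 6)``,
    * ``V_mean``: per-column P(V=1) of the decoy (``n_decoys == 1``),
    * ``I_n`` / ``I_t``: per-read candidate marginals.
    """
    K = len(panel_rows)
    ncol = len(panel_rows[0])
    n_rows = n_decoys + 2
    Pn, Pt = len(normal_reads), len(tumor_reads)

    # per-read per-column per-symbol emission factors
    def emis_factors(reads):
        out = []
        for r in reads:
            f = {}
            for j, col in enumerate(r.cols):
                f[col] = np.array([emission_prob(r.symbols[j], s, r.q, h)
                                   for s in range(6)])
            out.append(f)
        return out

    em_n = emis_factors(normal_reads)
    em_t = emis_factors(tumor_reads)

    som = np.array([[somatic_prob(sn, st, h) for st in range(6)]
                    for sn in range(6)])

    genotype_marg = {}
    sn_marg = np.zeros((ncol, 6))
    st_marg = np.zeros((ncol, 6))
    v_marg = np.zeros(ncol)
    in_marg = np.zeros((Pn, n_rows))
    it_marg = np.zeros((Pt, 2 * n_rows))
    total = 0.0

    v_configs = (list(itertools.product((0, 1), repeat=ncol))
                 if (enumerate_V and n_decoys == 1) else [None])

    for R in itertools.product(range(K), repeat=n_rows):
        pR = p_t[R[0]] * p_t[R[1]] * (1.0 / K) ** n_decoys
        # germline x somatic tables per (row, col): joint over (sn, st)
        G_tab = np.zeros((n_rows, ncol, 6, 6))
        for m in range(n_rows):
            decoy = m >= 2
            for col in range(ncol):
                r = panel_rows[R[m]][col]
                imp = panel_imp[R[m]][col]
                g = np.array([germline_prob(r, sn, decoy, imp, h)
                              for sn in range(6)])
                G_tab[m, col] = g[:, None] * som
        for Vrow in v_configs:
            if Vrow is None:
                V = np.ones((n_rows, ncol), dtype=int)
                pV = 1.0
            else:
                V = np.ones((n_rows, ncol), dtype=int)
                V[2] = Vrow
                pV = v_chain_prob(Vrow, h)
            wn = []
            for r in normal_reads:
                w = np.array([
                    F[m] if any(V[m, c] for c in r.cols) else 0.0
                    for m in range(n_rows)])
                wn.append(w / w.sum())
            wt = []
            for r in tumor_reads:
                ok = [any(V[m, c] for c in r.cols) for m in range(n_rows)]
                w = np.array([F[m] * G if ok[m] else 0.0
                              for m in range(n_rows)]
                             + [F[m] if ok[m] else 0.0
                                for m in range(n_rows)])
                wt.append(w / w.sum())
            for I_n in itertools.product(range(n_rows), repeat=Pn):
                pIn = math.prod(wn[i][I_n[i]] for i in range(Pn))
                if pIn == 0.0:
                    continue
                for I_t in itertools.product(range(2 * n_rows), repeat=Pt):
                    pIt = math.prod(wt[i][I_t[i]] for i in range(Pt))
                    if pIt == 0.0:
                        continue
                    # per (row, col): joint table over (sn, st) times
                    # emissions of assigned reads
                    w_total = pR * pV * pIn * pIt
                    col_sums = np.zeros((n_rows, ncol))
                    joints = np.zeros((n_rows, ncol, 6, 6))
                    for m in range(n_rows):
                        for col in range(ncol):
                            J = G_tab[m, col].copy()
                            for i in range(Pn):
                                if I_n[i] == m and col in em_n[i]:
                                    J *= em_n[i][col][:, None]
                            for i in range(Pt):
                                if I_t[i] == m and col in em_t[i]:
                                    J *= em_t[i][col][:, None]
                                if I_t[i] == m + n_rows and col in em_t[i]:
                                    J *= em_t[i][col][None, :]
                            joints[m, col] = J
                            col_sums[m, col] = J.sum()
                    w_total *= math.prod(
                        col_sums[m, col]
                        for m in range(n_rows) for col in range(ncol))
                    if w_total == 0.0:
                        continue
                    total += w_total
                    key = tuple(sorted(R[:2]))
                    genotype_marg[key] = genotype_marg.get(key, 0.0) + w_total
                    for m in (0, 1):
                        for col in range(ncol):
                            J = joints[m, col] / col_sums[m, col]
                            sn_marg[col] += 0.5 * w_total * J.sum(axis=1)
                            st_marg[col] += 0.5 * w_total * J.sum(axis=0)
                    if Vrow is not None:
                        v_marg += w_total * np.array(Vrow)
                    for i in range(Pn):
                        in_marg[i, I_n[i]] += w_total
                    for i in range(Pt):
                        it_marg[i, I_t[i]] += w_total

    return {
        "genotype": {k: v / total for k, v in genotype_marg.items()},
        "S_n": sn_marg / total,
        "S_t": st_marg / total,
        "V_mean": v_marg / total,
        "I_n": in_marg / total,
        "I_t": it_marg / total,
        "normalizer": total,
    }


# ---------------------------------------------------------------------------
# Wolff cluster-bound enumeration

def wolff_bound_distribution(V, pi0, pi1):
    """Exact distribution of flipped-cluster bounds ``(b, e)`` (0-based).

    Matches the growth process: start uniform at p, extend left/right
    through equal-valued neighbors, each extension surviving a break draw
    with the value-dependent continuation probability.
    """
    ncol = len(V)
    out = {}
    for p in range(ncol):
        v = V[p]
        cont = pi1 if v == 1 else pi0
        # left growth: probability that the cluster reaches exactly b
        left = {}
        b = p
        prob_reach = 1.0
        while True:
            stop_here = 1.0
            if b > 0 and V[b - 1] == v:
                stop_here = 1.0 - cont
            left[b] = prob_reach * stop_here
            if b > 0 and V[b - 1] == v:
                prob_reach *= cont
                b -= 1
            else:
                break
        right = {}
        e = p
        prob_reach = 1.0
        while True:
            stop_here = 1.0
            if e < ncol - 1 and V[e + 1] == v:
                stop_here = 1.0 - cont
            right[e] = prob_reach * stop_here
            if e < ncol - 1 and V[e + 1] == v:
                prob_reach *= cont
                e += 1
            else:
                break
        for b, pb in left.items():
            for e, pe in right.items():
                out[(b, e)] = out.get((b, e), 0.0) + pb * pe / ncol
    return out


# ---------------------------------------------------------------------------
# statistics helpers

def batch_se(x, n_batches=50):
    """Batch-means standard error of the mean of a (correlated) series."""
    x = np.asarray(x, dtype=float)
    n = len(x) // n_batches * n_batches
    if n == 0:
        return float("inf")
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))
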