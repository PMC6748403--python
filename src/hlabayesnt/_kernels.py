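"""Numba kernels for the MCMC sweep.

These are the per-sweep hot loops: emission log-likelihood matrices,
sufficient statistics of reads per (haplotype, column), and the Gibbs
draws for sequences, types, and indicators.  All kernels operate on the
flat arrays of :class:`~hlabayesnt.model.PackedReads` and integer-coded
sequences; randomness comes from a ``numpy.random.Generator`` passed in
explicitly so runs are reproducible.

Tempering is applied by scaling log-conditionals with ``beta`` (inverse
temperature) before sampling.
"""

import numpy as np
from numba import njit

# emission kind codes (mirrors hlabayesnt.model)
_KIND_LOG1MQ = 1
_KIND_LOGQ3 = 2

# indices into the emission scalar vector
EM_C_BASE, EM_L_DEL, EM_L_N, EM_L_INS4, EM_L_GAPSTAY, EM_L_NBASE = range(6)


@njit(cache=True)
def mate_logliks_tbl(sym, l1q, lq3, off, start, S, em_const, em_kind):
    """Log-likelihood of every mate under every candidate row of ``S``."""
    n_mates = len(start)
    n_cand = S.shape[0]
    L = np.zeros((n_mates, n_cand))
    for i in range(n_mates):
        o0 = off[i]
        ln = off[i + 1] - o0
        st = start[i]
        for c in range(n_cand):
            tot = 0.0
            for p in range(ln):
                x = sym[o0 + p]
                s = S[c, st + p]
                tot += em_const[s, x]
                k = em_kind[s, x]
                if k == _KIND_LOG1MQ:
                    tot += l1q[o0 + p]
                elif k == _KIND_LOGQ3:
                    tot += lq3[o0 + p]
            L[i, c] = tot
    return L


@njit(cache=True)
def mate_logliks_subset(sym, l1q, lq3, off, start, mate_idx, S,
                        em_const, em_kind):
    """Like :func:`mate_logliks_tbl` but only for the listed mates."""
    n = len(mate_idx)
    n_cand = S.shape[0]
    L = np.zeros((n, n_cand))
    for ii in range(n):
        i = mate_idx[ii]
        o0 = off[i]
        ln = off[i + 1] - o0
        st = start[i]
        for c in range(n_cand):
            tot = 0.0
            for p in range(ln):
                x = sym[o0 + p]
                s = S[c, st + p]
                tot += em_const[s, x]
                k = em_kind[s, x]
                if k == _KIND_LOG1MQ:
                    tot += l1q[o0 + p]
                elif k == _KIND_LOGQ3:
                    tot += lq3[o0 + p]
            L[ii, c] = tot
    return L


@njit(cache=True)
def pair_sum(L, pair_of_mate, n_pairs):
    """Sum mate log-likelihood rows into read-pair rows."""
    n_cand = L.shape[1]
    out = np.zeros((n_pairs, n_cand))
    for i in range(L.shape[0]):
        pi = pair_of_mate[i]
        for c in range(n_cand):
            out[pi, c] += L[i, c]
    return out


@njit(cache=True)
def pair_valid(V, start, length, pair_of_mate, n_pairs):
    """Per (pair, haplotype row): does the pair cover any valid column."""
    n_rows = V.shape[0]
    out = np.zeros((n_pairs, n_rows), dtype=np.uint8)
    for i in range(len(start)):
        pi = pair_of_mate[i]
        lo = start[i]
        hi = lo + length[i]
        for m in range(n_rows):
            if out[pi, m] == 0:
                for col in range(lo, hi):
                    if V[m, col] == 1:
                        out[pi, m] = 1
                        break
    return out


@njit(cache=True)
def _sample_from_logits(logits, rng):
    """Draw an index from unnormalized log-weights (``-inf`` excluded)."""
    n = len(logits)
    mx = -np.inf
    for c in range(n):
        if logits[c] > mx:
            mx = logits[c]
    tot = 0.0
    for c in range(n):
        if logits[c] > -np.inf:
            tot += np.exp(logits[c] - mx)
    u = rng.random() * tot
    acc = 0.0
    for c in range(n):
        if logits[c] > -np.inf:
            acc += np.exp(logits[c] - mx)
            if u <= acc:
                return c
    return n - 1


@njit(cache=True)
def sample_indicators(Lp, validC, logw, beta, rng):
    """Gibbs draw of read-origin indicators plus per-pair marginals.

    Returns ``(I, logZ, logW)`` where ``logZ[i]`` is the tempered
    log-sum over allowed candidates of ``beta * (logw + L)`` and
    ``logW[i] = beta * log(sum of allowed prior weights)``.
    """
    n_pairs, n_cand = Lp.shape
    I = np.empty(n_pairs, dtype=np.int64)
    logZ = np.empty(n_pairs)
    logW = np.empty(n_pairs)
    logits = np.empty(n_cand)
    for i in range(n_pairs):
        for c in range(n_cand):
            if validC[i, c] == 1:
                logits[c] = beta * (logw[c] + Lp[i, c])
            else:
                logits[c] = -np.inf
        I[i] = _sample_from_logits(logits, rng)
        logZ[i] = _logsumexp(logits)
        logW[i] = beta * _logsumexp_masked(logw, validC, i)
    return I, logZ, logW


@njit(cache=True)
def indicator_marginals(Lp, validC, logw, beta):
    """Tempered per-pair marginals without sampling (for MH ratios)."""
    n_pairs, n_cand = Lp.shape
    logZ = np.empty(n_pairs)
    logW = np.empty(n_pairs)
    logits = np.empty(n_cand)
    for i in range(n_pairs):
        for c in range(n_cand):
            if validC[i, c] == 1:
                logits[c] = beta * (logw[c] + Lp[i, c])
            else:
                logits[c] = -np.inf
        logZ[i] = _logsumexp(logits)
        logW[i] = beta * _logsumexp_masked(logw, validC, i)
    return logZ, logW


@njit(cache=True)
def _logsumexp(logits):
    mx = -np.inf
    for c in range(len(logits)):
        if logits[c] > mx:
            mx = logits[c]
    if mx == -np.inf:
        return -np.inf
    tot = 0.0
    for c in range(len(logits)):
        if logits[c] > -np.inf:
            tot += np.exp(logits[c] - mx)
    return mx + np.log(tot)


@njit(cache=True)
def _logsumexp_masked(logw, validC, i):
    mx = -np.inf
    for c in range(len(logw)):
        if validC[i, c] == 1 and logw[c] > mx:
            mx = logw[c]
    if mx == -np.inf:
        return -np.inf
    tot = 0.0
    for c in range(len(logw)):
        if validC[i, c] == 1:
            tot += np.exp(logw[c] - mx)
    return mx + np.log(tot)


@njit(cache=True)
def accumulate_stats(sym, l1q, lq3, off, start, rows_of_mate,
                     cnt, sl1q, slq3):
    """Per (row, column) sufficient statistics of assigned reads.

    ``cnt[m, col, x]`` counts read symbols; ``sl1q``/``slq3`` accumulate
    ``log(1-q)`` / ``log(q/3)`` per read base.  Mates with a negative row
    are skipped.
    """
    for i in range(len(start)):
        m = rows_of_mate[i]
        if m < 0:
            continue
        o0 = off[i]
        ln = off[i + 1] - o0
        st = start[i]
        for p in range(ln):
            x = sym[o0 + p]
            col = st + p
            cnt[m, col, x] += 1
            if x < 4:
                sl1q[m, col, x] += l1q[o0 + p]
                slq3[m, col, x] += lq3[o0 + p]


@njit(cache=True)
def accumulate_coverage(off, start, rows_of_mate, D):
    """Count, per (row, column), the mates assigned to the row covering it."""
    for i in range(len(start)):
        m = rows_of_mate[i]
        if m < 0:
            continue
        for col in range(start[i], start[i] + off[i + 1] - off[i]):
            D[m, col] += 1


@njit(cache=True)
def _emission_stat_logp(cnt, sl1q, slq3, m, col, s, em_sc):
    """Summed emission log-likelihood at (m, col) if the haplotype symbol is s."""
    nb = 0.0
    slq3_tot = 0.0
    for b in range(4):
        nb += cnt[m, col, b]
        slq3_tot += slq3[m, col, b]
    n_n = cnt[m, col, 4]
    n_gap = cnt[m, col, 5]
    if s < 4:
        return (em_sc[EM_C_BASE] * nb + sl1q[m, col, s]
                + (slq3_tot - slq3[m, col, s])
                + n_gap * em_sc[EM_L_DEL] + n_n * em_sc[EM_L_N])
    elif s == 5:  # gap
        return (nb * em_sc[EM_L_INS4] + n_gap * em_sc[EM_L_GAPSTAY]
                + n_n * em_sc[EM_L_N])
    else:  # N
        return (nb * em_sc[EM_L_NBASE] + n_gap * em_sc[EM_L_DEL]
                + n_n * em_sc[EM_L_N])


@njit(cache=True)
def gibbs_sequences(S_n, S_t, R_rows, R_imp, germ, som,
                    cnt_n, sl1q_n, slq3_n, cnt_t, sl1q_t, slq3_t,
                    em_sc, beta, rng):
    """Per-position Gibbs scan of all normal then tumor haplotype symbols.

    The normal symbol's conditional combines the germline prior, the
    somatic prior to the current tumor symbol, and emissions of reads
    currently assigned to the normal haplotype (from either sample); the
    tumor symbol's conditional combines the somatic prior from the fresh
    normal symbol and emissions of tumor-origin reads.
    """
    n_rows, ncol = S_n.shape
    logits = np.empty(6)
    for m in range(n_rows):
        d = 1 if m >= 2 else 0
        for col in range(ncol):
            r = R_rows[m, col]
            imp = R_imp[m, col]
            st_sym = S_t[m, col]
            for s in range(6):
                logits[s] = beta * (germ[d, imp, r, s] + som[s, st_sym]
                                    + _emission_stat_logp(
                                        cnt_n, sl1q_n, slq3_n, m, col, s,
                                        em_sc))
            sn = _sample_from_logits(logits, rng)
            S_n[m, col] = sn
            for s in range(6):
                logits[s] = beta * (som[sn, s] + _emission_stat_logp(
                    cnt_t, sl1q_t, slq3_t, m, col, s, em_sc))
            S_t[m, col] = _sample_from_logits(logits, rng)


@njit(cache=True)
def type_logliks(S_row, panel_rows, panel_imp, germ, decoy):
    """Germline log-likelihood of one normal haplotype under every allele."""
    K, ncol = panel_rows.shape
    out = np.zeros(K)
    for k in range(K):
        tot = 0.0
        for col in range(ncol):
            tot += germ[decoy, panel_imp[k, col], panel_rows[k, col],
                        S_row[col]]
        out[k] = tot
    return out


@njit(cache=True)
def gibbs_types(S_n, panel_rows, panel_imp, logp_t, germ, beta, rng):
    """Gibbs draw of every reference pick from its exact conditional."""
    n_rows = S_n.shape[0]
    K = panel_rows.shape[0]
    R_idx = np.empty(n_rows, dtype=np.int64)
    for m in range(n_rows):
        d = 1 if m >= 2 else 0
        ll = type_logliks(S_n[m], panel_rows, panel_imp, germ, d)
        logits = np.empty(K)
        for k in range(K):
            prior = logp_t[k] if m < 2 else 0.0
            logits[k] = beta * (prior + ll[k])
        R_idx[m] = _sample_from_logits(logits, rng)
    return R_idx


@njit(cache=True)
def mismatch_counts_vs_refs(sym, off, start, R0, R1):
    """Per mate, the minimum base-mismatch count against the two references."""
    n = len(start)
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        o0 = off[i]
        ln = off[i + 1] - o0
        st = start[i]
        mm0 = 0
        mm1 = 0
        for p in range(ln):
            x = sym[o0 + p]
            if x < 4:
                if R0[st + p] < 4 and x != R0[st + p]:
                    mm0 += 1
                if R1[st + p] < 4 and x != R1[st + p]:
                    mm1 += 1
        out[i] = min(mm0, mm1)
    return out
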