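"""MCMC sampling of the joint model.

The sampler mixes several move classes within one sweep:

* exact Gibbs scans of the haplotype sequences, reference picks, and
  read-origin indicators;
* Metropolis-Hastings on each ``F`` with a log-normal random walk (the
  multiplicative proposal is symmetric in ``log F``; the ``F*/F`` Jacobian
  is included so the chain targets the density of ``F`` itself);
* a cluster move on each decoy's validity flags: a contiguous run of
  equal flags is grown stochastically and flipped (Wolff-style), the
  indicators are refreshed, and the move is accepted against the
  indicator-marginalized likelihood so the joint update is exact;
* a decoy-swap move exchanging a sequence interval between a genotype
  haplotype and a decoy, with reference picks and indicators refreshed
  under the proposal and an acceptance ratio in which both are
  marginalized out;
* a blocked move resampling a row's reference pick and matched
  normal/tumor sequences together, proposing from read-coverage-masked
  sequences (uncovered positions read as ``N``);
* burn-in-only heuristics (periodic reference copying; pushing
  high-mismatch reads onto decoys), never applied after burn-in so the
  retained samples are unbiased.

Multistart pilot chains choose the initial state and parallel tempering
moves the cold chain between posterior modes.  All randomness flows from
a single seed; runs are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from hlabayesnt.alphabet import N as N_SYM
from hlabayesnt.config import HyperParameters, lognormal_logpdf
from hlabayesnt import _kernels as K
from hlabayesnt.model import (
    ModelState,
    _as_packed,
    build_emission_tables,
    build_germline_tables,
    build_somatic_table,
)
from hlabayesnt.reference_panel import AlleleFrequencyTable, AlleleMSA

__all__ = [
    "ChainConfig",
    "PosteriorSamples",
    "run_mcmc",
    "gibbs_update_indicators",
    "gibbs_update_sequences",
    "gibbs_update_types",
    "mh_update_frequency",
    "wolff_propose_validity",
    "mh_update_validity",
    "swap_segment_move",
    "blocked_type_sequence_move",
    "heuristic_moves",
]


@dataclass
class ChainConfig:
    """Run-length, tempering, and move-schedule settings of one MCMC run."""

    n_iterations: int = 800
    burn_in: int = 300
    thinning: int = 2
    n_starts: int = 8
    pilot_sweeps: int = 50
    temperature_ladder: tuple = (3.375, 2.25, 1.5, 1.0)
    seed: int = 0
    heuristic_period: int = 20
    special_move_period: int = 5
    # move-class switches (base Gibbs scans always run)
    enable_frequency: bool = True
    enable_validity: bool = True
    enable_swap: bool = True
    enable_blocked: bool = True
    enable_heuristics: bool = True
    enable_tempering: bool = True
    # hold F and G fixed (used when comparing against enumeration, where
    # the continuous scalars are conditioned on rather than integrated)
    freeze_scalars: bool = False

    def __post_init__(self):
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        ladder = tuple(sorted(self.temperature_ladder, reverse=True))
        if not math.isclose(ladder[-1], 1.0):
            raise ValueError("temperature ladder must end at 1.0")
        if any(t < 1.0 for t in ladder):
            raise ValueError("temperatures must be >= 1")
        self.temperature_ladder = ladder
        if self.thinning < 1 or self.n_starts < 1:
            raise ValueError("thinning and n_starts must be >= 1")


@dataclass
class PosteriorSamples:
    """Retained cold-chain draws plus the per-sweep log-posterior trace."""

    allele_names: list
    n_decoys: int
    n_columns: int
    sweeps: np.ndarray
    R_idx: np.ndarray
    S_n: np.ndarray
    S_t: np.ndarray
    V: np.ndarray
    F: np.ndarray
    G: np.ndarray
    logpost_trace: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sweeps)

    def genotype_pairs(self) -> list:
        """Unordered genotype pair (allele names) of every retained draw."""
        out = []
        for s in range(self.n_samples):
            a = self.allele_names[self.R_idx[s, 0]]
            b = self.allele_names[self.R_idx[s, 1]]
            out.append(tuple(sorted((a, b))))
        return out

    def write_trace_tsv(self, path) -> None:
        with open(path, "w") as fh:
            n_rows = self.F.shape[1] if self.n_samples else 0
            fcols = "\t".join(f"F{m + 1}" for m in range(n_rows))
            fh.write(f"sweep\tlog_posterior\tG\t{fcols}\n".rstrip() + "\n")
            for s in range(self.n_samples):
                sweep = int(self.sweeps[s])
                fvals = "\t".join(f"{x:.6g}" for x in self.F[s])
                fh.write(f"{sweep}\t{self.logpost_trace[sweep]:.6f}\t"
                         f"{self.G[s]:.6g}\t{fvals}\n".rstrip() + "\n")

    def write_genotype_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sweep\tallele1\tallele2\n")
            for s, (a, b) in zip(self.sweeps, self.genotype_pairs()):
                fh.write(f"{int(s)}\t{a}\t{b}\n")

    def consensus_matrix(self, row: int, sample: str = "normal") -> np.ndarray:
        """Per-column symbol frequencies of one haplotype row, ``(N, 6)``."""
        seqs = self.S_n if sample == "normal" else self.S_t
        out = np.zeros((self.n_columns, 6))
        for s in range(self.n_samples):
            out[np.arange(self.n_columns), seqs[s, row]] += 1
        return out / max(self.n_samples, 1)


# ---------------------------------------------------------------------------
# sampler context and chain runner

class _Context:
    """Immutable per-locus data shared by all chains: reads, panel, tables."""

    def __init__(self, reads, msa: AlleleMSA, freqs: AlleleFrequencyTable,
                 h: HyperParameters):
        self.pr = _as_packed(reads)
        self.msa = msa
        self.freqs = freqs
        self.h = h
        self.em_const, self.em_kind = build_emission_tables(h)
        self.som = build_somatic_table(h)
        self.germ = build_germline_tables(h)
        self.em_sc = np.array([
            math.log(1.0 - h.err_del - h.err_n),
            math.log(h.err_del),
            math.log(h.err_n),
            math.log(h.err_ins / 4.0),
            math.log(1.0 - h.err_ins - h.err_n),
            math.log((1.0 - h.err_del - h.err_n) / 4.0),
        ])
        self.panel_rows = np.ascontiguousarray(msa.rows)
        self.panel_imp = np.ascontiguousarray(
            msa.imputed_mask.astype(np.uint8))
        self.logp_t = freqs.log_probs(msa.allele_names)
        self.n_rows = h.n_decoys + 2
        self.ncol = msa.n_columns


class _Chain:
    """One tempered chain: state arrays plus per-sweep caches."""

    def __init__(self, ctx: _Context, rng: np.random.Generator,
                 beta: float = 1.0, cfg: ChainConfig = None):
        self.ctx = ctx
        self.rng = rng
        self.beta = beta
        self.cfg = cfg or ChainConfig()
        n_rows, ncol = ctx.n_rows, ctx.ncol
        self.R_idx = np.zeros(n_rows, dtype=np.int64)
        # S stacks normal rows then tumor rows so that tumor-read
        # candidates are exactly its rows
        self.S = np.zeros((2 * n_rows, ncol), dtype=np.uint8)
        self.F = np.ones(n_rows)
        self.G = math.exp(ctx.h.contam_mu)
        self.V = np.ones((n_rows, ncol), dtype=np.uint8)
        self.I_n = np.zeros(ctx.pr.n_normal, dtype=np.int64)
        self.I_t = np.zeros(ctx.pr.n_tumor, dtype=np.int64)
        self._R_rows = np.zeros((n_rows, ncol), dtype=np.uint8)
        self._R_imp = np.zeros((n_rows, ncol), dtype=np.uint8)
        self._L_dirty = True
        self._valid_dirty = True
        self.Lp_n = None
        self.Lp_t = None
        self.valid_n = None
        self.valid_t = None

    # -- state plumbing ----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.ctx.n_rows

    @property
    def S_n(self) -> np.ndarray:
        return self.S[:self.n_rows]

    @property
    def S_t(self) -> np.ndarray:
        return self.S[self.n_rows:]

    def _refresh_R(self) -> None:
        self._R_rows = np.ascontiguousarray(self.ctx.panel_rows[self.R_idx])
        self._R_imp = np.ascontiguousarray(self.ctx.panel_imp[self.R_idx])

    def load_state(self, state: ModelState) -> None:
        self.R_idx = state.R_idx.copy()
        self.S[:self.n_rows] = state.S_n
        self.S[self.n_rows:] = state.S_t
        self.F = state.F.copy()
        self.G = float(state.G)
        self.V = state.V.copy()
        self.I_n = state.I_n.copy()
        self.I_t = state.I_t.copy()
        self._refresh_R()
        self._L_dirty = True
        self._valid_dirty = True

    def export_state(self) -> ModelState:
        return ModelState(self.R_idx.copy(), self.S_n.copy(), self.S_t.copy(),
                          self.F.copy(), self.G, self.V.copy(),
                          self.I_n.copy(), self.I_t.copy())

    def init_state(self, genotype_init: tuple = None) -> None:
        """Draw an overdispersed starting point from the priors.

        ``genotype_init`` pins the two reference picks (used by the
        multistart driver to seed pilots from read-vote-supported
        alleles).
        """
        ctx, rng = self.ctx, self.rng
        p = np.exp(ctx.logp_t)
        p /= p.sum()
        if genotype_init is not None:
            self.R_idx[0], self.R_idx[1] = genotype_init
        else:
            self.R_idx[0] = rng.choice(len(p), p=p)
            self.R_idx[1] = rng.choice(len(p), p=p)
        for m in range(2, self.n_rows):
            self.R_idx[m] = rng.integers(len(p))
        self._refresh_R()
        self.S[:self.n_rows] = self._R_rows
        self.S[self.n_rows:] = self._R_rows
        self.F[:2] = math.exp(ctx.h.freq_mu_ref)
        self.F[2:] = math.exp(ctx.h.freq_mu_decoy)
        self.G = math.exp(ctx.h.contam_mu)
        self.V[:] = 1
        self._L_dirty = True
        self._valid_dirty = True
        self.update_indicators()

    def _ensure_L(self) -> None:
        if not self._L_dirty:
            return
        pr = self.ctx.pr
        Lm = K.mate_logliks_tbl(pr.normal.sym, pr.normal.l1q, pr.normal.lq3,
                                pr.normal.off, pr.normal.start,
                                self.S[:self.n_rows],
                                self.ctx.em_const, self.ctx.em_kind)
        self.Lp_n = K.pair_sum(Lm, pr.normal.pair_of_mate, pr.n_normal)
        Lm = K.mate_logliks_tbl(pr.tumor.sym, pr.tumor.l1q, pr.tumor.lq3,
                                pr.tumor.off, pr.tumor.start, self.S,
                                self.ctx.em_const, self.ctx.em_kind)
        self.Lp_t = K.pair_sum(Lm, pr.tumor.pair_of_mate, pr.n_tumor)
        self._L_dirty = False

    def _ensure_valid(self) -> None:
        if not self._valid_dirty:
            return
        pr = self.ctx.pr
        self.valid_n = K.pair_valid(self.V, pr.normal.start,
                                    pr.normal.length, pr.normal.pair_of_mate,
                                    pr.n_normal)
        self.valid_t = K.pair_valid(self.V, pr.tumor.start, pr.tumor.length,
                                    pr.tumor.pair_of_mate, pr.n_tumor)
        self._valid_dirty = False

    def _logw_n(self) -> np.ndarray:
        return np.log(self.F)

    def _logw_t(self) -> np.ndarray:
        lf = np.log(self.F)
        return np.concatenate([lf + math.log(self.G), lf])

    def _validC_t(self) -> np.ndarray:
        return np.concatenate([self.valid_t, self.valid_t], axis=1)

    # -- Gibbs moves -------------------------------------------------------

    def update_indicators(self) -> None:
        self._ensure_L()
        self._ensure_valid()
        pr = self.ctx.pr
        self.I_n, _, _ = K.sample_indicators(
            self.Lp_n, self.valid_n, self._logw_n(), self.beta, self.rng)
        self.I_t, _, _ = K.sample_indicators(
            self.Lp_t, self._validC_t(), self._logw_t(), self.beta, self.rng)
        if pr.n_normal and (~self.valid_n.any(axis=1)).any():
            raise ValueError("a normal read pair has no valid candidate")
        if pr.n_tumor and (~self.valid_t.any(axis=1)).any():
            raise ValueError("a tumor read pair has no valid candidate")

    def _rows_of_mates(self):
        """Kernel row targets: (normal-row rows for normal mates, normal-row
        rows for tumor mates, tumor-row rows for tumor mates)."""
        pr = self.ctx.pr
        rn = self.I_n[pr.normal.pair_of_mate] if pr.normal.n_mates else \
            np.empty(0, dtype=np.int64)
        it = self.I_t[pr.tumor.pair_of_mate] if pr.tumor.n_mates else \
            np.empty(0, dtype=np.int64)
        rt_norm = np.where(it < self.n_rows, it, -1)
        rt_tum = np.where(it >= self.n_rows, it - self.n_rows, -1)
        return rn, rt_norm, rt_tum

    def update_sequences(self) -> None:
        ctx = self.ctx
        pr = ctx.pr
        n_rows, ncol = self.n_rows, ctx.ncol
        cnt_n = np.zeros((n_rows, ncol, 6))
        sl1q_n = np.zeros((n_rows, ncol, 4))
        slq3_n = np.zeros((n_rows, ncol, 4))
        cnt_t = np.zeros((n_rows, ncol, 6))
        sl1q_t = np.zeros((n_rows, ncol, 4))
        slq3_t = np.zeros((n_rows, ncol, 4))
        rn, rt_norm, rt_tum = self._rows_of_mates()
        K.accumulate_stats(pr.normal.sym, pr.normal.l1q, pr.normal.lq3,
                           pr.normal.off, pr.normal.start, rn,
                           cnt_n, sl1q_n, slq3_n)
        K.accumulate_stats(pr.tumor.sym, pr.tumor.l1q, pr.tumor.lq3,
                           pr.tumor.off, pr.tumor.start, rt_norm,
                           cnt_n, sl1q_n, slq3_n)
        K.accumulate_stats(pr.tumor.sym, pr.tumor.l1q, pr.tumor.lq3,
                           pr.tumor.off, pr.tumor.start, rt_tum,
                           cnt_t, sl1q_t, slq3_t)
        K.gibbs_sequences(self.S[:n_rows], self.S[n_rows:],
                          self._R_rows, self._R_imp, ctx.germ, ctx.som,
                          cnt_n, sl1q_n, slq3_n, cnt_t, sl1q_t, slq3_t,
                          ctx.em_sc, self.beta, self.rng)
        self._L_dirty = True

    def update_types(self) -> None:
        ctx = self.ctx
        self.R_idx = K.gibbs_types(self.S[:self.n_rows], ctx.panel_rows,
                                   ctx.panel_imp, ctx.logp_t, ctx.germ,
                                   self.beta, self.rng)
        self._refresh_R()

    # -- Metropolis-Hastings moves ----------------------------------------

    def update_frequency(self) -> None:
        """One log-normal random-walk MH step per haplotype's ``F``."""
        ctx, h = self.ctx, self.ctx.h
        self._ensure_valid()
        counts = np.zeros(self.n_rows)
        for m in self.I_n:
            counts[m] += 1
        for m in self.I_t:
            counts[m % self.n_rows] += 1
        for m in range(self.n_rows):
            f_old = self.F[m]
            f_new = math.exp(math.log(f_old)
                             + h.freq_proposal_sigma * self.rng.normal())
            mu, sig = ((h.freq_mu_ref, h.freq_sigma_ref) if m < 2
                       else (h.freq_mu_decoy, h.freq_sigma_decoy))
            dlf = math.log(f_new) - math.log(f_old)
            F_new = self.F.copy()
            F_new[m] = f_new
            w_n_old = self.valid_n @ self.F
            w_n_new = self.valid_n @ F_new
            w_t_old = self.valid_t @ (self.F * (1.0 + self.G))
            w_t_new = self.valid_t @ (F_new * (1.0 + self.G))
            dlogW = (np.log(w_n_new).sum() - np.log(w_n_old).sum()
                     + np.log(w_t_new).sum() - np.log(w_t_old).sum())
            dlog = self.beta * (counts[m] * dlf - dlogW
                                + lognormal_logpdf(f_new, mu, sig)
                                - lognormal_logpdf(f_old, mu, sig))
            dlog += dlf  # Jacobian of the log-scale random walk
            if dlog >= 0 or self.rng.random() < math.exp(dlog):
                self.F[m] = f_new

    def update_contamination(self) -> None:
        """Log-normal random-walk MH on the normal-cell fraction ``G``."""
        h = self.ctx.h
        self._ensure_valid()
        g_old = self.G
        g_new = math.exp(math.log(g_old)
                         + h.freq_proposal_sigma * self.rng.normal())
        dlg = math.log(g_new) - math.log(g_old)
        n_norm_origin = int((self.I_t < self.n_rows).sum())
        w_old = self.valid_t @ (self.F * (1.0 + g_old))
        w_new = self.valid_t @ (self.F * (1.0 + g_new))
        dlogW = float(np.log(w_new).sum() - np.log(w_old).sum())
        dlog = self.beta * (n_norm_origin * dlg - dlogW
                            + lognormal_logpdf(g_new, h.contam_mu,
                                               h.contam_sigma)
                            - lognormal_logpdf(g_old, h.contam_mu,
                                               h.contam_sigma))
        dlog += dlg  # Jacobian
        if dlog >= 0 or self.rng.random() < math.exp(dlog):
            self.G = g_new

    def wolff_propose(self, m: int):
        """Grow and flip a run of equal validity flags on decoy row ``m``.

        Returns ``(V_row*, b, e, dlogq)`` with 0-based inclusive cluster
        bounds and the proposal log-ratio ``log q(rev) - log q(fwd)``.
        """
        h = self.ctx.h
        V = self.V[m]
        ncol = len(V)
        p = int(self.rng.integers(ncol))
        v = int(V[p])
        pi = (h.wolff_ext0, h.wolff_ext1)
        b = p
        while b > 0 and V[b - 1] == v:
            if self.rng.random() < 1.0 - pi[v]:
                break
            b -= 1
        e = p
        while e < ncol - 1 and V[e + 1] == v:
            if self.rng.random() < 1.0 - pi[v]:
                break
            e += 1
        V_new = V.copy()
        V_new[b:e + 1] = 1 - v
        # proposal ratio: reverse grows a (1-v)-cluster over the same span
        dlogq = (e - b) * (math.log(pi[1 - v]) - math.log(pi[v]))
        for edge, inside in ((b - 1, b > 0), (e + 1, e < ncol - 1)):
            if inside:
                if V[edge] == v:  # forward stopped by a break draw
                    dlogq -= math.log(1.0 - pi[v])
                else:  # natural bound; reverse must draw a break here
                    dlogq += math.log(1.0 - pi[1 - v])
        return V_new, b, e, dlogq

    def _chain_logp(self, row: np.ndarray) -> float:
        h = self.ctx.h
        lo, le = math.log(h.valid_open), math.log(h.valid_ext)
        lno, lne = math.log(1 - h.valid_open), math.log(1 - h.valid_ext)
        prev = 0
        total = 0.0
        for v in row:
            if prev == 1:
                total += le if v == 1 else lne
            else:
                total += lo if v == 1 else lno
            prev = v
        return total

    def update_validity(self, m: int) -> None:
        """Cluster-flip MH on decoy row ``m`` with indicators refreshed."""
        if m < 2:
            raise ValueError("validity flags of nondecoy rows are fixed at 1")
        ctx = self.ctx
        pr = ctx.pr
        self._ensure_L()
        self._ensure_valid()
        V_row_new, _, _, dlogq = self.wolff_propose(m)
        V_new = self.V.copy()
        V_new[m] = V_row_new
        valid_n_new = K.pair_valid(V_new, pr.normal.start, pr.normal.length,
                                   pr.normal.pair_of_mate, pr.n_normal)
        valid_t_new = K.pair_valid(V_new, pr.tumor.start, pr.tumor.length,
                                   pr.tumor.pair_of_mate, pr.n_tumor)
        if ((pr.n_normal and not valid_n_new.any(axis=1).all())
                or (pr.n_tumor and not valid_t_new.any(axis=1).all())):
            return  # proposal would leave a read unexplainable
        logw_n, logw_t = self._logw_n(), self._logw_t()
        z_n, w_n = K.indicator_marginals(self.Lp_n, self.valid_n, logw_n,
                                         self.beta)
        z_t, w_t = K.indicator_marginals(self.Lp_t, self._validC_t(), logw_t,
                                         self.beta)
        validC_t_new = np.concatenate([valid_t_new, valid_t_new], axis=1)
        z_n2, w_n2 = K.indicator_marginals(self.Lp_n, valid_n_new, logw_n,
                                           self.beta)
        z_t2, w_t2 = K.indicator_marginals(self.Lp_t, validC_t_new, logw_t,
                                           self.beta)
        dlog = (self.beta * (self._chain_logp(V_row_new)
                             - self._chain_logp(self.V[m]))
                + dlogq
                + (z_n2.sum() - z_n.sum()) + (z_t2.sum() - z_t.sum())
                - (w_n2.sum() - w_n.sum()) - (w_t2.sum() - w_t.sum()))
        if dlog >= 0 or self.rng.random() < math.exp(dlog):
            self.V = V_new
            self.valid_n = valid_n_new
            self.valid_t = valid_t_new
            self.I_n, _, _ = K.sample_indicators(
                self.Lp_n, self.valid_n, logw_n, self.beta, self.rng)
            self.I_t, _, _ = K.sample_indicators(
                self.Lp_t, self._validC_t(), logw_t, self.beta, self.rng)

    # -- multimodality moves ----------------------------------------------

    def _type_marginal(self, m: int, S_row: np.ndarray) -> float:
        """Tempered log-marginal over the reference pick of one row."""
        ctx = self.ctx
        d = 1 if m >= 2 else 0
        ll = K.type_logliks(S_row, ctx.panel_rows, ctx.panel_imp, ctx.germ, d)
        logits = self.beta * (ll + (ctx.logp_t if m < 2 else 0.0))
        return _logsumexp(logits)

    def _sample_type(self, m: int, S_row: np.ndarray) -> int:
        ctx = self.ctx
        d = 1 if m >= 2 else 0
        ll = K.type_logliks(S_row, ctx.panel_rows, ctx.panel_imp, ctx.germ, d)
        logits = self.beta * (ll + (ctx.logp_t if m < 2 else 0.0))
        return _categorical(logits, self.rng)

    def swap_segment(self) -> None:
        """Swap an interval of matched sequences with a decoy, exactly.

        The interval must be fully valid on the decoy; reference picks of
        the two rows and all indicators are refreshed under the proposal,
        and both are marginalized out of the acceptance ratio.
        """
        if self.n_rows < 3:
            return
        pr = self.ctx.pr
        rng = self.rng
        m = int(rng.integers(2))
        mp = 2 + int(rng.integers(self.n_rows - 2))
        # half the proposals use the longest valid run so a whole
        # haplotype stranded on a decoy can migrate in one move; the
        # interval distribution depends only on V, so the proposal stays
        # symmetric either way
        if rng.random() < 0.5:
            iv = _longest_valid_run(self.V[mp])
        else:
            iv = _sample_valid_interval(self.V[mp], rng)
        if iv is None:
            return
        a, b = iv
        self._ensure_L()
        self._ensure_valid()
        logw_n, logw_t = self._logw_n(), self._logw_t()
        z_n, _ = K.indicator_marginals(self.Lp_n, self.valid_n, logw_n,
                                       self.beta)
        z_t, _ = K.indicator_marginals(self.Lp_t, self._validC_t(), logw_t,
                                       self.beta)
        zr_old = self._type_marginal(m, self.S_n[m]) \
            + self._type_marginal(mp, self.S_n[mp])
        sl = slice(a, b + 1)
        n_rows = self.n_rows
        # swap both normal and tumor content; the somatic factor over the
        # interval is invariant because matched pairs move together
        for r1, r2 in ((m, mp), (m + n_rows, mp + n_rows)):
            tmp = self.S[r1, sl].copy()
            self.S[r1, sl] = self.S[r2, sl]
            self.S[r2, sl] = tmp
        self._L_dirty = True
        self._ensure_L()
        z_n2, _ = K.indicator_marginals(self.Lp_n, self.valid_n, logw_n,
                                        self.beta)
        z_t2, _ = K.indicator_marginals(self.Lp_t, self._validC_t(), logw_t,
                                        self.beta)
        zr_new = self._type_marginal(m, self.S_n[m]) \
            + self._type_marginal(mp, self.S_n[mp])
        dlog = (zr_new - zr_old) + (z_n2.sum() - z_n.sum()) \
            + (z_t2.sum() - z_t.sum())
        if dlog >= 0 or rng.random() < math.exp(dlog):
            self.R_idx[m] = self._sample_type(m, self.S_n[m])
            self.R_idx[mp] = self._sample_type(mp, self.S_n[mp])
            self._refresh_R()
            self.I_n, _, _ = K.sample_indicators(
                self.Lp_n, self.valid_n, logw_n, self.beta, self.rng)
            self.I_t, _, _ = K.sample_indicators(
                self.Lp_t, self._validC_t(), logw_t, self.beta, self.rng)
        else:  # revert
            for r1, r2 in ((m, mp), (m + n_rows, mp + n_rows)):
                tmp = self.S[r1, sl].copy()
                self.S[r1, sl] = self.S[r2, sl]
                self.S[r2, sl] = tmp
            self._L_dirty = True

    def tumor_swap(self) -> None:
        """Swap a tumor-sequence interval between a genotype row and any
        other row, with tumor indicators refreshed and marginalized.

        Two failure modes of plain Gibbs dissolve under this move: a
        heterozygous site phased onto opposite haplotypes in the normal
        and tumor samples (reads as two reciprocal somatic substitutions),
        and somatic content stranded on a decoy, whose permissive
        germline prior lets it adopt tumor-only variants first.  The
        interval distribution depends only on the partner's validity row,
        which the swap leaves unchanged, so the proposal is symmetric.
        """
        pr = self.ctx.pr
        if pr.n_tumor == 0:
            return
        rng = self.rng
        m = int(rng.integers(2))
        mp = int(rng.integers(self.n_rows - 1))
        if mp >= m:
            mp += 1
        if rng.random() < 0.5:
            iv = _longest_valid_run(self.V[mp])
        else:
            iv = _sample_valid_interval(self.V[mp], rng)
        if iv is None:
            return
        a, b = iv
        sl = slice(a, b + 1)
        self._ensure_L()
        self._ensure_valid()
        logw_t = self._logw_t()
        z_t, _ = K.indicator_marginals(self.Lp_t, self._validC_t(), logw_t,
                                       self.beta)
        som = self.ctx.som
        som_old = float(som[self.S_n[m, sl], self.S_t[m, sl]].sum()
                        + som[self.S_n[mp, sl], self.S_t[mp, sl]].sum())
        r0, r1 = self.n_rows + m, self.n_rows + mp
        tmp = self.S[r0, sl].copy()
        self.S[r0, sl] = self.S[r1, sl]
        self.S[r1, sl] = tmp
        self._L_dirty = True
        self._ensure_L()
        som_new = float(som[self.S_n[m, sl], self.S_t[m, sl]].sum()
                        + som[self.S_n[mp, sl], self.S_t[mp, sl]].sum())
        z_t2, _ = K.indicator_marginals(self.Lp_t, self._validC_t(), logw_t,
                                        self.beta)
        dlog = self.beta * (som_new - som_old) + (z_t2.sum() - z_t.sum())
        if dlog >= 0 or rng.random() < math.exp(dlog):
            self.I_t, _, _ = K.sample_indicators(
                self.Lp_t, self._validC_t(), logw_t, self.beta, self.rng)
        else:
            tmp = self.S[r0, sl].copy()
            self.S[r0, sl] = self.S[r1, sl]
            self.S[r1, sl] = tmp
            self._L_dirty = True

    def somatic_reset(self, m: int, window: int = 25) -> None:
        """Redraw a window of one tumor row from the somatic prior.

        The proposal draws ``S_t`` over a random window from
        ``p(S_t | S_n)`` (mostly the identity), then refreshes the tumor
        indicators; because the proposal density cancels against the
        somatic prior, acceptance reduces to the indicator-marginalized
        tumor evidence ratio.  This dissolves spurious tumor-only
        deviations that read reassignment alone cannot unwind.
        """
        pr = self.ctx.pr
        if pr.n_tumor == 0:
            return
        rng = self.rng
        ncol = self.ctx.ncol
        a = int(rng.integers(ncol))
        b = min(a + window, ncol)
        sl = slice(a, b)
        self._ensure_L()
        self._ensure_valid()
        logw_t = self._logw_t()
        z_t, _ = K.indicator_marginals(self.Lp_t, self._validC_t(), logw_t,
                                       self.beta)
        old = self.S[m + self.n_rows, sl].copy()
        logits = self.beta * self.ctx.som[self.S_n[m, sl]]
        draws, _ = _categorical_rows(logits, rng)
        self.S[m + self.n_rows, sl] = draws.astype(np.uint8)
        self._L_dirty = True
        self._ensure_L()
        z_t2, _ = K.indicator_marginals(self.Lp_t, self._validC_t(), logw_t,
                                        self.beta)
        dlog = z_t2.sum() - z_t.sum()
        if dlog >= 0 or rng.random() < math.exp(dlog):
            self.I_t, _, _ = K.sample_indicators(
                self.Lp_t, self._validC_t(), logw_t, self.beta, self.rng)
        else:
            self.S[m + self.n_rows, sl] = old
            self._L_dirty = True

    def _coverage(self) -> np.ndarray:
        """Read-depth per (row, column), pooling matched normal/tumor rows."""
        pr = self.ctx.pr
        D = np.zeros((self.n_rows, self.ctx.ncol), dtype=np.int64)
        rn, rt_norm, rt_tum = self._rows_of_mates()
        K.accumulate_coverage(pr.normal.off, pr.normal.start, rn, D)
        K.accumulate_coverage(pr.tumor.off, pr.tumor.start, rt_norm, D)
        K.accumulate_coverage(pr.tumor.off, pr.tumor.start, rt_tum, D)
        return D

    def _row_mate_logliks(self, m: int, S_n_row, S_t_row) -> float:
        """Emission log-likelihood of all mates assigned to row ``m``."""
        pr = self.ctx.pr
        rn, rt_norm, rt_tum = self._rows_of_mates()
        S2 = np.ascontiguousarray(np.stack([S_n_row, S_t_row]))
        total = 0.0
        idx = np.flatnonzero(rn == m).astype(np.int64)
        if idx.size:
            L = K.mate_logliks_subset(pr.normal.sym, pr.normal.l1q,
                                      pr.normal.lq3, pr.normal.off,
                                      pr.normal.start, idx, S2,
                                      self.ctx.em_const, self.ctx.em_kind)
            total += float(L[:, 0].sum())
        idx = np.flatnonzero(rt_norm == m).astype(np.int64)
        if idx.size:
            L = K.mate_logliks_subset(pr.tumor.sym, pr.tumor.l1q,
                                      pr.tumor.lq3, pr.tumor.off,
                                      pr.tumor.start, idx, S2,
                                      self.ctx.em_const, self.ctx.em_kind)
            total += float(L[:, 0].sum())
        idx = np.flatnonzero(rt_tum == m).astype(np.int64)
        if idx.size:
            L = K.mate_logliks_subset(pr.tumor.sym, pr.tumor.l1q,
                                      pr.tumor.lq3, pr.tumor.off,
                                      pr.tumor.start, idx, S2,
                                      self.ctx.em_const, self.ctx.em_kind)
            total += float(L[:, 1].sum())
        return total

    def _blocked_propose_row(self, m, S_nN, S_tN):
        """Draw (R*, S_n*, S_t*) for row m from the masked-sequence ladder;
        returns the draw and its tempered proposal log-density."""
        ctx, rng = self.ctx, self.rng
        d = 1 if m >= 2 else 0
        ll = K.type_logliks(S_nN, ctx.panel_rows, ctx.panel_imp, ctx.germ, d)
        logits = self.beta * (ll + (ctx.logp_t if m < 2 else 0.0))
        r_new = _categorical(logits, rng)
        logq = logits[r_new] - _logsumexp(logits)
        r_row = ctx.panel_rows[r_new]
        r_imp = ctx.panel_imp[r_new].astype(np.intp)
        lg = ctx.germ[d][r_imp, r_row]            # (N, 6)
        ls = ctx.som[:, S_tN].T                   # (N, 6)
        logits_n = self.beta * (lg + ls)
        s_n, lq = _categorical_rows(logits_n, rng)
        logq += lq
        logits_t = self.beta * ctx.som[s_n]       # (N, 6)
        s_t, lq = _categorical_rows(logits_t, rng)
        logq += lq
        return r_new, s_n.astype(np.uint8), s_t.astype(np.uint8), logq

    def _blocked_eval_row(self, m, S_nN, S_tN, r_idx, s_n, s_t) -> float:
        """Tempered log-density that the ladder proposal generates the
        given (R, S_n, S_t) for row m."""
        ctx = self.ctx
        d = 1 if m >= 2 else 0
        ll = K.type_logliks(S_nN, ctx.panel_rows, ctx.panel_imp, ctx.germ, d)
        logits = self.beta * (ll + (ctx.logp_t if m < 2 else 0.0))
        logq = logits[r_idx] - _logsumexp(logits)
        r_row = ctx.panel_rows[r_idx]
        r_imp = ctx.panel_imp[r_idx].astype(np.intp)
        logits_n = self.beta * (ctx.germ[d][r_imp, r_row]
                                + ctx.som[:, S_tN].T)
        logq += _rows_logprob(logits_n, s_n)
        logits_t = self.beta * ctx.som[s_n]
        logq += _rows_logprob(logits_t, s_t)
        return logq

    def _row_prior_logp(self, m, r_idx, s_n, s_t) -> float:
        """Type + germline + somatic log-prior of one row (untempered)."""
        ctx = self.ctx
        d = 1 if m >= 2 else 0
        r_row = ctx.panel_rows[r_idx]
        r_imp = ctx.panel_imp[r_idx].astype(np.intp)
        lp = float(ctx.germ[d][r_imp, r_row, s_n].sum())
        lp += float(ctx.som[s_n, s_t].sum())
        lp += float(ctx.logp_t[r_idx]) if m < 2 else \
            -math.log(ctx.panel_rows.shape[0])
        return lp

    def blocked_row_move(self, m: int) -> None:
        """Joint MH resampling of (R_m, S_n_m, S_t_m) via coverage masking.

        The reference pick and matched sequences of one row are proposed
        from a ladder conditioned on coverage-masked sequences; all
        indicators are then refreshed under the proposal and marginalized
        out of the acceptance ratio, so reads can follow the row to a new
        genotype mode in one move.  The reverse ladder density uses the
        proposal's own coverage mask.
        """
        D = self._coverage()
        cov = D[m] > 0
        S_nN = np.where(cov, self.S_n[m], N_SYM).astype(np.uint8)
        S_tN = np.where(cov, self.S_t[m], N_SYM).astype(np.uint8)
        r_new, s_n_new, s_t_new, logq_fwd = self._blocked_propose_row(
            m, S_nN, S_tN)
        d_prior = (self._row_prior_logp(m, r_new, s_n_new, s_t_new)
                   - self._row_prior_logp(m, int(self.R_idx[m]),
                                          self.S_n[m], self.S_t[m]))
        self._ensure_L()
        self._ensure_valid()
        logw_n, logw_t = self._logw_n(), self._logw_t()
        z_n, _ = K.indicator_marginals(self.Lp_n, self.valid_n, logw_n,
                                       self.beta)
        z_t, _ = K.indicator_marginals(self.Lp_t, self._validC_t(), logw_t,
                                       self.beta)
        S_old_n, S_old_t = self.S[m].copy(), self.S[m + self.n_rows].copy()
        R_old = int(self.R_idx[m])
        self.S[m] = s_n_new
        self.S[m + self.n_rows] = s_t_new
        self._L_dirty = True
        self._ensure_L()
        z_n2, _ = K.indicator_marginals(self.Lp_n, self.valid_n, logw_n,
                                        self.beta)
        z_t2, _ = K.indicator_marginals(self.Lp_t, self._validC_t(), logw_t,
                                        self.beta)
        I_n_new, _, _ = K.sample_indicators(self.Lp_n, self.valid_n, logw_n,
                                            self.beta, self.rng)
        I_t_new, _, _ = K.sample_indicators(self.Lp_t, self._validC_t(),
                                            logw_t, self.beta, self.rng)
        I_n_old, I_t_old = self.I_n, self.I_t
        self.I_n, self.I_t = I_n_new, I_t_new
        D_new = self._coverage()
        cov_new = D_new[m] > 0
        S_nN_rev = np.where(cov_new, s_n_new, N_SYM).astype(np.uint8)
        S_tN_rev = np.where(cov_new, s_t_new, N_SYM).astype(np.uint8)
        logq_rev = self._blocked_eval_row(
            m, S_nN_rev, S_tN_rev, R_old, S_old_n, S_old_t)
        dlog = (self.beta * d_prior
                + (z_n2.sum() - z_n.sum()) + (z_t2.sum() - z_t.sum())
                + logq_rev - logq_fwd)
        if dlog >= 0 or self.rng.random() < math.exp(dlog):
            self.R_idx[m] = r_new
            self._refresh_R()
        else:
            self.S[m] = S_old_n
            self.S[m + self.n_rows] = S_old_t
            self.I_n, self.I_t = I_n_old, I_t_old
            self._L_dirty = True

    def blocked_move(self) -> None:
        for m in range(self.n_rows):
            self.blocked_row_move(m)

    # -- heuristics (burn-in only) ----------------------------------------

    def heuristics(self) -> None:
        """Reference copying and decoy reassignment of mismatch-heavy reads."""
        pr = self.ctx.pr
        h = self.ctx.h
        self.S[0:2] = self._R_rows[0:2]
        self.S[self.n_rows:self.n_rows + 2] = self._R_rows[0:2]
        self._L_dirty = True
        # reads must follow the reset sequences, otherwise the next
        # sequence scan immediately restores the pre-copy state
        self.update_indicators()
        if self.n_rows < 3:
            return
        R0, R1 = self._R_rows[0], self._R_rows[1]
        for sr, I, tumor in ((pr.normal, self.I_n, False),
                             (pr.tumor, self.I_t, True)):
            if sr.n_mates == 0:
                continue
            mm = K.mismatch_counts_vs_refs(sr.sym, sr.off, sr.start, R0, R1)
            per_pair = np.zeros(sr.n_pairs, dtype=np.int64)
            np.add.at(per_pair, sr.pair_of_mate, mm)
            heavy = per_pair > h.decoy_reassign_mismatches
            for i in np.flatnonzero(heavy):
                decoy = 2 + int(self.rng.integers(self.n_rows - 2))
                I[i] = decoy + self.n_rows if tumor else decoy

    # -- diagnostics -------------------------------------------------------

    def raw_log_posterior(self) -> float:
        """Untempered log posterior of the current state (all nine factors)."""
        ctx = self.ctx
        h = ctx.h
        self._ensure_L()
        self._ensure_valid()
        total = 0.0
        if ctx.pr.n_normal:
            total += float(self.Lp_n[np.arange(ctx.pr.n_normal),
                                     self.I_n].sum())
        if ctx.pr.n_tumor:
            total += float(self.Lp_t[np.arange(ctx.pr.n_tumor),
                                     self.I_t].sum())
        total += float(ctx.som[self.S_n, self.S_t].sum())
        for m in range(self.n_rows):
            d = 1 if m >= 2 else 0
            total += float(ctx.germ[d, self._R_imp[m].astype(np.intp),
                                    self._R_rows[m], self.S_n[m]].sum())
        total += float(ctx.logp_t[self.R_idx[0]] + ctx.logp_t[self.R_idx[1]])
        total += -(self.n_rows - 2) * math.log(ctx.panel_rows.shape[0])
        lf = np.log(self.F)
        if ctx.pr.n_normal:
            W = self.valid_n @ self.F
            total += float(lf[self.I_n].sum() - np.log(W).sum())
        if ctx.pr.n_tumor:
            W = self.valid_t @ (self.F * (1.0 + self.G))
            lw_t = np.concatenate([lf + math.log(self.G), lf])
            total += float(lw_t[self.I_t].sum() - np.log(W).sum())
        for m in range(self.n_rows):
            mu, sig = ((h.freq_mu_ref, h.freq_sigma_ref) if m < 2
                       else (h.freq_mu_decoy, h.freq_sigma_decoy))
            total += lognormal_logpdf(self.F[m], mu, sig)
        total += lognormal_logpdf(self.G, h.contam_mu, h.contam_sigma)
        for m in range(2, self.n_rows):
            total += self._chain_logp(self.V[m])
        return total

    # -- one full sweep ----------------------------------------------------

    def sweep(self, iteration: int, in_burn_in: bool) -> None:
        cfg = self.cfg
        self.update_sequences()
        self.update_types()
        self.update_indicators()
        if cfg.enable_frequency and not cfg.freeze_scalars:
            self.update_frequency()
            self.update_contamination()
        if cfg.enable_validity:
            for m in range(2, self.n_rows):
                self.update_validity(m)
        if cfg.enable_swap and iteration % cfg.special_move_period == 0:
            if self.n_rows >= 3:
                self.swap_segment()
            self.tumor_swap()
            self.tumor_swap()
            for m in range(2):
                self.somatic_reset(m)
        if cfg.enable_blocked and iteration % cfg.special_move_period == 0:
            self.blocked_move()
        if cfg.enable_heuristics and in_burn_in and cfg.heuristic_period \
                and iteration > 0 and iteration % cfg.heuristic_period == 0:
            self.heuristics()


# ---------------------------------------------------------------------------
# small numeric helpers

def _logsumexp(x: np.ndarray) -> float:
    mx = np.max(x)
    if mx == -np.inf:
        return -np.inf
    return float(mx + np.log(np.exp(x - mx).sum()))


def _categorical(logits: np.ndarray, rng) -> int:
    mx = np.max(logits)
    p = np.exp(logits - mx)
    p /= p.sum()
    return int(rng.choice(len(p), p=p))


def _categorical_rows(logits: np.ndarray, rng):
    """Sample one symbol per row of an ``(N, k)`` logit matrix; returns the
    draws and their summed normalized log-probability."""
    mx = logits.max(axis=1, keepdims=True)
    p = np.exp(logits - mx)
    z = p.sum(axis=1, keepdims=True)
    p = p / z
    u = rng.random((logits.shape[0], 1))
    draws = (p.cumsum(axis=1) < u).sum(axis=1)
    draws = np.minimum(draws, logits.shape[1] - 1)
    lp = np.log(p[np.arange(len(draws)), draws]).sum()
    return draws, float(lp)


def _rows_logprob(logits: np.ndarray, draws: np.ndarray) -> float:
    mx = logits.max(axis=1, keepdims=True)
    p = np.exp(logits - mx)
    p = p / p.sum(axis=1, keepdims=True)
    return float(np.log(p[np.arange(len(draws)), draws]).sum())


def _longest_valid_run(V_row: np.ndarray):
    """Bounds (inclusive) of the longest run of 1s, or None."""
    padded = np.r_[0, V_row.astype(np.int64), 0]
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    if len(starts) == 0:
        return None
    i = int(np.argmax(ends - starts))
    return int(starts[i]), int(ends[i] - 1)


def _sample_valid_interval(V_row: np.ndarray, rng):
    """Uniform draw among all intervals fully inside valid runs of a row."""
    padded = np.r_[0, V_row.astype(np.int64), 0]
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]  # runs are [start, end)
    lengths = ends - starts
    counts = lengths * (lengths + 1) // 2
    total = int(counts.sum())
    if total == 0:
        return None
    t = int(rng.integers(total))
    run = int(np.searchsorted(np.cumsum(counts), t, side="right"))
    t -= int(np.cumsum(counts)[run - 1]) if run > 0 else 0
    L = int(lengths[run])
    a = 0
    while t >= L - a:
        t -= L - a
        a += 1
    b = a + t
    return int(starts[run] + a), int(starts[run] + b)


# ---------------------------------------------------------------------------
# public per-move API (thin wrappers used directly in unit tests)

def _runner_from_state(state, reads, msa, freqs, h, rng,
                       cfg=None) -> _Chain:
    ctx = _Context(reads, msa, freqs, h)
    chain = _Chain(ctx, rng, beta=1.0, cfg=cfg)
    chain.load_state(state)
    return chain


def gibbs_update_indicators(state, reads, msa, freqs, h, rng) -> ModelState:
    c = _runner_from_state(state, reads, msa, freqs, h, rng)
    c.update_indicators()
    return c.export_state()


def gibbs_update_sequences(state, reads, msa, freqs, h, rng) -> ModelState:
    c = _runner_from_state(state, reads, msa, freqs, h, rng)
    c.update_sequences()
    return c.export_state()


def gibbs_update_types(state, reads, msa, freqs, h, rng) -> ModelState:
    c = _runner_from_state(state, reads, msa, freqs, h, rng)
    c.update_types()
    return c.export_state()


def mh_update_frequency(state, reads, msa, freqs, h, rng) -> ModelState:
    c = _runner_from_state(state, reads, msa, freqs, h, rng)
    c.update_frequency()
    return c.export_state()


def wolff_propose_validity(V_row: np.ndarray, h: HyperParameters, rng):
    """Standalone Wolff-style cluster proposal on a binary vector.

    Returns ``(V*, (b, e))`` with 0-based inclusive cluster bounds.
    """
    dummy = _Chain.__new__(_Chain)
    dummy.rng = rng

    class _C:  # minimal context shim
        pass

    _c = _C()
    _c.h = h
    dummy.ctx = _c
    dummy.V = np.asarray(V_row, dtype=np.uint8).reshape(1, -1)
    V_new, b, e, _ = _Chain.wolff_propose(dummy, 0)
    return V_new, (b, e)


def mh_update_validity(state, reads, msa, freqs, h, rng) -> ModelState:
    c = _runner_from_state(state, reads, msa, freqs, h, rng)
    for m in range(2, c.n_rows):
        c.update_validity(m)
    return c.export_state()


def swap_segment_move(state, reads, msa, freqs, h, rng) -> ModelState:
    c = _runner_from_state(state, reads, msa, freqs, h, rng)
    c.swap_segment()
    return c.export_state()


def blocked_type_sequence_move(state, reads, msa, freqs, h, rng) -> ModelState:
    c = _runner_from_state(state, reads, msa, freqs, h, rng)
    c.blocked_move()
    return c.export_state()


def heuristic_moves(state, reads, msa, freqs, h, rng,
                    iteration: int, cfg: ChainConfig = None) -> ModelState:
    cfg = cfg or ChainConfig()
    c = _runner_from_state(state, reads, msa, freqs, h, rng, cfg)
    if cfg.heuristic_period and iteration > 0 \
            and iteration % cfg.heuristic_period == 0:
        c.heuristics()
    return c.export_state()


# ---------------------------------------------------------------------------
# the full run

def run_mcmc(reads, msa: AlleleMSA, freqs: AlleleFrequencyTable,
             h: HyperParameters, cfg: ChainConfig) -> PosteriorSamples:
    """Multistart + parallel-tempered MCMC; returns cold-chain samples.

    Pilot chains (``cfg.n_starts`` of ``cfg.pilot_sweeps`` sweeps each)
    run at temperature 1 with heuristics enabled; the best final state by
    log posterior seeds every rung of the ladder.  Post-burn-in states of
    the temperature-1 chain are retained every ``cfg.thinning`` sweeps.
    """
    pr = _as_packed(reads)
    if pr.n_normal + pr.n_tumor == 0:
        raise ValueError("empty read set")
    ctx = _Context(pr, msa, freqs, h)
    ladder = list(cfg.temperature_ladder)
    if not cfg.enable_tempering:
        ladder = [1.0]
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_starts + len(ladder) + 1)
    pilot_rngs = [np.random.default_rng(s) for s in children[:cfg.n_starts]]
    chain_rngs = [np.random.default_rng(s)
                  for s in children[cfg.n_starts:cfg.n_starts + len(ladder)]]
    swap_rng = np.random.default_rng(children[-1])

    # Pilot diversity: genotypes are seeded from the alleles most voted
    # for by per-mate best alignments (plus prior draws), and the burn-in
    # heuristics alternate on and off; selection by log posterior then
    # beats any single policy.
    votes = np.zeros(ctx.panel_rows.shape[0], dtype=np.int64)
    for sr in (pr.normal, pr.tumor):
        if sr.n_mates:
            votes += np.bincount(sr.best_allele, minlength=len(votes))
    top = list(np.argsort(-votes)[:4])
    seed_pairs = [(top[0], top[0]), (top[0], top[1]),
                  (top[0], top[2]) if len(top) > 2 else (top[0], top[1]),
                  (top[1], top[1]),
                  (top[1], top[2]) if len(top) > 2 else (top[0], top[0]),
                  None, None, None]
    best_state, best_lp = None, -np.inf
    for pi, rng in enumerate(pilot_rngs):
        pcfg = ChainConfig(**{**cfg.__dict__,
                              "enable_heuristics":
                              cfg.enable_heuristics and pi % 2 == 0})
        pilot = _Chain(ctx, rng, beta=1.0, cfg=pcfg)
        pilot.init_state(seed_pairs[pi % len(seed_pairs)])
        for it in range(cfg.pilot_sweeps):
            pilot.sweep(it, in_burn_in=True)
        lp = pilot.raw_log_posterior()
        if lp > best_lp:
            best_lp, best_state = lp, pilot.export_state()

    chains = [_Chain(ctx, rng, beta=1.0 / t, cfg=cfg)
              for t, rng in zip(ladder, chain_rngs)]
    for chain in chains:
        chain.load_state(best_state)
    cold = len(ladder) - 1  # ladder sorted descending; last rung is T=1

    n_keep = (cfg.n_iterations - cfg.burn_in + cfg.thinning - 1) \
        // cfg.thinning
    n_rows, ncol = ctx.n_rows, ctx.ncol
    out = PosteriorSamples(
        allele_names=list(msa.allele_names), n_decoys=h.n_decoys,
        n_columns=ncol,
        sweeps=np.zeros(n_keep, dtype=np.int64),
        R_idx=np.zeros((n_keep, n_rows), dtype=np.int64),
        S_n=np.zeros((n_keep, n_rows, ncol), dtype=np.uint8),
        S_t=np.zeros((n_keep, n_rows, ncol), dtype=np.uint8),
        V=np.zeros((n_keep, n_rows, ncol), dtype=np.uint8),
        F=np.zeros((n_keep, n_rows)),
        G=np.zeros(n_keep),
        logpost_trace=np.zeros(cfg.n_iterations),
    )
    kept = 0
    for it in range(cfg.n_iterations):
        in_burn = it < cfg.burn_in
        for chain in chains:
            # heuristics live in the pilots only; the ladder chains run
            # pure MCMC so every retained state is a posterior draw
            chain.sweep(it, in_burn_in=False)
        if len(chains) > 1:
            j = it % (len(chains) - 1)
            ca, cb = chains[j], chains[j + 1]
            ea, eb = ca.raw_log_posterior(), cb.raw_log_posterior()
            dlog = (ca.beta - cb.beta) * (eb - ea)
            if dlog >= 0 or swap_rng.random() < math.exp(dlog):
                chains[j], chains[j + 1] = cb, ca
                ca.beta, cb.beta = cb.beta, ca.beta
        cc = chains[cold]
        out.logpost_trace[it] = cc.raw_log_posterior()
        if not in_burn and (it - cfg.burn_in) % cfg.thinning == 0:
            out.sweeps[kept] = it
            out.R_idx[kept] = cc.R_idx
            out.S_n[kept] = cc.S_n
            out.S_t[kept] = cc.S_t
            out.V[kept] = cc.V
            out.F[kept] = cc.F
            out.G[kept] = cc.G
            kept += 1
    assert kept == n_keep
    return out
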