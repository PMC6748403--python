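"""Posterior factors: emissions, priors, and the assembled log posterior."""

import itertools
import math

import numpy as np
import pytest

import oracles
from conftest import tiny_locus
from hlabayesnt.config import HyperParameters, lognormal_logpdf
from hlabayesnt.model import (
    ModelState,
    build_germline_tables,
    build_somatic_table,
    emission_logprob,
    germline_prior_logp,
    indicator_prior_logp,
    log_posterior,
    read_set_loglik,
    scalar_priors_logp,
    somatic_prior_logp,
    type_prior_logp,
)

H = HyperParameters(n_decoys=0)
SYMS = "ACGTN-"


class TestEmission:
    @pytest.mark.parametrize("seq_sym", list(SYMS))
    @pytest.mark.parametrize("q", [0.0, 0.01, 0.3])
    def test_distribution_normalizes(self, seq_sym, q):
        total = sum(math.exp(emission_logprob(x, seq_sym, q, H))
                    for x in SYMS)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_match_and_mismatch_values(self):
        h = HyperParameters(err_del=1e-4, err_ins=1e-4, err_n=1e-4)
        assert emission_logprob("A", "A", 0.01, h) == pytest.approx(
            math.log((1 - 2e-4) * 0.99))
        assert emission_logprob("C", "A", 0.03, h) == pytest.approx(
            math.log((1 - 2e-4) * 0.01))

    def test_matches_independent_oracle_everywhere(self):
        for s in range(6):
            for x in range(6):
                for q in (0.001, 0.2):
                    got = math.exp(emission_logprob(x, s, q, H))
                    assert got == pytest.approx(
                        oracles.emission_prob(x, s, q, H), rel=1e-12)


class TestEventPriors:
    def test_somatic_identity_closed_form(self):
        h = HyperParameters(n_decoys=0)
        table = build_somatic_table(h)
        stay = math.log(1 - h.som_sub - h.som_del - h.som_n)
        n = 100
        s = np.zeros(n, dtype=np.uint8)
        state = _state(h, S_n=[s, s], S_t=[s.copy(), s.copy()])
        assert somatic_prior_logp(state, h) == pytest.approx(2 * n * stay)
        # one substituted position shifts by log(pi_ss/3) - stay
        state.S_t[0, 3] = 1
        assert somatic_prior_logp(state, h) == pytest.approx(
            2 * n * stay + math.log(h.som_sub / 3) - stay)
        assert table[0, 1] == pytest.approx(math.log(h.som_sub / 3))

    @pytest.mark.parametrize("src", range(6))
    def test_somatic_and_germline_normalize(self, src):
        st = build_somatic_table(H)
        assert np.exp(st[src]).sum() == pytest.approx(1.0, abs=1e-12)
        gt = build_germline_tables(H)
        for d in range(2):
            for i in range(2):
                assert np.exp(gt[d, i, src]).sum() == pytest.approx(
                    1.0, abs=1e-12)

    def test_imputed_and_decoy_orderings(self):
        gt = build_germline_tables(H)
        # deviating from an imputed reference base is never less likely
        assert gt[0, 1, 0, 1] >= gt[0, 0, 0, 1]
        # and a decoy haplotype deviates at least as freely
        assert gt[1, 0, 0, 1] >= gt[0, 0, 0, 1]

    def test_germline_tables_match_oracle(self):
        gt = build_germline_tables(H)
        for d in range(2):
            for i in range(2):
                for r in range(6):
                    for s in range(6):
                        assert math.exp(gt[d, i, r, s]) == pytest.approx(
                            oracles.germline_prob(r, s, d, i, H), rel=1e-12)


def _state(h, S_n, S_t, R_idx=None, F=None, G=0.3, V=None, I_n=(), I_t=()):
    S_n = np.asarray(S_n, dtype=np.uint8)
    n_rows, ncol = S_n.shape
    return ModelState(
        R_idx=R_idx if R_idx is not None else np.zeros(n_rows, int),
        S_n=S_n, S_t=np.asarray(S_t, dtype=np.uint8),
        F=F if F is not None else np.ones(n_rows), G=G,
        V=V if V is not None else np.ones((n_rows, ncol), np.uint8),
        I_n=np.asarray(I_n, int), I_t=np.asarray(I_t, int))


class TestTypeAndIndicatorPriors:
    def _fixture(self):
        return tiny_locus(
            panel_rows=[(0, 1, 2), (3, 1, 0)], imputed=[(0,) * 3, (0,) * 3],
            p_t=(0.7, 0.3),
            normal_reads=[(0, (0, 1), 0.05)],
            tumor_reads=[(0, (0, 1, 2), 0.05)])

    def test_type_prior_symmetry_and_values(self):
        msa, freqs, _, _ = self._fixture()
        s = np.zeros((2, 3), dtype=np.uint8)
        a = _state(H, s, s, R_idx=np.array([0, 1]))
        b = _state(H, s, s, R_idx=np.array([1, 0]))
        assert type_prior_logp(a, freqs, msa) == pytest.approx(
            type_prior_logp(b, freqs, msa))
        both_top = _state(H, s, s, R_idx=np.array([0, 0]))
        assert type_prior_logp(both_top, freqs, msa) == pytest.approx(
            2 * math.log(0.7))

    def test_decoy_term_is_uniform(self):
        msa, freqs, _, _ = self._fixture()
        h = HyperParameters(n_decoys=1)
        s = np.zeros((3, 3), dtype=np.uint8)
        a = _state(h, s, s, R_idx=np.array([0, 1, 0]))
        b = _state(h, s, s, R_idx=np.array([0, 1, 1]))
        assert type_prior_logp(a, freqs, msa) == pytest.approx(
            type_prior_logp(b, freqs, msa))

    def test_indicator_prior_symmetric_and_contaminated(self):
        _, _, _, pr = self._fixture()
        s = np.zeros((2, 3), dtype=np.uint8)
        st = _state(H, s, s, G=0.25, I_n=[0], I_t=[0])
        # normal read: two equal candidates -> log(1/2); tumor read with
        # normal-origin pick: weights (FG, FG, F, F) -> 0.25/2.5
        expected = math.log(0.5) + math.log(0.25 / 2.5)
        assert indicator_prior_logp(st, pr, H) == pytest.approx(expected)
        st_t = _state(H, s, s, G=0.25, I_n=[0], I_t=[2])
        expected_t = math.log(0.5) + math.log(1.0 / 2.5)
        assert indicator_prior_logp(st_t, pr, H) == pytest.approx(expected_t)

    def test_masked_candidate_is_unreachable(self):
        _, _, _, pr = self._fixture()
        h = HyperParameters(n_decoys=1)
        s = np.zeros((3, 3), dtype=np.uint8)
        V = np.ones((3, 3), np.uint8)
        V[2] = 0  # decoy invalid everywhere
        st = _state(h, s, s, V=V, I_n=[2], I_t=[0])
        with pytest.raises(ValueError):
            indicator_prior_logp(st, pr, h)


class TestScalarPriors:
    def test_contamination_at_prior_median(self):
        s = np.zeros((2, 4), dtype=np.uint8)
        st = _state(H, s, s, G=math.exp(H.contam_mu))
        base = scalar_priors_logp(st, H)
        f_terms = 2 * lognormal_logpdf(1.0, H.freq_mu_ref, H.freq_sigma_ref)
        g_term = -math.log(H.contam_sigma * math.sqrt(2 * math.pi)) \
            - H.contam_mu
        assert base == pytest.approx(f_terms + g_term)

    def test_decoy_validity_chain_closed_forms(self):
        h = HyperParameters(n_decoys=1)
        n = 30
        s = np.zeros((3, n), dtype=np.uint8)
        V = np.ones((3, n), np.uint8)
        V[2] = 0
        all_zero = scalar_priors_logp(_state(h, s, s, V=V), h)
        V2 = np.ones((3, n), np.uint8)
        all_one = scalar_priors_logp(_state(h, s, s, V=V2), h)
        # closed forms of the two extreme rows
        expected_zero = n * math.log(1 - h.valid_open)
        expected_one = math.log(h.valid_open) + (n - 1) * math.log(h.valid_ext)
        assert all_zero - all_one == pytest.approx(
            expected_zero - expected_one)
        assert math.exp(all_zero - all_one) == pytest.approx(
            oracles.v_chain_prob([0] * n, h) / oracles.v_chain_prob([1] * n, h))

    def test_nondecoy_validity_must_be_one(self):
        s = np.zeros((2, 4), dtype=np.uint8)
        V = np.ones((2, 4), np.uint8)
        V[1, 2] = 0
        with pytest.raises(ValueError):
            _state(H, s, s, V=V)


class TestReadLikelihood:
    def test_zero_reads_is_zero(self):
        msa, freqs, rs, pr = tiny_locus(
            panel_rows=[(0, 1), (2, 3)], imputed=[(0, 0), (0, 0)],
            p_t=(0.5, 0.5), normal_reads=[], tumor_reads=[])
        s = np.zeros((2, 2), dtype=np.uint8)
        st = _state(H, s, s)
        assert read_set_loglik(pr, st, H) == 0.0

    def test_perfect_match_limit(self):
        h = HyperParameters(err_del=1e-12, err_ins=1e-12, err_n=1e-12)
        msa, freqs, rs, pr = tiny_locus(
            panel_rows=[(0, 1, 2), (3, 3, 3)], imputed=[(0,) * 3, (0,) * 3],
            p_t=(0.5, 0.5), normal_reads=[(0, (0, 1, 2), 1e-12)],
            tumor_reads=[])
        st = _state(h, [(0, 1, 2), (3, 3, 3)], [(0, 1, 2), (3, 3, 3)],
                    I_n=[0])
        assert read_set_loglik(pr, st, h) == pytest.approx(0.0, abs=1e-8)

    def test_matches_bruteforce_summation(self):
        msa, freqs, rs, pr = tiny_locus(
            panel_rows=[(0, 1, 2, 3), (3, 2, 1, 0)],
            imputed=[(0,) * 4, (0,) * 4], p_t=(0.5, 0.5),
            normal_reads=[(0, (0, 1), 0.05), (1, (2, 5, 0), 0.1)],
            tumor_reads=[(2, (1, 3), 0.02)])
        S_n = np.array([(0, 1, 2, 3), (3, 2, 1, 0)], dtype=np.uint8)
        S_t = np.array([(0, 1, 5, 3), (3, 2, 1, 0)], dtype=np.uint8)
        st = _state(H, S_n, S_t, I_n=[0, 1], I_t=[2])
        expected = 0.0
        for (s0, sym, q), row in ((
                (0, (0, 1), 0.05), S_n[0]), ((1, (2, 5, 0), 0.1), S_n[1]),
                ((2, (1, 3), 0.02), S_t[0])):
            for j, x in enumerate(sym):
                expected += math.log(
                    oracles.emission_prob(x, int(row[s0 + j]), q, H))
        assert read_set_loglik(pr, st, H) == pytest.approx(expected)


class TestLogPosterior:
    def test_is_sum_of_factors(self, enum_fixture):
        msa, freqs, rs, pr, h = enum_fixture
        S = msa.rows[:2].copy()
        st = _state(h, S, S.copy(), R_idx=np.array([0, 1]),
                    I_n=[0, 1, 0], I_t=[0, 1, 2])
        total = log_posterior(st, pr, msa, freqs, h)
        parts = (read_set_loglik(pr, st, h) + somatic_prior_logp(st, h)
                 + germline_prior_logp(st, msa, h)
                 + type_prior_logp(st, freqs, msa)
                 + indicator_prior_logp(st, pr, h)
                 + scalar_priors_logp(st, h))
        assert total == pytest.approx(parts)

    def test_label_switching_symmetry(self, enum_fixture):
        msa, freqs, rs, pr, h = enum_fixture
        S_n = np.array([msa.rows[0], msa.rows[1]])
        S_t = S_n.copy()
        S_t[0, 2] = 3
        a = _state(h, S_n, S_t, R_idx=np.array([0, 1]),
                   I_n=[0, 1, 0], I_t=[0, 3, 2])
        b = _state(h, S_n[::-1].copy(), S_t[::-1].copy(),
                   R_idx=np.array([1, 0]),
                   I_n=[1, 0, 1], I_t=[1, 2, 3])
        assert log_posterior(a, pr, msa, freqs, h) == pytest.approx(
            log_posterior(b, pr, msa, freqs, h))

    def test_worse_data_fit_lowers_posterior(self, enum_fixture):
        msa, freqs, rs, pr, h = enum_fixture
        S = msa.rows[:2].copy()
        st = _state(h, S, S.copy(), R_idx=np.array([0, 1]),
                    I_n=[0, 1, 0], I_t=[0, 1, 2])
        base = log_posterior(st, pr, msa, freqs, h)
        st.S_n[0, 0] = 3  # read n0 starts with A; make the haplotype T
        assert log_posterior(st, pr, msa, freqs, h) < base

    def test_full_grid_normalization_matches_enumeration_oracle(self):
        """Summing exp(log_posterior) over every state reproduces the
        independently enumerated genotype posterior."""
        h = HyperParameters(n_decoys=0, err_del=0.02, err_ins=0.02,
                            err_n=0.01, som_sub=0.03, som_del=0.02,
                            som_ins=0.02, som_n=0.01)
        msa, freqs, rs, pr = tiny_locus(
            panel_rows=[(0,), (3,)], imputed=[(0,), (1,)],
            p_t=(0.7, 0.3), normal_reads=[(0, (0,), 0.05)],
            tumor_reads=[(0, (3,), 0.05)])
        per_pair = {}
        total = 0.0
        F = np.ones(2)
        for R in itertools.product(range(2), repeat=2):
            for sn in itertools.product(range(6), repeat=2):
                S_n = np.array(sn, dtype=np.uint8).reshape(2, 1)
                for stt in itertools.product(range(6), repeat=2):
                    S_t = np.array(stt, dtype=np.uint8).reshape(2, 1)
                    for i_n in range(2):
                        for i_t in range(4):
                            st = _state(h, S_n, S_t,
                                        R_idx=np.array(R), F=F, G=0.3,
                                        I_n=[i_n], I_t=[i_t])
                            w = math.exp(log_posterior(st, pr, msa, freqs, h)
                                         - scalar_priors_logp(st, h))
                            total += w
                            key = tuple(sorted(R))
                            per_pair[key] = per_pair.get(key, 0.0) + w
        oracle = oracles.enumerate_posterior(
            [(0,), (3,)], [(0,), (1,)], np.array([0.7, 0.3]),
            [oracles.TinyRead(0, (0,), 0.05)],
            [oracles.TinyRead(0, (3,), 0.05)], h, F, 0.3, n_decoys=0)
        for key, p in oracle["genotype"].items():
            assert per_pair[key] / total == pytest.approx(p, abs=1e-9)


def test_hyperparameters_yaml_roundtrip(tmp_path):
    h = HyperParameters(n_decoys=3, som_sub=5e-4, valid_open=0.02)
    h.germline[0, 0, 0] = 2e-3
    h.validate()
    path = tmp_path / "config.yaml"
    h.to_yaml(path)
    back = HyperParameters.from_yaml(path)
    assert back.n_decoys == 3
    assert back.som_sub == pytest.approx(5e-4)
    assert back.valid_open == pytest.approx(0.02)
    np.testing.assert_allclose(back.germline, h.germline)
    with pytest.raises(ValueError, match="unknown"):
        HyperParameters.from_dict({"not_a_field": 1})


def test_hyperparameter_ordering_constraints_enforced():
    g = _default_valid_germline()
    g[0, 1] = 5e-4  # imputed below original
    with pytest.raises(ValueError, match="imputed"):
        HyperParameters(germline=g)
    with pytest.raises(ValueError, match="freq_mu_decoy"):
        HyperParameters(freq_mu_decoy=0.5)


def _default_valid_germline():
    g = np.empty((2, 2, 4))
    g[0, 0], g[0, 1], g[1, 0], g[1, 1] = 1e-3, 1e-2, 1e-2, 1e-1
    return g


def test_state_snapshot_tsv(tmp_path):
    s = np.zeros((2, 4), dtype=np.uint8)
    st = _state(H, s, s, I_n=[0], I_t=[1])
    path = tmp_path / "state.tsv"
    st.to_tsv(path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("#G\t")
    assert lines[3] == "row\tR_idx\tF\tS_n\tS_t\tV"
    assert lines[4].split("\t")[3] == "AAAA"
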