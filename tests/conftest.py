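"""Shared fixtures: tiny enumerable locus setups and a small synthetic run."""

import numpy as np
import pytest

from hlabayesnt.config import HyperParameters
from hlabayesnt.model import PackedReads
from hlabayesnt.read_pipeline import LocusReadSet, RealignedRead
from hlabayesnt.reference_panel import AlleleFrequencyTable, AlleleMSA


def make_realigned(start0, symbols, q, sample="normal", read_id="r",
                   mate_index=0, best_allele=0):
    """Build a single-mate realigned read from 0-based start and codes."""
    symbols = np.asarray(symbols, dtype=np.uint8)
    probs = np.full(len(symbols), float(q))
    probs[symbols == 5] = np.nan
    return RealignedRead(id=read_id, mate_index=mate_index, sample=sample,
                         start=start0 + 1, symbols=symbols,
                         mismatch_probs=probs, best_allele=best_allele)


def tiny_locus(panel_rows, imputed, p_t, normal_reads, tumor_reads,
               locus="A"):
    """Package a hand-built panel plus TinyRead-style reads.

    ``normal_reads`` / ``tumor_reads`` are (start0, symbols, q) tuples,
    one single-mate pair each.
    """
    rows = np.asarray(panel_rows, dtype=np.uint8)
    names = [f"{locus}*01:{i + 1:02d}" for i in range(rows.shape[0])]
    msa = AlleleMSA(locus=locus, allele_names=names, rows=rows,
                    imputed_mask=np.asarray(imputed, dtype=bool))
    freqs = AlleleFrequencyTable(
        entries={n: float(p) for n, p in zip(names, p_t)})
    rs = LocusReadSet(
        locus=locus, n_columns=rows.shape[1],
        normal_pairs=[[make_realigned(s, sym, q, "normal", f"n{i}")]
                      for i, (s, sym, q) in enumerate(normal_reads)],
        tumor_pairs=[[make_realigned(s, sym, q, "tumor", f"t{i}")]
                     for i, (s, sym, q) in enumerate(tumor_reads)])
    return msa, freqs, rs, PackedReads(rs)


@pytest.fixture(scope="session")
def hyper_small():
    """Hyperparameters with deviation rates large enough to enumerate
    comfortably on toy fixtures."""
    h = HyperParameters(n_decoys=0, err_del=0.02, err_ins=0.02, err_n=0.01,
                        som_sub=0.03, som_del=0.02, som_ins=0.02, som_n=0.01)
    h.germline[:] = [[[0.04, 0.02, 0.02, 0.01], [0.08, 0.04, 0.04, 0.02]],
                     [[0.08, 0.04, 0.04, 0.02], [0.16, 0.08, 0.08, 0.04]]]
    return h


@pytest.fixture(scope="session")
def enum_fixture(hyper_small):
    """3 alleles x 4 columns, 3 normal + 3 tumor single-mate pairs."""
    msa, freqs, rs, pr = tiny_locus(
        panel_rows=[(0, 1, 2, 3), (0, 1, 0, 3), (3, 1, 2, 0)],
        imputed=[(0, 0, 0, 0), (0, 0, 1, 0), (0, 0, 0, 0)],
        p_t=(0.5, 0.3, 0.2),
        normal_reads=[(0, (0, 1, 2), 0.05), (1, (1, 0, 3), 0.05),
                      (0, (0, 1, 0, 3), 0.08)],
        tumor_reads=[(0, (3, 1, 2), 0.05), (1, (1, 5, 3), 0.08),
                     (2, (2, 3), 0.05)])
    return msa, freqs, rs, pr, hyper_small
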