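"""Reference panel handling: allele MSAs, imputation, and frequency priors.

An HLA locus is represented by a multiple sequence alignment (MSA) of its
known allele sequences.  Public databases leave large stretches of many
alleles unsequenced; before genotyping, those unknown cells are filled in
from the Hamming-nearest fully-informative allele, and the filled cells are
flagged so that the model can treat them as less trustworthy than
originally sequenced bases.  Allele population frequencies serve as the
genotype prior.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace

import numpy as np

from hlabayesnt.alphabet import GAP, N, N_BASES, decode, encode

__all__ = [
    "AlleleMSA",
    "AlleleFrequencyTable",
    "parse_msa",
    "impute_incomplete_alleles",
    "load_frequencies",
    "read_frequency_tsv",
    "synthesize_panel",
    "write_panel_fasta",
]

#: Total prior mass shared by panel alleles absent from the frequency table,
#: before renormalization.  Keeps rare, unobserved alleles reachable.
DEFAULT_MASS = 1e-4


@dataclass
class AlleleMSA:
    """Per-locus multiple sequence alignment of allele sequences.

    ``rows`` holds integer-coded symbols over ``ACGTN-`` with shape
    ``(n_alleles, n_columns)``.  ``unknown_mask`` marks cells whose base was
    never sequenced (stored as ``N`` pending imputation); ``imputed_mask``
    marks cells that have been filled by imputation.  ``feature_map`` labels
    each column with its gene feature (e.g. ``exon2``).
    """

    locus: str
    allele_names: list
    rows: np.ndarray
    imputed_mask: np.ndarray
    unknown_mask: np.ndarray = None
    feature_map: np.ndarray = None

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.uint8)
        K, ncol = self.rows.shape
        if len(self.allele_names) != K:
            raise ValueError("allele_names length does not match rows")
        if len(set(self.allele_names)) != K:
            raise ValueError(f"duplicate allele name in locus {self.locus}")
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        if self.imputed_mask.shape != self.rows.shape:
            raise ValueError("imputed_mask shape mismatch")
        if self.unknown_mask is None:
            self.unknown_mask = np.zeros_like(self.imputed_mask)
        self.unknown_mask = np.asarray(self.unknown_mask, dtype=bool)
        if self.unknown_mask.shape != self.rows.shape:
            raise ValueError("unknown_mask shape mismatch")
        if self.feature_map is None:
            self.feature_map = np.array(["exon"] * ncol, dtype=object)
        if len(self.feature_map) != ncol:
            raise ValueError("feature_map length mismatch")

    @property
    def n_alleles(self) -> int:
        return self.rows.shape[0]

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    def sequence(self, name_or_index) -> str:
        """Aligned (gapped) sequence of one allele as a string."""
        idx = (name_or_index if isinstance(name_or_index, (int, np.integer))
               else self.allele_names.index(name_or_index))
        return decode(self.rows[idx])

    def ungapped_sequence(self, name_or_index) -> str:
        return self.sequence(name_or_index).replace("-", "")


@dataclass
class AlleleFrequencyTable:
    """Prior probabilities of panel alleles, normalized to sum to one."""

    entries: dict
    default_mass: float = DEFAULT_MASS

    def __post_init__(self):
        vals = np.array(list(self.entries.values()), dtype=float)
        if (vals <= 0).any():
            raise ValueError("allele prior probabilities must be positive")
        total = vals.sum()
        self.entries = {k: float(v) / total for k, v in self.entries.items()}

    def probability(self, name: str) -> float:
        return self.entries[name]

    def log_probs(self, allele_names) -> np.ndarray:
        return np.log([self.entries[a] for a in allele_names])


# ---------------------------------------------------------------------------
# parsing

_NAME_RE = re.compile(r"^[A-Za-z0-9_.:*-]+$")


def parse_msa(text: str, style: str = "imgt") -> AlleleMSA:
    """Parse a per-locus alignment text into an :class:`AlleleMSA`.

    Two conventions are supported.  ``style="imgt"`` follows the database
    alignment-file convention: the first allele line carries the full
    sequence, subsequent alleles use ``-`` for identity with the first
    allele, ``.`` for an alignment gap, a letter for a substitution, and
    ``*`` for an unsequenced (unknown) stretch.  ``style="plain"`` reads
    every row literally, with ``-`` as gap and ``*`` as unknown.  Alignment
    blocks may be split over several paragraphs; per-allele chunks are
    concatenated in order of appearance.

    Unknown cells are stored as ``N`` and flagged in ``unknown_mask`` for
    later imputation.
    """
    if style not in ("imgt", "plain"):
        raise ValueError(f"unknown style {style!r}")
    chunks: dict = {}
    order: list = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        name = parts[0]
        if "*" not in name or not _NAME_RE.match(name):
            continue  # header / ruler line
        seq = "".join(parts[1:])
        if not seq:
            continue
        if name not in chunks:
            chunks[name] = []
            order.append(name)
        chunks[name].append(seq)
    if not order:
        raise ValueError("empty panel: no allele rows found")
    seqs = {n: "".join(chunks[n]) for n in order}
    seen = set()
    for n in order:
        if n in seen:
            raise ValueError(f"duplicate allele name {n}")
        seen.add(n)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
    loci = {n.split("*")[0] for n in order}
    if len(loci) != 1:
        raise ValueError(f"alignment mixes loci: {sorted(loci)}")
    locus = loci.pop()

    ncol = lengths.pop()
    K = len(order)
    rows = np.empty((K, ncol), dtype=np.uint8)
    unknown = np.zeros((K, ncol), dtype=bool)
    ref = None
    for i, name in enumerate(order):
        s = seqs[name]
        unk = np.frombuffer(s.encode(), dtype=np.uint8) == ord("*")
        body = s.replace("*", "N")
        row = encode(body)
        if style == "imgt":
            if i == 0:
                if unk.any():
                    raise ValueError(
                        "first allele of an IMGT-style alignment must be "
                        "fully sequenced")
                ref = row.copy()
            else:
                ident = np.frombuffer(body.encode(), dtype=np.uint8) == ord("-")
                row = np.where(ident, ref, row)
        unknown[i] = unk
        row = np.where(unk, np.uint8(N), row)
        rows[i] = row
    return AlleleMSA(locus=locus, allele_names=order, rows=rows,
                     imputed_mask=np.zeros((K, ncol), dtype=bool),
                     unknown_mask=unknown)


# ---------------------------------------------------------------------------
# imputation

def _normalized_hamming(a, b, known_a, known_b):
    both = known_a & known_b
    n = int(both.sum())
    if n == 0:
        return np.inf, 0
    return float((a[both] != b[both]).sum()) / n, n


def impute_incomplete_alleles(msa: AlleleMSA) -> AlleleMSA:
    """Fill unknown cells of each incomplete allele from its nearest donor.

    The donor is the allele minimizing normalized Hamming distance over
    columns known in *both* alleles; ties break by ascending allele name.
    Donors are consulted in distance order until every unknown cell of the
    target is filled, so a partially known donor can serve where it is
    informative.  Known cells are never modified; imputation is idempotent.
    """
    if not msa.unknown_mask.any():
        return replace(
            msa,
            rows=msa.rows.copy(),
            imputed_mask=msa.imputed_mask.copy(),
            unknown_mask=msa.unknown_mask.copy(),
        )
    K = msa.n_alleles
    known = ~msa.unknown_mask
    rows = msa.rows.copy()
    imputed = msa.imputed_mask.copy()
    unknown = msa.unknown_mask.copy()
    for i in range(K):
        if not unknown[i].any():
            continue
        if not known[i].any():
            raise ValueError(
                f"allele {msa.allele_names[i]} has no known column; "
                "Hamming distance is undefined")
        dists = []
        for j in range(K):
            if j == i:
                continue
            d, n = _normalized_hamming(msa.rows[i], msa.rows[j],
                                       known[i], known[j])
            if n > 0:
                dists.append((d, msa.allele_names[j], j))
        dists.sort()
        todo = unknown[i].copy()
        for _, _, j in dists:
            usable = todo & known[j]
            if usable.any():
                rows[i, usable] = msa.rows[j, usable]
                imputed[i, usable] = True
                todo &= ~usable
            if not todo.any():
                break
        if todo.any():
            raise ValueError(
                f"allele {msa.allele_names[i]}: no donor known at "
                f"{int(todo.sum())} column(s)")
        unknown[i] = False
    return replace(msa, rows=rows, imputed_mask=imputed, unknown_mask=unknown)


# ---------------------------------------------------------------------------
# frequencies

def load_frequencies(table: dict, msa: AlleleMSA,
                     default_mass: float = DEFAULT_MASS) -> AlleleFrequencyTable:
    """Build the normalized allele prior for a panel.

    ``table`` maps allele names to counts or frequencies (any positive
    scale).  Panel alleles absent from the table share ``default_mass``
    equally before renormalization; an empty table yields a uniform prior.
    """
    for name, v in table.items():
        if v < 0:
            raise ValueError(f"negative frequency for {name}")
    present = {a: float(table[a]) for a in msa.allele_names
               if a in table and table[a] > 0}
    missing = [a for a in msa.allele_names if a not in present]
    entries = dict(present)
    if missing:
        if present:
            total = sum(present.values())
            share = default_mass * total / len(missing)
        else:
            share = 1.0 / len(missing)
        for a in missing:
            entries[a] = share
    return AlleleFrequencyTable(entries=entries, default_mass=default_mass)


def read_frequency_tsv(path) -> dict:
    """Read a two-column ``allele<TAB>frequency`` table."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("allele"):
                continue
            name, freq = line.split("\t")[:2]
            out[name] = float(freq)
    return out


def write_frequency_tsv(freqs: AlleleFrequencyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("allele\tfrequency\n")
        for name, p in freqs.entries.items():
            fh.write(f"{name}\t{p:.10g}\n")


# ---------------------------------------------------------------------------
# synthesis

def synthesize_panel(n_alleles: int, msa_length: int, divergence: float,
                     n_paralogs: int, seed: int,
                     paralog_divergence: float = None,
                     gap_columns: int = 0, locus: str = "A"):
    """Generate a toy panel: an allele MSA, frequencies, and a paralog MSA.

    Alleles derive from a common random ancestor by substituting each
    column independently with probability ``divergence``.  The paralog MSA
    stands in for pseudogene paralogs that contaminate read filtering: it
    diverges from the same ancestor at ``paralog_divergence`` (default
    ``min(10 * divergence, 0.5)``), so paralog reads resemble — but do not
    match — panel alleles.  ``gap_columns`` columns are deleted in a random
    half of the alleles to exercise indel handling.  Frequencies follow a
    geometric profile so that some alleles are common and some rare.
    Deterministic for a fixed seed.
    """
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    if paralog_divergence is None:
        paralog_divergence = min(10.0 * divergence, 0.5)
    if not 0.0 <= paralog_divergence <= 1.0:
        raise ValueError("paralog_divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, N_BASES, size=msa_length).astype(np.uint8)

    def _mutate(base_row, rate):
        row = base_row.copy()
        hit = rng.random(msa_length) < rate
        shift = rng.integers(1, N_BASES, size=msa_length).astype(np.uint8)
        row[hit] = (row[hit] + shift[hit]) % N_BASES
        return row

    rows = np.stack([_mutate(ancestor, divergence) for _ in range(n_alleles)])
    if gap_columns:
        cols = rng.choice(msa_length, size=gap_columns, replace=False)
        which = rng.random(n_alleles) < 0.5
        if not which.any():
            which[0] = True
        for c in cols:
            rows[which, c] = GAP
    names = [f"{locus}*{i // 100 + 1:02d}:{i % 100 + 1:02d}"
             for i in range(n_alleles)]
    msa = AlleleMSA(locus=locus, allele_names=names, rows=rows,
                    imputed_mask=np.zeros_like(rows, dtype=bool),
                    feature_map=_default_features(msa_length))
    weights = 0.6 ** np.arange(n_alleles)
    freqs = AlleleFrequencyTable(
        entries={n: float(w) for n, w in zip(names, weights)})

    prows = np.stack([_mutate(ancestor, paralog_divergence)
                      for _ in range(max(n_paralogs, 1))])[:n_paralogs]
    pnames = [f"{locus}P*{i + 1:02d}:01" for i in range(n_paralogs)]
    paralog = None
    if n_paralogs > 0:
        paralog = AlleleMSA(locus=f"{locus}P", allele_names=pnames, rows=prows,
                            imputed_mask=np.zeros_like(prows, dtype=bool),
                            feature_map=_default_features(msa_length))
    return msa, freqs, paralog


def _default_features(ncol: int) -> np.ndarray:
    """Label the central half of the columns exonic, flanks intronic."""
    fm = np.array(["intron1"] * ncol, dtype=object)
    lo, hi = ncol // 4, ncol - ncol // 4
    fm[lo:hi] = "exon2"
    fm[hi:] = "intron2"
    return fm


# ---------------------------------------------------------------------------
# serialization

def write_panel_fasta(msa: AlleleMSA, fasta_path, intervals_path=None) -> None:
    """Write gap-stripped allele sequences plus a sidecar of imputed spans.

    The sidecar TSV records, per allele, 1-based inclusive MSA column
    intervals that were filled by imputation.
    """
    with open(fasta_path, "w") as fh:
        for i, name in enumerate(msa.allele_names):
            fh.write(f">{name}\n{msa.ungapped_sequence(i)}\n")
    if intervals_path is None:
        return
    with open(intervals_path, "w") as fh:
        fh.write("allele\tstart\tend\n")
        for i, name in enumerate(msa.allele_names):
            mask = msa.imputed_mask[i]
            if not mask.any():
                continue
            edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
            for s, e in zip(edges[::2], edges[1::2]):
                fh.write(f"{name}\t{s + 1}\t{e}\n")
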