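"""Ground-truthed synthetic data: individuals, mutations, and read sets.

The generator mirrors the model's own generative assumptions: a diploid
genotype drawn from panel allele frequencies, germline substitutions on
the two haplotypes, somatic events (substitutions and small indels)
applied at a cellular fraction in the tumor, tumor purity mixing
normal-cell fragments into the tumor sample, Phred-calibrated
substitution errors, and a fraction of contaminating fragments drawn
from a diverged paralog (standing in for pseudogene reads that the
filtering stage must reject).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from hlabayesnt.alphabet import GAP, N_BASES, decode
from hlabayesnt.read_pipeline import Mate, ReadPair
from hlabayesnt.reference_panel import AlleleFrequencyTable, AlleleMSA

__all__ = [
    "TruthSet",
    "simulate_individual",
    "add_somatic_events",
    "simulate_reads",
    "write_fastq",
    "write_truth_json",
    "read_truth_json",
]


@dataclass
class TruthSet:
    """Everything a test needs to score calls against the simulation."""

    genotype: tuple                  # allele names (sorted)
    genotype_idx: tuple              # panel indices
    germline: list                   # (haplotype, column0, ref, alt)
    somatic: list                    # dicts: haplotype, column0, kind, ...
    purity: float
    normal_haplotypes: np.ndarray    # (2, N) codes, germline applied
    tumor_haplotypes: np.ndarray     # (2, N) codes, somatic applied
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "genotype": list(self.genotype),
            "genotype_idx": list(int(i) for i in self.genotype_idx),
            "germline": [list(g) for g in self.germline],
            "somatic": list(self.somatic),
            "purity": self.purity,
            "normal_haplotypes": [decode(r) for r in self.normal_haplotypes],
            "tumor_haplotypes": [decode(r) for r in self.tumor_haplotypes],
            "seed": self.seed,
        }


def simulate_individual(msa: AlleleMSA, freqs: AlleleFrequencyTable,
                        n_germline: int, rng: np.random.Generator,
                        seed: int = 0) -> TruthSet:
    """Draw a diploid genotype from the allele prior and add germline SNVs.

    Germline substitutions are placed uniformly over non-gap columns of
    the two haplotypes (at most one per column per haplotype).
    """
    p = np.array([freqs.probability(a) for a in msa.allele_names])
    p = p / p.sum()
    idx = (int(rng.choice(msa.n_alleles, p=p)),
           int(rng.choice(msa.n_alleles, p=p)))
    haps = np.stack([msa.rows[idx[0]].copy(), msa.rows[idx[1]].copy()])
    germline = []
    for _ in range(n_germline):
        hap = int(rng.integers(2))
        base_cols = np.flatnonzero(haps[hap] < N_BASES)
        col = int(rng.choice(base_cols))
        ref = int(haps[hap, col])
        alt = (ref + 1 + int(rng.integers(N_BASES - 1))) % N_BASES
        haps[hap, col] = alt
        germline.append((hap, col, "ACGT"[ref], "ACGT"[alt]))
    names = tuple(sorted(msa.allele_names[i] for i in idx))
    return TruthSet(genotype=names, genotype_idx=idx, germline=germline,
                    somatic=[], purity=1.0,
                    normal_haplotypes=haps, tumor_haplotypes=haps.copy(),
                    seed=seed)


def add_somatic_events(truth: TruthSet, events: list,
                       rng: np.random.Generator,
                       margin: int = 0, min_separation: int = 10) -> TruthSet:
    """Apply somatic events to the tumor haplotypes.

    Each event is a dict with ``kind`` (``substitution`` | ``deletion``),
    optional ``haplotype``, ``column0`` (0-based MSA column; drawn
    uniformly over eligible columns if absent), ``length`` (deletions),
    and ``cellular_fraction`` (default 1.0, clonal).  Auto-placed events
    keep ``margin`` columns away from the locus ends (so they fall in
    fully covered sequence) and ``min_separation`` columns away from each
    other and from germline variants, so every planted event is
    separately observable.
    """
    tumor = truth.tumor_haplotypes.copy()
    recorded = []
    taken = [g[1] for g in truth.germline] + \
        [ev.get("column0") for ev in truth.somatic if "column0" in ev]
    for ev in events:
        ev = dict(ev)
        hap = ev.setdefault("haplotype", int(rng.integers(2)))
        ev.setdefault("cellular_fraction", 1.0)
        if not 0.0 < ev["cellular_fraction"] <= 1.0:
            raise ValueError("cellular_fraction must be in (0, 1]")
        length = int(ev.get("length", 1))
        base_cols = np.flatnonzero(tumor[hap] < N_BASES)
        if "column0" not in ev:
            ncol = tumor.shape[1]
            ok = base_cols[(base_cols >= margin)
                           & (base_cols < ncol - margin - length)]
            if len(taken):
                far = np.abs(ok[:, None] - np.array(taken)[None, :])
                ok = ok[(far >= min_separation).all(axis=1)]
            if len(ok) == 0:
                raise ValueError("no eligible column for somatic event")
            ev["column0"] = int(rng.choice(ok))
        taken.append(ev["column0"])
        col = int(ev["column0"])
        if ev["kind"] == "substitution":
            ref = int(tumor[hap, col])
            alt = (ref + 1 + int(rng.integers(N_BASES - 1))) % N_BASES
            tumor[hap, col] = alt
            ev["ref"], ev["alt"] = "ACGT"[ref], "ACGT"[alt]
        elif ev["kind"] == "deletion":
            cols = base_cols[np.searchsorted(base_cols, col):][:length]
            ev["ref"] = "".join("ACGT-N"[int(tumor[hap, c])] for c in cols)
            tumor[hap, cols] = GAP
            ev["columns0"] = [int(c) for c in cols]
        else:
            raise ValueError(f"unknown somatic event kind {ev['kind']!r}")
        recorded.append(ev)
    return dataclasses.replace(truth, tumor_haplotypes=tumor,
                               somatic=truth.somatic + recorded)


def _ungapped(hap: np.ndarray) -> str:
    return decode(hap).replace("-", "")


def _fragment_reads(seq: str, read_length: int, insert: int, phred: int,
                    rng: np.random.Generator):
    """One paired-end fragment from a template sequence, with errors."""
    L = len(seq)
    frag = min(insert, L)
    start = int(rng.integers(0, L - frag + 1))
    r1 = seq[start:start + read_length]
    r2_end = start + frag
    r2 = seq[max(r2_end - read_length, start):r2_end]
    err = 10.0 ** (-phred / 10.0)

    def _mutate(s):
        arr = list(s)
        hits = np.flatnonzero(rng.random(len(arr)) < err)
        for i in hits:
            if arr[i] in "ACGT":
                arr[i] = "ACGT"[("ACGT".index(arr[i])
                                 + 1 + int(rng.integers(3))) % 4]
        return "".join(arr)

    return _mutate(r1), _mutate(r2)


def simulate_reads(truth: TruthSet, read_length: int = 80,
                   coverage: float = 30.0, phred: int = 30,
                   paralog_fraction: float = 0.0,
                   paralog_msa: AlleleMSA = None,
                   insert: int = 150, sample: str = "normal",
                   rng: np.random.Generator = None,
                   id_prefix: str = "r") -> list:
    """Simulate one sample's paired reads as :class:`ReadPair` objects.

    For the normal sample every fragment derives from a germline
    haplotype.  For the tumor sample a fragment derives from a tumor
    haplotype with probability ``purity`` and from a germline haplotype
    otherwise; subclonal somatic events are re-applied per fragment at
    their cellular fraction.  ``paralog_fraction`` of fragments instead
    derive from a random paralog allele.  Base quality is constant at
    ``phred``; substitution errors occur at the matching rate.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    templates = [_ungapped(h) for h in truth.normal_haplotypes]
    if min(len(t) for t in templates) < read_length:
        raise ValueError("read_length exceeds haplotype length")
    mean_len = int(np.mean([len(t) for t in templates]))
    n_pairs = max(1, int(round(coverage * mean_len / (2 * read_length))))
    quals = np.full(read_length, phred, dtype=np.int64)

    # subclonal events need per-fragment application; clonal ones are
    # already in the tumor haplotypes
    subclonal = [ev for ev in truth.somatic
                 if ev.get("cellular_fraction", 1.0) < 1.0]

    pairs = []
    for i in range(n_pairs):
        if paralog_fraction > 0 and paralog_msa is not None \
                and rng.random() < paralog_fraction:
            k = int(rng.integers(paralog_msa.n_alleles))
            template = paralog_msa.ungapped_sequence(k)
            origin = "paralog"
        else:
            hap = int(rng.integers(2))
            if sample == "tumor" and rng.random() < truth.purity:
                row = truth.tumor_haplotypes[hap].copy()
                for ev in subclonal:
                    if ev["haplotype"] != hap:
                        continue
                    if rng.random() >= ev["cellular_fraction"]:
                        # revert the event for this fragment
                        if ev["kind"] == "substitution":
                            row[ev["column0"]] = "ACGT".index(ev["ref"])
                template = _ungapped(row)
            else:
                template = templates[hap]
            origin = f"hap{hap}"
        r1, r2 = _fragment_reads(template, read_length, insert, phred, rng)
        pairs.append(ReadPair(
            id=f"{id_prefix}{i:06d}_{origin}",
            mates=[Mate(r1, quals.copy()), Mate(r2, quals.copy())],
            sample=sample))
    return pairs


def default_scenario(seed: int, with_mutations: bool = True,
                     n_alleles: int = 20, msa_length: int = 250,
                     divergence: float = 0.02, n_germline: int = 2,
                     purity: float = 0.8, coverage_normal: float = 30.0,
                     coverage_tumor: float = 60.0, phred: int = 30,
                     read_length: int = 80, paralog_fraction: float = 0.1):
    """The package's reference synthetic experiment.

    A 20-allele panel with one diverged paralog locus; a diploid
    individual with two germline substitutions; tumor purity 0.8; 30x
    normal and 60x tumor coverage at Phred 30.  When ``with_mutations``
    is set, one clonal somatic substitution and one clonal 2-bp somatic
    deletion are planted at distinct, fully covered columns (expected
    variant allele fraction 0.4 at purity 0.8).  Returns
    ``(msa, freqs, paralog, truth, normal_pairs, tumor_pairs)``.
    """
    from hlabayesnt.reference_panel import synthesize_panel

    rng = np.random.default_rng(seed)
    msa, freqs, paralog = synthesize_panel(
        n_alleles, msa_length, divergence, n_paralogs=1, seed=100_000 + seed)
    truth = simulate_individual(msa, freqs, n_germline, rng, seed=seed)
    truth.purity = purity
    if with_mutations:
        # keep events inside fully covered sequence: read_length from the
        # ends at the default locus size, proportionally less on short loci
        margin = min(read_length, max(0, (msa_length - read_length) // 2 - 5))
        truth = add_somatic_events(
            truth,
            [{"kind": "substitution", "cellular_fraction": 1.0},
             {"kind": "deletion", "length": 2, "cellular_fraction": 1.0}],
            rng, margin=margin)
    normal = simulate_reads(truth, read_length=read_length,
                            coverage=coverage_normal, phred=phred,
                            sample="normal", rng=rng,
                            paralog_fraction=paralog_fraction,
                            paralog_msa=paralog, id_prefix="n")
    tumor = simulate_reads(truth, read_length=read_length,
                           coverage=coverage_tumor, phred=phred,
                           sample="tumor", rng=rng,
                           paralog_fraction=paralog_fraction,
                           paralog_msa=paralog, id_prefix="t")
    return msa, freqs, paralog, truth, normal, tumor


def write_fastq(pairs: list, path_r1, path_r2) -> None:
    """Write mates 1 and 2 of every pair as a FASTQ file pair."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            for mate, fh in zip(p.mates, (f1, f2)):
                qual = "".join(chr(q + 33) for q in mate.qualities)
                fh.write(f"@{p.id}\n{mate.sequence}\n+\n{qual}\n")


def read_fastq_pairs(path_r1, path_r2, sample: str = "normal") -> list:
    """Load a FASTQ file pair back into :class:`ReadPair` objects."""
    def _records(path):
        with open(path) as fh:
            while True:
                head = fh.readline().strip()
                if not head:
                    return
                seq = fh.readline().strip()
                fh.readline()
                qual = fh.readline().strip()
                quals = np.array([ord(c) - 33 for c in qual], dtype=np.int64)
                yield head[1:], Mate(seq, quals)

    out = []
    for (id1, m1), (id2, m2) in zip(_records(path_r1), _records(path_r2)):
        if id1 != id2:
            raise ValueError("FASTQ pair files are out of sync")
        out.append(ReadPair(id=id1, mates=[m1, m2], sample=sample))
    return out


def write_truth_json(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
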