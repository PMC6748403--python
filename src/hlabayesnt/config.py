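"""Model hyperparameters: scoring weights, error rates, and prior settings.

All tunable constants of the pipeline live in a single
:class:`HyperParameters` object that can be round-tripped through YAML.
Ordering constraints that the model relies on (e.g. germline deviation
probabilities at imputed reference positions must be at least those at
originally sequenced positions, and decoy haplotypes must be at least as
permissive as non-decoy ones) are validated on construction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Event order of germline/somatic deviation probabilities.
EVENTS = ("sub", "del", "ins", "n")


def _default_germline() -> np.ndarray:
    # [decoy][imputed][event]; decoy rows 10x more permissive, imputed
    # positions 10x more permissive than originally sequenced ones.
    g = np.empty((2, 2, 4))
    g[0, 0] = 1e-3
    g[0, 1] = 1e-2
    g[1, 0] = 1e-2
    g[1, 1] = 1e-1
    return g


@dataclass
class HyperParameters:
    """Every tunable constant of the scoring, filtering, and model stages.

    Attributes
    ----------
    alpha_reward:
        Per-aligned-base reward of the read-to-allele score (positive).
    alpha_del_open, alpha_del_ext, alpha_ins_open, alpha_ins_ext, alpha_n:
        Non-positive penalties for gap opening/extension and for columns
        containing an ``N``.
    theta_paired_score, theta_paired_diff:
        Locus-assignment thresholds for paired-end reads: minimum locus
        score, and minimum margin over the best other locus.
    theta_single_score, theta_single_diff:
        Stricter thresholds applied to single-end (unpaired) reads.
    min_alignment_score:
        Raw local-alignment score floor below which a read-to-allele
        alignment is treated as unmapped.
    err_del, err_ins, err_n:
        Sequencing-error probabilities: spurious deletion, spurious
        insertion, and an ``N`` base call in a read.
    som_sub, som_del, som_ins, som_n:
        Per-position somatic event probabilities (tumor vs. normal
        haplotype).
    germline:
        Array of shape ``(2, 2, 4)`` indexed by ``[decoy][imputed][event]``
        with events ordered ``(sub, del, ins, n)``: per-position germline
        deviation probabilities of a normal haplotype from its reference
        allele.
    freq_mu_ref, freq_sigma_ref, freq_mu_decoy, freq_sigma_decoy:
        Log-normal prior on the read-generating propensity ``F`` of
        non-decoy and decoy haplotypes.
    contam_mu, contam_sigma:
        Log-normal prior on the normal-cell fraction ``G`` of the tumor
        sample.
    valid_open, valid_ext:
        Markov-chain prior on decoy validity flags: probability that a
        valid run opens after an invalid position, and that it extends.
    n_decoys:
        Number of decoy haplotypes absorbing reads from paralogous genes.
    freq_proposal_sigma:
        Scale of the log-normal random-walk proposal for ``F``.
    decoy_reassign_mismatches:
        Burn-in heuristic: reads with more than this many mismatches
        against both non-decoy references are pushed onto a decoy.
    """

    # read-to-allele score
    alpha_reward: float = 1.0
    alpha_del_open: float = -6.0
    alpha_del_ext: float = -1.0
    alpha_ins_open: float = -6.0
    alpha_ins_ext: float = -1.0
    alpha_n: float = -1.0
    # locus filtering thresholds
    theta_paired_score: float = 0.0
    theta_paired_diff: float = 10.0
    theta_single_score: float = 20.0
    theta_single_diff: float = 20.0
    min_alignment_score: float = 30.0
    # read error probabilities
    err_del: float = 1e-3
    err_ins: float = 1e-3
    err_n: float = 1e-4
    # somatic event probabilities
    som_sub: float = 1e-4
    som_del: float = 1e-4
    som_ins: float = 1e-4
    som_n: float = 1e-4
    # germline deviation probabilities [decoy][imputed][sub, del, ins, n]
    germline: np.ndarray = field(default_factory=_default_germline)
    # log-normal prior on F
    freq_mu_ref: float = 0.0
    freq_sigma_ref: float = 0.5
    freq_mu_decoy: float = -2.5
    freq_sigma_decoy: float = 0.5
    # log-normal prior on G
    contam_mu: float = -1.5
    contam_sigma: float = 1.0
    # validity flag prior
    valid_open: float = 0.01
    valid_ext: float = 0.99
    # structure
    n_decoys: int = 2
    # sampler knobs
    freq_proposal_sigma: float = 0.3
    decoy_reassign_mismatches: int = 15

    def __post_init__(self) -> None:
        self.germline = np.asarray(self.germline, dtype=float)
        self.validate()

    # Wolff proposal continuation probabilities are tied to the validity
    # prior: growing through a 0-run continues with 1 - valid_open, through
    # a 1-run with valid_ext.
    @property
    def wolff_ext0(self) -> float:
        return 1.0 - self.valid_open

    @property
    def wolff_ext1(self) -> float:
        return self.valid_ext

    def validate(self) -> None:
        h = self
        if not h.alpha_reward > 0:
            raise ValueError("alpha_reward must be positive")
        for name in ("alpha_del_open", "alpha_del_ext", "alpha_ins_open",
                     "alpha_ins_ext", "alpha_n"):
            if getattr(h, name) > 0:
                raise ValueError(f"{name} must be <= 0")
        for name in ("err_del", "err_ins", "err_n", "som_sub", "som_del",
                     "som_ins", "som_n", "valid_open", "valid_ext"):
            v = getattr(h, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if h.err_del + h.err_n >= 1 or h.err_ins + h.err_n >= 1:
            raise ValueError("read error probabilities sum to >= 1")
        if h.som_sub + h.som_del + h.som_n >= 1 or h.som_ins + h.som_n >= 1:
            raise ValueError("somatic event probabilities sum to >= 1")
        if h.germline.shape != (2, 2, 4):
            raise ValueError("germline must have shape (2, 2, 4)")
        if ((h.germline <= 0) | (h.germline >= 1)).any():
            raise ValueError("germline probabilities must be in (0, 1)")
        sums = h.germline[..., [0, 1, 3]].sum(axis=-1)
        if (sums >= 1).any() or (h.germline[..., [2, 3]].sum(axis=-1) >= 1).any():
            raise ValueError("germline probabilities sum to >= 1")
        if (h.germline[:, 1, :] < h.germline[:, 0, :]).any():
            raise ValueError(
                "germline probabilities at imputed positions must be >= "
                "those at original positions")
        if (h.germline[1] < h.germline[0]).any():
            raise ValueError(
                "decoy germline probabilities must be >= nondecoy ones")
        for name in ("freq_sigma_ref", "freq_sigma_decoy", "contam_sigma",
                     "freq_proposal_sigma"):
            if getattr(h, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not h.freq_mu_decoy < h.freq_mu_ref:
            raise ValueError("freq_mu_decoy must be smaller than freq_mu_ref")
        if h.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        g = d.pop("germline")
        d["germline"] = {
            cls: {
                kind: dict(zip(EVENTS, [float(x) for x in g[i][j]]))
                for j, kind in enumerate(("original", "imputed"))
            }
            for i, cls in enumerate(("nondecoy", "decoy"))
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParameters":
        d = dict(d)
        if "germline" in d and isinstance(d["germline"], dict):
            gd = d["germline"]
            g = np.empty((2, 2, 4))
            for i, c in enumerate(("nondecoy", "decoy")):
                for j, kind in enumerate(("original", "imputed")):
                    g[i, j] = [gd[c][kind][e] for e in EVENTS]
            d["germline"] = g
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown hyperparameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "HyperParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "HyperParameters":
        return dataclasses.replace(self, **kw)


def lognormal_logpdf(x: float, mu: float, sigma: float) -> float:
    """Log-density of a log-normal with log-scale mean/sd ``mu``/``sigma``."""
    if x <= 0:
        return -math.inf
    lx = math.log(x)
    return -math.log(x * sigma * math.sqrt(2 * math.pi)) \
        - (lx - mu) ** 2 / (2 * sigma ** 2)
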