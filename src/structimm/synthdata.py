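"""Synthetic fixtures: groove structures and labeled peptide pools.

Nothing here requires a download.  The groove fixture is a deliberately
minimal stand-in for an MHC class I binding groove: two idealized
antiparallel alpha-helices flanking an extended nonamer, enough structure
to exercise threading, refinement, scoring and SASA occlusion end to end.
The peptide generator emulates the statistical shape of the real corpus:
an immunogenic pool enriched in hydrophobic residues at TCR-facing
positions (4, 5, 7, 8 by default), an MHC-binding self pool, and a
nonbinder pool violating the canonical anchor rules at positions 2 and 9.
Pool sizes default to the real corpus proportions (self 2756, immunogenic
155, nonbinder 1044).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import PeptideRecord
from .errors import ConfigError
from .features import wimley_white_scale
from .modeling import build_backbone
from .structmodel import AA_ALPHABET, Chain, Complex

ANCHOR_RESIDUES = "LMIV"          # canonical HLA-A2 anchor set at p2/p9
_NON_ANCHOR = "DEKNQRSHGPTY"      # forced at p2/p9 in the nonbinder pool

# mildly realistic background amino-acid weights
_BG_WEIGHTS = {
    "A": 8, "C": 2, "D": 5, "E": 6, "F": 4, "G": 7, "H": 2, "I": 5,
    "K": 6, "L": 9, "M": 2, "N": 4, "P": 5, "Q": 4, "R": 5, "S": 7,
    "T": 6, "V": 7, "W": 1, "Y": 3,
}


@dataclass
class GrooveFixtureConfig:
    seed: int = 0
    helix_length: int = 24
    groove_width: float = 13.0         # A between the two helix axes
    peptide_sequence: str = "LLFGYPVYV"
    noise: float = 0.0                 # A, Gaussian jitter on every atom
    helix_sequence: str | None = None  # defaults to a repeating amphipathic motif

    def __post_init__(self) -> None:
        if len(self.peptide_sequence) != 9:
            raise ConfigError("peptide_sequence must be a nonamer")
        if self.noise < 0:
            raise ConfigError("noise must be >= 0")


def _axis_align(coords: np.ndarray, axis_from: np.ndarray) -> np.ndarray:
    """Rotate so *axis_from* maps onto +x, then center at the origin."""
    v = axis_from / np.linalg.norm(axis_from)
    x = np.array([1.0, 0.0, 0.0])
    c = float(np.dot(v, x))
    if c > 1.0 - 1e-12:
        rot = np.eye(3)
    elif c < -1.0 + 1e-12:
        rot = np.diag([-1.0, -1.0, 1.0])
    else:
        k = np.cross(v, x)
        s = np.linalg.norm(k)
        k = k / s
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + kx * s + kx @ kx * (1 - c)
    out = coords @ rot.T
    return out - out.mean(axis=0)


def _place_chain(residues, offset, flip=False):
    coords = np.array([a.position for r in residues for a in r.atoms])
    ca = [r.atom("CA").position for r in residues]
    aligned = _axis_align(coords, np.asarray(ca[-1]) - np.asarray(ca[0]))
    if flip:
        aligned = aligned @ np.diag([-1.0, -1.0, 1.0]).T
    aligned = aligned + np.asarray(offset)
    k = 0
    for r in residues:
        for a in r.atoms:
            a.position = aligned[k]
            k += 1
    return residues


def make_groove_fixture(config: GrooveFixtureConfig | None = None) -> Complex:
    """Two-helix groove holding an extended nonamer; deterministic by seed."""
    config = config or GrooveFixtureConfig()
    helix_seq = config.helix_sequence
    if helix_seq is None:
        motif = "LAELAKKSA"
        helix_seq = (motif * (config.helix_length // len(motif) + 1)
                     )[:config.helix_length]
    half = config.groove_width / 2.0

    h1 = build_backbone(helix_seq, phi=-57.0, psi=-47.0, chain_id="A",
                        chis=(180.0,) * 4)
    _place_chain(h1, (0.0, -half, 0.0))
    h2 = build_backbone(helix_seq, phi=-57.0, psi=-47.0, chain_id="B",
                        chis=(180.0,) * 4)
    _place_chain(h2, (0.0, half, 0.0), flip=True)
    pep = build_backbone(config.peptide_sequence, phi=-139.0, psi=135.0,
                         chain_id="C", chis=(180.0,) * 4)
    _place_chain(pep, (0.0, 0.0, 0.0))
    for chain_id, residues in (("A", h1), ("B", h2), ("C", pep)):
        for r in residues:
            r.chain_id = chain_id
    cx = Complex([Chain("A", h1), Chain("B", h2), Chain("C", pep)],
                 peptide_chain_id="C",
                 template_id=f"synthetic-groove-seed{config.seed}")
    if config.noise > 0:
        rng = np.random.default_rng(config.seed)
        for a in cx.iter_atoms():
            a.position = a.position + rng.normal(0.0, config.noise, size=3)
    cx.validate()
    return cx


# ---------------------------------------------------------------------------
# labeled peptide pools

@dataclass
class SyntheticDatasetConfig:
    n_self: int = 2756
    n_immunogenic: int = 155
    n_nonbinder: int = 1044
    # logistic immunogenicity propensity on -hydropathy at weighted positions
    coefficients: dict[int, float] = field(
        default_factory=lambda: {4: 1.8, 5: 1.0, 7: 1.8, 8: 1.4})
    intercept: float = -1.0
    seed: int = 0
    # optional stochastic pool assignment: n_total records, immunogenic
    # drawn per-record with probability base_rate
    n_total: int | None = None
    base_rate: float | None = None

    def __post_init__(self) -> None:
        for n in (self.n_self, self.n_immunogenic, self.n_nonbinder):
            if n < 1:
                raise ConfigError("pool sizes must be >= 1")
        if not all(np.isfinite(v) for v in self.coefficients.values()):
            raise ConfigError("coefficients must be finite")


def _sample_seq(rng, anchors: bool) -> str:
    aas = list(_BG_WEIGHTS)
    w = np.array([_BG_WEIGHTS[a] for a in aas], dtype=float)
    w /= w.sum()
    seq = [aas[i] for i in rng.choice(len(aas), size=9, p=w)]
    if anchors:
        seq[1] = ANCHOR_RESIDUES[rng.integers(len(ANCHOR_RESIDUES))]
        seq[8] = ANCHOR_RESIDUES[rng.integers(len(ANCHOR_RESIDUES))]
    else:
        seq[1] = _NON_ANCHOR[rng.integers(len(_NON_ANCHOR))]
        seq[8] = _NON_ANCHOR[rng.integers(len(_NON_ANCHOR))]
    return "".join(seq)


def _propensity(seq: str, config: SyntheticDatasetConfig,
                scale: dict[str, float]) -> float:
    z = config.intercept
    for pos, coef in config.coefficients.items():
        z += coef * (-scale[seq[pos - 1]])  # negative scale = hydrophobic
    return z


def make_labeled_peptides(config: SyntheticDatasetConfig | None = None
                          ) -> list[PeptideRecord]:
    """Sample the three pools; deterministic given config.seed.

    The immunogenic pool is rejection-sampled so that acceptance follows a
    logistic model in positional hydrophobicity at the weighted (TCR-facing)
    positions; the self pool is plain anchor-compatible background; the
    nonbinder pool violates the p2/p9 anchor rules.
    """
    config = config or SyntheticDatasetConfig()
    rng = np.random.default_rng(config.seed)
    scale = wimley_white_scale()

    n_imm, n_self, n_non = (config.n_immunogenic, config.n_self,
                            config.n_nonbinder)
    if config.n_total is not None and config.base_rate is not None:
        # per-record pool assignment: immunogenic with prob base_rate,
        # remainder split self:nonbinder at the default corpus ratio
        draws = rng.uniform(size=config.n_total)
        n_imm = max(int(np.sum(draws < config.base_rate)), 1)
        rest = config.n_total - n_imm
        frac_self = config.n_self / (config.n_self + config.n_nonbinder)
        n_self = max(int(round(rest * frac_self)), 1)
        n_non = max(rest - n_self, 1)

    records: list[PeptideRecord] = []
    accepted = 0
    while accepted < n_imm:
        seq = _sample_seq(rng, anchors=True)
        z = _propensity(seq, config, scale)
        if rng.uniform() < 1.0 / (1.0 + math.exp(-z)):
            records.append(PeptideRecord(
                sequence=seq, pool="immunogenic", allele="HLA-A*02:01",
                response_frequency=float(50 + rng.poisson(30)),
                provenance="synthetic-immunogenic"))
            accepted += 1
    for _ in range(n_self):
        records.append(PeptideRecord(
            sequence=_sample_seq(rng, anchors=True), pool="self",
            allele="HLA-A*02:01", provenance="synthetic-self"))
    for _ in range(n_non):
        records.append(PeptideRecord(
            sequence=_sample_seq(rng, anchors=False), pool="nonbinder",
            allele="HLA-A*02:01", provenance="synthetic-nonbinder"))
    return records
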