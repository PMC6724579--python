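"""Network input vectors: structure-derived and sequence-only encodings.

The structure-derived candidate vector has 117 entries: 18 whole-complex
energy terms (registry order), then for each peptide position p1..p9 the 9
atomic-level per-residue energy terms plus total and hydrophobic SASA
(11 per position).  Selection masks reduce the per-position block; the
shipped final mask keeps 7 entries per position, giving 18 + 9*7 = 81.

Sequence-only baselines: a flattened 20x9 one-hot encoding (180 inputs) and
a 9-long Wimley-White interface hydropathy profile.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .energy import EnergyBreakdown, TermRegistry, default_registry
from .errors import EncodingError, LayoutError
from .structmodel import AA_ALPHABET
from .surface import SasaResult

SASA_TERMS = ("sasa_total", "sasa_hydrophobic")

_WW_SCALE: dict[str, float] | None = None


def wimley_white_scale() -> dict[str, float]:
    """Packaged Wimley-White interface hydropathy values (kcal/mol).

    Negative = hydrophobic (favorable membrane-interface partitioning).
    """
    global _WW_SCALE
    if _WW_SCALE is None:
        table = {}
        ref = importlib.resources.files("structimm.data") / "wimley_white.tsv"
        for line in ref.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("aa\t"):
                continue
            aa, val = line.split("\t")
            table[aa] = float(val)
        _WW_SCALE = table
    return _WW_SCALE


@dataclass
class StructureFeatureVector:
    values: np.ndarray
    layout: list[str]
    selected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.layout):
            raise LayoutError(f"{len(self.values)} values vs "
                              f"{len(self.layout)} layout names")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SelectionMask:
    """Kept complex-term names plus kept per-residue term names (applied
    uniformly to all nine positions)."""

    complex_terms: list[str]
    residue_terms: list[str]


def paper_final_mask(registry: TermRegistry | None = None) -> SelectionMask:
    """Default post-selection mask: all 18 complex terms and 7 per-position
    entries (hydrophobic solvation, electrostatics, packing terms plus both
    SASA aggregates).  The exact surviving per-position set is configurable;
    this default keeps the terms with the clearest physical signal for
    TCR-facing positions.
    """
    registry = registry or default_registry()
    return SelectionMask(
        complex_terms=list(registry.complex_terms),
        residue_terms=["fa_atr", "fa_rep", "fa_sol", "fa_elec", "hbond_sc",
                       "sasa_total", "sasa_hydrophobic"],
    )


def candidate_layout(registry: TermRegistry | None = None) -> list[str]:
    registry = registry or default_registry()
    names = list(registry.complex_terms)
    for pos in range(1, 10):
        for t in registry.residue_terms:
            names.append(f"p{pos}:{t}")
        for t in SASA_TERMS:
            names.append(f"p{pos}:{t}")
    return names


def build_candidate_vector(consensus_energy: EnergyBreakdown,
                           consensus_sasa: SasaResult,
                           registry: TermRegistry | None = None
                           ) -> StructureFeatureVector:
    """Assemble the full candidate vector from averaged decoy features."""
    registry = registry or default_registry()
    values: list[float] = []
    for t in registry.complex_terms:
        if t not in consensus_energy.unweighted:
            raise LayoutError(f"consensus breakdown missing complex term {t!r}")
        values.append(consensus_energy.unweighted[t])
    for pos in range(1, 10):
        for t in registry.residue_terms:
            key = (pos, t)
            if key not in consensus_energy.per_residue:
                raise LayoutError(f"missing per-residue term {t!r} at p{pos}")
            values.append(consensus_energy.per_residue[key])
        if pos not in consensus_sasa.per_residue_total:
            raise LayoutError(f"missing SASA for peptide position p{pos}")
        values.append(consensus_sasa.per_residue_total[pos])
        values.append(consensus_sasa.per_residue_hydrophobic.get(pos, 0.0))
    return StructureFeatureVector(np.array(values), candidate_layout(registry))


def apply_mask(vector: StructureFeatureVector,
               mask: SelectionMask) -> StructureFeatureVector:
    """Project a candidate-layout vector onto the selected layout."""
    if vector.selected:
        raise LayoutError("vector is already in a selected layout")
    index = {name: i for i, name in enumerate(vector.layout)}
    keep_names: list[str] = []
    for t in mask.complex_terms:
        if t not in index:
            raise LayoutError(f"mask complex term {t!r} absent from layout")
        keep_names.append(t)
    for pos in range(1, 10):
        for t in mask.residue_terms:
            name = f"p{pos}:{t}"
            if name not in index:
                raise LayoutError(f"mask per-residue term {name!r} absent")
            keep_names.append(name)
    idx = [index[n] for n in keep_names]
    return StructureFeatureVector(vector.values[idx], keep_names, selected=True)


def _check_nonamer(sequence: str) -> str:
    sequence = sequence.upper()
    if len(sequence) != 9:
        raise EncodingError(f"expected a nonamer, got length {len(sequence)}")
    bad = set(sequence) - set(AA_ALPHABET)
    if bad:
        raise EncodingError(f"invalid amino-acid letter(s): {sorted(bad)}")
    return sequence


def one_hot_encode(sequence: str) -> np.ndarray:
    """Flattened 20x9 indicator vector (position-major), 180 long."""
    sequence = _check_nonamer(sequence)
    vec = np.zeros(180)
    for pos, aa in enumerate(sequence):
        vec[pos * 20 + AA_ALPHABET.index(aa)] = 1.0
    return vec


def hydropathy_encode(sequence: str) -> np.ndarray:
    """Positional Wimley-White interface hydropathy profile, 9 long."""
    sequence = _check_nonamer(sequence)
    scale = wimley_white_scale()
    return np.array([scale[aa] for aa in sequence])
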