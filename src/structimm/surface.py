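"""Solvent-accessible surface area by deterministic sphere-point sampling.

Shrake-Rupley style: each heavy atom carries a fixed golden-spiral point set
on its solvent-expanded sphere (radius + probe); points occluded by any
neighbor's expanded sphere are removed and the surviving fraction scales the
analytic sphere area.  The point layout is a pure function of ``n_points``,
so results are exactly reproducible — no RNG anywhere.

Hydrophobic classification is atomic: carbon and sulfur count as
hydrophobic, nitrogen and oxygen as polar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError
from .structmodel import Complex

# heavy-atom van der Waals radii (A)
_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
_HYDROPHOBIC_ELEMENTS = {"C", "S"}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


@dataclass
class SasaResult:
    per_atom: np.ndarray                      # A^2, one entry per atom in order
    per_residue_total: dict[int, float] = field(default_factory=dict)
    per_residue_hydrophobic: dict[int, float] = field(default_factory=dict)
    peptide_total: float = 0.0
    peptide_hydrophobic: float = 0.0


def sasa(cx: Complex, probe_radius: float = 1.4, n_points: int = 960) -> SasaResult:
    """SASA of every atom; peptide aggregates computed in complex context.

    The groove occludes the peptide: per-residue values for peptide
    positions 1..9 reflect only the surface still reachable by the probe in
    the assembled complex.
    """
    atoms = list(cx.iter_atoms())
    if not atoms:
        raise EmptyStructureError("no atoms for SASA")
    coords = np.array([a.position for a in atoms])
    radii = np.array([_RADII.get(a.element[0].upper(), 1.70) for a in atoms])
    hydroph = np.array([a.element[0].upper() in _HYDROPHOBIC_ELEMENTS
                        for a in atoms])
    expanded = radii + probe_radius
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom = np.zeros(len(atoms))
    for idx in range(len(atoms)):
        pts = coords[idx] + expanded[idx] * unit
        nbrs = [j for j in tree.query_ball_point(coords[idx], max_reach)
                if j != idx]
        if nbrs:
            nbrs = np.array(nbrs)
            d2 = np.sum((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < expanded[nbrs][None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[idx] = frac * 4.0 * np.pi * expanded[idx] ** 2

    result = SasaResult(per_atom=per_atom)
    if cx.peptide_chain_id is not None:
        # map atom index ranges for peptide residues
        k = 0
        for chain in cx.chains:
            for ri, res in enumerate(chain.residues):
                n_at = len(res.atoms)
                if chain.chain_id == cx.peptide_chain_id:
                    sl = slice(k, k + n_at)
                    tot = float(per_atom[sl].sum())
                    hyd = float(per_atom[sl][hydroph[sl]].sum())
                    result.per_residue_total[ri + 1] = tot
                    result.per_residue_hydrophobic[ri + 1] = hyd
                k += n_at
        result.peptide_total = sum(result.per_residue_total.values())
        result.peptide_hydrophobic = sum(result.per_residue_hydrophobic.values())
    return result


def hydrophobic_fraction(result: SasaResult) -> tuple[dict[int, float], float]:
    """Hydrophobic share of exposed area per peptide position and overall.

    Fully buried positions (zero total area) report a fraction of 0.
    """
    per_pos = {}
    for pos, tot in result.per_residue_total.items():
        hyd = result.per_residue_hydrophobic.get(pos, 0.0)
        per_pos[pos] = hyd / tot if tot > 0 else 0.0
    overall = (result.peptide_hydrophobic / result.peptide_total
               if result.peptide_total > 0 else 0.0)
    return per_pos, overall
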