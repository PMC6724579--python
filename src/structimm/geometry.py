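"""Least-squares superposition (Kabsch) and the two RMSD metrics.

RMSDs can be evaluated in two frames: ``groove`` fits the superposition on
groove C-alpha atoms only and then measures the peptide without refitting
(how far the peptide sits from its reference placement *within* the groove),
while ``peptide`` fits and evaluates on the peptide itself (pure
conformational difference).  Reflections are excluded: the returned rotation
is always proper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, PairingError
from .structmodel import Complex, Residue

HEAVY_BACKBONE = ("N", "CA", "C", "O")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, proper orthonormal
    translation: np.ndarray   # 3-vector, Angstrom
    fit_rmsd: float           # over the fitting atom set

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Rigid transform minimizing sum of squared paired distances.

    Closed-form Kabsch solution via SVD; the reflection branch is folded to
    a proper rotation.  Requires n >= 3 non-collinear paired points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise PairingError(f"coordinate sets must be paired (n,3) arrays, "
                           f"got {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - mc, ref - rc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    # collinear sets leave the rotation about the line undetermined
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear or coincident")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, fit_rmsd=rmsd)


def _ca_coords(residues: list[Residue]) -> np.ndarray:
    out = []
    for r in residues:
        try:
            out.append(r.atom("CA").position)
        except KeyError as exc:
            raise PairingError(str(exc)) from exc
    return np.array(out, dtype=float)


def _groove_ca(cx: Complex) -> np.ndarray:
    res = [r for c in cx.groove_chains() for r in c.residues]
    return _ca_coords(res)


def _paired_heavy(model_res: list[Residue], ref_res: list[Residue]):
    """Pair peptide heavy atoms by (position, atom name); mutated positions
    fall back to the common-atom set (always includes the backbone)."""
    mob, ref, names = [], [], []
    for i, (mr, rr) in enumerate(zip(model_res, ref_res)):
        ref_names = {a.name for a in rr.atoms}
        for a in mr.atoms:
            if a.name in ref_names:
                mob.append(a.position)
                ref.append(rr.atom(a.name).position)
                names.append((i + 1, a.name))
    if not mob:
        raise PairingError("no atoms could be paired between model and reference")
    return np.array(mob), np.array(ref), names


def _aligned_peptide_rmsd(cx_model: Complex, cx_ref: Complex,
                          frame: str, ca_only: bool) -> float:
    if frame not in ("groove", "peptide"):
        raise ValueError(f"frame must be 'groove' or 'peptide', got {frame!r}")
    mres = cx_model.peptide.residues
    rres = cx_ref.peptide.residues
    if len(mres) != len(rres):
        raise PairingError(f"peptide lengths differ: {len(mres)} vs {len(rres)}")
    if ca_only:
        mob_eval, ref_eval = _ca_coords(mres), _ca_coords(rres)
    else:
        mob_eval, ref_eval, _ = _paired_heavy(mres, rres)
    if frame == "groove":
        mg, rg = _groove_ca(cx_model), _groove_ca(cx_ref)
        if mg.shape != rg.shape:
            raise PairingError(f"groove CA sets differ: {mg.shape[0]} vs "
                               f"{rg.shape[0]} atoms")
        sup = superpose(mg, rg)
    else:
        sup = superpose(mob_eval, ref_eval)
    moved = sup.apply(mob_eval)
    return float(np.sqrt(np.mean(np.sum((moved - ref_eval) ** 2, axis=1))))


def rmsd_ca(model: Complex, reference: Complex, frame: str = "groove") -> float:
    """Peptide C-alpha RMSD (Angstrom) in the chosen frame."""
    return _aligned_peptide_rmsd(model, reference, frame, ca_only=True)


def rmsd_full_atom(model: Complex, reference: Complex,
                   frame: str = "groove") -> float:
    """Peptide heavy-atom RMSD; mismatched residues pair common atoms only."""
    return _aligned_peptide_rmsd(model, reference, frame, ca_only=False)
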