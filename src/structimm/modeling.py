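"""Peptide threading and Monte-Carlo refinement against a groove template.

``thread`` rewrites the template peptide's sequence in place: backbone
coordinates are kept, mutated side chains are rebuilt from ideal internal
geometry in a default (all-trans) rotamer.  ``refine`` runs Metropolis
simulated annealing over side-chain rotamer swaps (coarse
gauche-/trans/gauche+ library) and peptide-backbone crankshaft rotations,
producing an ensemble of independent decoys; ``consensus_features`` averages
the unweighted energy terms and SASA of the lowest-energy decoys, which is
what the classifier consumes.

Internal-coordinate atom placement (NeRF) lives here and is shared with the
synthetic groove generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import AtomTable, EnergyBreakdown, TermRegistry, default_registry
from .errors import ConfigError, EncodingError
from .structmodel import AA_ALPHABET, Atom, Complex, Residue
from .surface import SasaResult, sasa

# ---------------------------------------------------------------------------
# internal-coordinate geometry


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position D bonded to *a* with angle D-a-b and dihedral D-a-b-c."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    e1 = b - a
    e1 = e1 / np.linalg.norm(e1)
    u = c - a
    e2 = u - np.dot(u, e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    direction = (math.cos(theta) * e1
                 + math.sin(theta) * (math.cos(phi) * e2 - math.sin(phi) * e3))
    return a + bond * direction


def dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / (np.linalg.norm(b1) + 1e-12))
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


# side-chain topology: (atom, ref_bonded, ref_angle, ref_dihedral, bond A,
# angle deg, dihedral).  Dihedral entries are floats (fixed) or
# ("chi", k, offset_deg) meaning rotamer angle chi_k + offset.
_SC = {
    "A": [],
    "G": None,  # no CB at all
    "S": [("OG", "CB", "CA", "N", 1.42, 110.5, ("chi", 1, 0.0))],
    "C": [("SG", "CB", "CA", "N", 1.81, 114.0, ("chi", 1, 0.0))],
    "T": [("OG1", "CB", "CA", "N", 1.43, 109.5, ("chi", 1, 0.0)),
          ("CG2", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, -120.0))],
    "V": [("CG1", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, 0.0)),
          ("CG2", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, 120.0))],
    "L": [("CG", "CB", "CA", "N", 1.53, 116.3, ("chi", 1, 0.0)),
          ("CD1", "CG", "CB", "CA", 1.52, 110.5, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.52, 110.5, ("chi", 2, 120.0))],
    "I": [("CG1", "CB", "CA", "N", 1.53, 110.5, ("chi", 1, 0.0)),
          ("CG2", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, -120.0)),
          ("CD1", "CG1", "CB", "CA", 1.52, 113.8, ("chi", 2, 0.0))],
    "M": [("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1, 0.0)),
          ("SD", "CG", "CB", "CA", 1.80, 112.7, ("chi", 2, 0.0)),
          ("CE", "SD", "CG", "CB", 1.79, 100.9, ("chi", 3, 0.0))],
    "P": [("CG", "CB", "CA", "N", 1.49, 104.0, 30.0),
          ("CD", "CG", "CB", "CA", 1.50, 105.0, -35.0)],
    "F": [("CG", "CB", "CA", "N", 1.50, 113.8, ("chi", 1, 0.0)),
          ("CD1", "CG", "CB", "CA", 1.39, 120.0, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.39, 120.0, ("chi", 2, 180.0)),
          ("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
          ("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
          ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0)],
    "Y": [("CG", "CB", "CA", "N", 1.50, 113.8, ("chi", 1, 0.0)),
          ("CD1", "CG", "CB", "CA", 1.39, 120.0, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.39, 120.0, ("chi", 2, 180.0)),
          ("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
          ("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
          ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
          ("OH", "CZ", "CE1", "CD1", 1.38, 120.0, 180.0)],
    "W": [("CG", "CB", "CA", "N", 1.50, 113.8, ("chi", 1, 0.0)),
          ("CD1", "CG", "CB", "CA", 1.37, 127.0, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.43, 126.6, ("chi", 2, 180.0)),
          ("NE1", "CD1", "CG", "CB", 1.38, 110.0, 180.0),
          ("CE2", "CD2", "CG", "CB", 1.41, 107.0, 180.0),
          ("CE3", "CD2", "CG", "CB", 1.40, 133.9, 0.0),
          ("CZ2", "CE2", "CD2", "CG", 1.40, 122.0, 180.0),
          ("CZ3", "CE3", "CD2", "CG", 1.39, 118.8, 180.0),
          ("CH2", "CZ2", "CE2", "CD2", 1.37, 117.5, 180.0)],
    "D": [("CG", "CB", "CA", "N", 1.52, 113.0, ("chi", 1, 0.0)),
          ("OD1", "CG", "CB", "CA", 1.25, 119.0, ("chi", 2, 0.0)),
          ("OD2", "CG", "CB", "CA", 1.25, 119.0, ("chi", 2, 180.0))],
    "N": [("CG", "CB", "CA", "N", 1.52, 113.0, ("chi", 1, 0.0)),
          ("OD1", "CG", "CB", "CA", 1.23, 120.8, ("chi", 2, 0.0)),
          ("ND2", "CG", "CB", "CA", 1.33, 116.4, ("chi", 2, 180.0))],
    "E": [("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1, 0.0)),
          ("CD", "CG", "CB", "CA", 1.52, 113.0, ("chi", 2, 0.0)),
          ("OE1", "CD", "CG", "CB", 1.25, 119.0, ("chi", 3, 0.0)),
          ("OE2", "CD", "CG", "CB", 1.25, 119.0, ("chi", 3, 180.0))],
    "Q": [("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1, 0.0)),
          ("CD", "CG", "CB", "CA", 1.52, 113.0, ("chi", 2, 0.0)),
          ("OE1", "CD", "CG", "CB", 1.23, 120.8, ("chi", 3, 0.0)),
          ("NE2", "CD", "CG", "CB", 1.33, 116.4, ("chi", 3, 180.0))],
    "K": [("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1, 0.0)),
          ("CD", "CG", "CB", "CA", 1.52, 111.3, ("chi", 2, 0.0)),
          ("CE", "CD", "CG", "CB", 1.52, 111.3, ("chi", 3, 0.0)),
          ("NZ", "CE", "CD", "CG", 1.49, 111.2, ("chi", 4, 0.0))],
    "R": [("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1, 0.0)),
          ("CD", "CG", "CB", "CA", 1.52, 111.3, ("chi", 2, 0.0)),
          ("NE", "CD", "CG", "CB", 1.46, 112.0, ("chi", 3, 0.0)),
          ("CZ", "NE", "CD", "CG", 1.33, 124.2, ("chi", 4, 0.0)),
          ("NH1", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
          ("NH2", "CZ", "NE", "CD", 1.33, 120.0, 180.0)],
    "H": [("CG", "CB", "CA", "N", 1.49, 113.8, ("chi", 1, 0.0)),
          ("ND1", "CG", "CB", "CA", 1.38, 122.7, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.35, 131.0, ("chi", 2, 180.0)),
          ("CE1", "ND1", "CG", "CB", 1.32, 109.0, 180.0),
          ("NE2", "CD2", "CG", "CB", 1.37, 107.0, 180.0)],
}

N_CHI = {"A": 0, "G": 0, "S": 1, "C": 1, "T": 1, "V": 1, "P": 0,
         "L": 2, "I": 2, "F": 2, "Y": 2, "W": 2, "D": 2, "N": 2, "H": 2,
         "M": 3, "E": 3, "Q": 3, "K": 4, "R": 4}

ROTAMER_ANGLES = (-60.0, 60.0, 180.0)  # gauche-, gauche+, trans per chi


def _element_of(name: str) -> str:
    return name[0] if name[0] in ("N", "O", "S") else "C"


def sidechain_atoms(aa: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                    chis: tuple[float, ...] = ()) -> list[tuple[str, np.ndarray]]:
    """Ideal-geometry side-chain heavy atoms (CB onward) for one residue."""
    if aa == "G":
        return []
    out: list[tuple[str, np.ndarray]] = []
    pos = {"N": n, "CA": ca, "C": c}
    # CB off the backbone frame (L-configuration improper)
    cb = place_atom(ca, n, c, 1.53, 110.5, -122.5)
    pos["CB"] = cb
    out.append(("CB", cb))
    for name, r1, r2, r3, bond, ang, dih in (_SC[aa] or []):
        if isinstance(dih, tuple):
            _, k, offset = dih
            chi = chis[k - 1] if k - 1 < len(chis) else 180.0
            dval = chi + offset
        else:
            dval = dih
        p = place_atom(pos[r1], pos[r2], pos[r3], bond, ang, dval)
        pos[name] = p
        out.append((name, p))
    return out


def build_residue(aa: str, chain_id: str, seq_pos: int,
                  n: np.ndarray, ca: np.ndarray, c: np.ndarray, o: np.ndarray,
                  chis: tuple[float, ...] = ()) -> Residue:
    res = Residue(aa, chain_id, seq_pos)
    res.atoms.append(Atom("N", "N", n))
    res.atoms.append(Atom("CA", "C", ca))
    res.atoms.append(Atom("C", "C", c))
    res.atoms.append(Atom("O", "O", o))
    for name, p in sidechain_atoms(aa, n, ca, c, chis):
        res.atoms.append(Atom(name, _element_of(name), p))
    return res


def build_backbone(sequence: str, phi: float, psi: float,
                   omega: float = 180.0, chain_id: str = "C",
                   chis: tuple[float, ...] = (180.0,) * 4) -> list[Residue]:
    """Chain with ideal backbone geometry at uniform (phi, psi)."""
    n_res = len(sequence)
    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([1.458, 0.0, 0.0])
    C[0] = CA[0] + 1.525 * np.array([math.cos(math.radians(180 - 111.2)),
                                     math.sin(math.radians(180 - 111.2)), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(C[i - 1], CA[i - 1], N[i - 1], 1.329, 116.2, psi)
        CA[i] = place_atom(N[i], C[i - 1], CA[i - 1], 1.458, 121.7, omega)
        C[i] = place_atom(CA[i], N[i], C[i - 1], 1.525, 111.2, phi)
    residues = []
    for i, aa in enumerate(sequence):
        if i + 1 < n_res:
            o = place_atom(C[i], CA[i], N[i + 1], 1.231, 120.5, 180.0)
        else:
            o = place_atom(C[i], CA[i], N[i], 1.231, 120.5, psi + 180.0)
        residues.append(build_residue(aa, chain_id, i + 1,
                                      N[i], CA[i], C[i], o, chis))
    return residues


# ---------------------------------------------------------------------------
# threading


def thread(template: Complex, sequence: str) -> Complex:
    """Thread a nonamer onto the template peptide backbone.

    Backbone coordinates are untouched; positions whose amino acid changes
    get an ideal-geometry side chain in the default all-trans rotamer;
    unchanged positions keep the template side chains.  Groove chains are
    never modified.
    """
    if len(sequence) != 9:
        raise EncodingError(f"peptide must be a nonamer, got length {len(sequence)}")
    sequence = sequence.upper()
    bad = set(sequence) - set(AA_ALPHABET)
    if bad:
        raise EncodingError(f"invalid amino-acid letter(s): {sorted(bad)}")
    if template.peptide_chain_id is None:
        raise ConfigError("template has no designated peptide chain")
    if len(template.peptide.residues) != 9:
        raise ConfigError("template peptide must have 9 residues")
    cx = template.copy()
    pep = cx.peptide
    for res, new_aa in zip(pep.residues, sequence):
        if res.aa == new_aa:
            continue
        n = res.atom("N").position
        ca = res.atom("CA").position
        c = res.atom("C").position
        o = res.atom("O").position
        rebuilt = build_residue(new_aa, res.chain_id, res.seq_pos, n, ca, c, o,
                                chis=(180.0,) * 4)
        res.aa = new_aa
        res.atoms = rebuilt.atoms
    return cx


# ---------------------------------------------------------------------------
# refinement

@dataclass
class RefinementConfig:
    cycles: int = 50
    decoys: int = 10
    keep_lowest: int = 3
    seed: int = 0
    temp_start: float = 2.0       # reduced temperature at cycle 0
    temp_end: float = 0.2         # reduced temperature at the last cycle
    backbone_step: float = 8.0    # max crankshaft rotation, degrees
    contact_cutoff: float = 4.5   # groove residues within this of the peptide move

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ConfigError("cycles must be >= 1")
        if not (1 <= self.keep_lowest <= self.decoys):
            raise ConfigError("need 1 <= keep_lowest <= decoys")


@dataclass
class DecoyEnsemble:
    decoys: list[tuple[Complex, EnergyBreakdown, int]]
    template_id: str = ""

    def sorted_by_total(self):
        return sorted(self.decoys, key=lambda t: t[1].total)


def _movable_residues(table: AtomTable, cutoff: float) -> list[int]:
    pep_atoms = np.where(table.atom_is_peptide)[0]
    pep_res = [r for r in range(table.n_res) if table.res_is_peptide[r]]
    movable = set(pep_res)
    if len(pep_atoms):
        pc = table.coords[pep_atoms]
        for r in range(table.n_res):
            if table.res_is_peptide[r] or N_CHI[table.res_aa[r]] == 0:
                continue
            ai = table.res_atoms[r]
            d = np.linalg.norm(table.coords[ai][:, None, :] - pc[None, :, :],
                               axis=2)
            if d.min() < cutoff:
                movable.add(r)
    return sorted(movable)


def _try_sidechain_move(table: AtomTable, r: int, rng) -> tuple | None:
    """Propose new side-chain coordinates for residue r; None if immovable."""
    aa = table.res_aa[r]
    nchi = N_CHI[aa]
    if nchi == 0:
        return None
    n_i = table._res_atom(r, "N")
    ca_i = table._res_atom(r, "CA")
    c_i = table._res_atom(r, "C")
    if None in (n_i, ca_i, c_i):
        return None
    chis = tuple(rng.choice(ROTAMER_ANGLES) + rng.uniform(-15.0, 15.0)
                 for _ in range(nchi))
    new = sidechain_atoms(aa, table.coords[n_i], table.coords[ca_i],
                          table.coords[c_i], chis)
    idxs, coords = [], []
    for name, p in new:
        k = table._res_atom(r, name)
        if k is None:
            return None  # topology mismatch (shouldn't happen post-thread)
        idxs.append(k)
        coords.append(p)
    return np.array(idxs), np.array(coords)


def _crankshaft(table: AtomTable, pep_res: list[int], max_deg: float, rng):
    """Rigid rotation of the segment between two peptide CA pivots."""
    if len(pep_res) < 3:
        return None
    i, j = sorted(rng.choice(len(pep_res), size=2, replace=False))
    if j - i < 1:
        return None
    ri, rj = pep_res[i], pep_res[j]
    ca_i = table._res_atom(ri, "CA")
    ca_j = table._res_atom(rj, "CA")
    if ca_i is None or ca_j is None:
        return None
    moved: list[int] = []
    for k in table.res_atoms[ri]:
        if table.names[k] in ("C", "O"):
            moved.append(k)
    for r in pep_res[i + 1:j]:
        moved.extend(table.res_atoms[r])
    nk = table._res_atom(rj, "N")
    if nk is not None:
        moved.append(nk)
    axis = table.coords[ca_j] - table.coords[ca_i]
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        return None
    axis = axis / norm
    ang = math.radians(rng.uniform(-max_deg, max_deg))
    k_ = axis
    moved = np.array(moved, dtype=int)
    v = table.coords[moved] - table.coords[ca_i]
    # Rodrigues rotation about the pivot axis
    rot = (v * math.cos(ang)
           + np.cross(np.broadcast_to(k_, v.shape), v) * math.sin(ang)
           + np.outer(v @ k_, k_) * (1.0 - math.cos(ang)))
    return moved, table.coords[ca_i] + rot, list(range(ri, rj + 1))


def refine(model: Complex, config: RefinementConfig,
           registry: TermRegistry | None = None) -> DecoyEnsemble:
    """Metropolis simulated annealing; deterministic given config.seed.

    Each decoy runs ``cycles`` sweeps.  A sweep proposes one rotamer swap
    per movable residue (all peptide residues plus groove residues
    contacting the peptide) and one peptide-backbone crankshaft move,
    accepting by the Metropolis criterion at a geometrically cooled
    temperature.  The best-visited conformation of each trajectory is kept.
    """
    registry = registry or default_registry()
    decoys = []
    for d in range(config.decoys):
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, d])
        cx = model.copy()
        table = AtomTable(cx)
        movable = _movable_residues(table, config.contact_cutoff)
        pep_res = [r for r in range(table.n_res) if table.res_is_peptide[r]]
        e_total = table.score(registry).total
        best_e = e_total
        best_coords = table.coords.copy()
        for cycle in range(config.cycles):
            frac = cycle / max(config.cycles - 1, 1)
            temp = config.temp_start * (config.temp_end / config.temp_start) ** frac
            order = rng.permutation(len(movable))
            for oi in order:
                r = movable[oi]
                prop = _try_sidechain_move(table, r, rng)
                if prop is None:
                    continue
                idxs, new_coords = prop
                e_before = table.local_energy([r], registry)
                old = table.coords[idxs].copy()
                table.coords[idxs] = new_coords
                delta = table.local_energy([r], registry) - e_before
                if delta <= 0 or (temp > 0
                                  and rng.uniform() < math.exp(-min(delta / temp, 50.0))):
                    e_total += delta
                    if e_total < best_e:
                        best_e = e_total
                        best_coords = table.coords.copy()
                else:
                    table.coords[idxs] = old
            bb = _crankshaft(table, pep_res, config.backbone_step, rng)
            if bb is not None:
                idxs, new_coords, touched = bb
                e_before = table.local_energy(touched, registry)
                old = table.coords[idxs].copy()
                table.coords[idxs] = new_coords
                delta = table.local_energy(touched, registry) - e_before
                if delta <= 0 or (temp > 0
                                  and rng.uniform() < math.exp(-min(delta / temp, 50.0))):
                    e_total += delta
                    if e_total < best_e:
                        best_e = e_total
                        best_coords = table.coords.copy()
                else:
                    table.coords[idxs] = old
        table.coords[:] = best_coords
        table.sync_to_complex(cx)
        breakdown = table.score(registry)
        decoys.append((cx, breakdown, d))
    return DecoyEnsemble(decoys=decoys, template_id=model.template_id)


def consensus_features(ensemble: DecoyEnsemble, keep_lowest: int = 3,
                       registry: TermRegistry | None = None,
                       probe_radius: float = 1.4,
                       n_points: int = 960) -> tuple[EnergyBreakdown, SasaResult]:
    """Average unweighted terms, per-residue terms and SASA over the
    ``keep_lowest`` lowest-total decoys."""
    registry = registry or default_registry()
    if keep_lowest > len(ensemble.decoys):
        raise ConfigError(f"keep_lowest={keep_lowest} exceeds ensemble size "
                          f"{len(ensemble.decoys)}")
    kept = ensemble.sorted_by_total()[:keep_lowest]
    unweighted = {t: float(np.mean([bd.unweighted.get(t, 0.0)
                                    for _, bd, _ in kept]))
                  for t in registry.complex_terms}
    keys = set()
    for _, bd, _ in kept:
        keys.update(bd.per_residue)
    per_residue = {k: float(np.mean([bd.per_residue.get(k, 0.0)
                                     for _, bd, _ in kept]))
                   for k in keys}
    avg_bd = EnergyBreakdown(unweighted=unweighted,
                             per_residue=per_residue).finalize(registry)

    sasas = [sasa(cx, probe_radius=probe_radius, n_points=n_points)
             for cx, _, _ in kept]
    per_atom = np.mean([s.per_atom for s in sasas], axis=0)
    avg_sasa = SasaResult(per_atom=per_atom)
    positions = sasas[0].per_residue_total.keys()
    for pos in positions:
        avg_sasa.per_residue_total[pos] = float(
            np.mean([s.per_residue_total[pos] for s in sasas]))
        avg_sasa.per_residue_hydrophobic[pos] = float(
            np.mean([s.per_residue_hydrophobic[pos] for s in sasas]))
    avg_sasa.peptide_total = sum(avg_sasa.per_residue_total.values())
    avg_sasa.peptide_hydrophobic = sum(avg_sasa.per_residue_hydrophobic.values())
    return avg_bd, avg_sasa
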