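"""Term-decomposed energy scoring of peptide/MHC complexes.

The scoring contract is an :class:`EnergyBreakdown` over a configurable
:class:`TermRegistry` of 18 whole-complex terms plus 9 atomic-level
per-residue terms.  The built-in "desk" backend implements the classic
all-atom term taxonomy with standard, heavy-atom-parameterized functional
forms:

* 12-6 Lennard-Jones split into attractive (``fa_atr``) and repulsive
  (``fa_rep``) parts with a 6 A cutoff and smooth switching,
* Coulomb electrostatics with a distance-dependent dielectric (``fa_elec``),
* Gaussian-exclusion implicit solvation with per-atom-type transfer free
  energies (``fa_sol`` / ``fa_intra_sol``); hydrophobic atom types carry
  negative transfer free energies, so burying them is favorable,
* geometric donor/acceptor hydrogen bonds over heavy atoms, split into the
  four backbone/side-chain classes,
* cosine-series backbone and side-chain torsion preferences (``rama``,
  ``omega``, ``fa_dun``, ``p_aa_pp``),
* per-residue reference energies (``ref``) and the ``pro_close`` /
  ``dslf_fa13`` / ``yhh_planarity`` specialty terms.

Lower totals are more favorable.  The backend is approximate by design: it
preserves the semantics each term feeds into the downstream feature vector
without reproducing any external program's numbers.  Externally computed
term tables can be injected through :func:`load_breakdown_tsv`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, ScoringError
from .structmodel import BACKBONE_ATOMS, Complex

# ---------------------------------------------------------------------------
# registry

DEFAULT_COMPLEX_TERMS: list[tuple[str, float]] = [
    ("fa_atr", 1.0),
    ("fa_rep", 0.55),
    ("fa_sol", 0.9375),
    ("fa_intra_rep", 0.005),
    ("fa_intra_sol", 1.0),
    ("fa_elec", 0.875),
    ("pro_close", 1.25),
    ("hbond_sr_bb", 1.17),
    ("hbond_lr_bb", 1.17),
    ("hbond_bb_sc", 1.17),
    ("hbond_sc", 1.1),
    ("dslf_fa13", 1.25),
    ("rama", 0.25),
    ("omega", 0.625),
    ("fa_dun", 0.7),
    ("p_aa_pp", 0.4),
    ("yhh_planarity", 0.625),
    ("ref", 1.0),
]

# atomic-level terms decomposable onto individual peptide positions,
# excluding amino-acid-specific terms (reference energies, rotamer priors,
# planarity and the like)
DEFAULT_RESIDUE_TERMS: list[str] = [
    "fa_atr", "fa_rep", "fa_sol", "fa_intra_rep", "fa_elec",
    "hbond_sr_bb", "hbond_lr_bb", "hbond_bb_sc", "hbond_sc",
]


@dataclass
class TermRegistry:
    """Ordered complex-level terms with weights, plus per-residue terms."""

    complex_terms: list[str]
    weights: dict[str, float]
    residue_terms: list[str]

    def __post_init__(self) -> None:
        if len(set(self.complex_terms)) != len(self.complex_terms):
            raise ConfigError("duplicate complex term names")
        if len(set(self.residue_terms)) != len(self.residue_terms):
            raise ConfigError("duplicate residue term names")
        for t in self.complex_terms:
            w = self.weights.get(t)
            if w is None or not np.isfinite(w):
                raise ConfigError(f"term {t!r} lacks a finite weight")


def default_registry() -> TermRegistry:
    return TermRegistry(
        complex_terms=[t for t, _ in DEFAULT_COMPLEX_TERMS],
        weights=dict(DEFAULT_COMPLEX_TERMS),
        residue_terms=list(DEFAULT_RESIDUE_TERMS),
    )


def load_registry(path) -> TermRegistry:
    """Read a registry from TSV: columns term, weight, per_residue (0/1)."""
    names, weights, res_terms = [], {}, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("term"):
                continue
            parts = line.split("\t")
            names.append(parts[0])
            weights[parts[0]] = float(parts[1])
            if len(parts) > 2 and parts[2].strip() == "1":
                res_terms.append(parts[0])
    return TermRegistry(names, weights, res_terms)


def list_terms(registry: TermRegistry) -> list[str]:
    """Stable complex-term ordering used for feature-vector layout."""
    return list(registry.complex_terms)


@dataclass
class EnergyBreakdown:
    """Unweighted per-term values, per-peptide-position values, weighted total."""

    unweighted: dict[str, float]
    per_residue: dict[tuple[int, str], float] = field(default_factory=dict)
    total: float = 0.0

    def finalize(self, registry: TermRegistry) -> "EnergyBreakdown":
        self.total = float(sum(registry.weights[t] * self.unweighted.get(t, 0.0)
                               for t in registry.complex_terms))
        return self


# ---------------------------------------------------------------------------
# parameters

_ELEMENT_PARAMS: dict[str, tuple[float, float, float]] | None = None


def _element_params() -> dict[str, tuple[float, float, float]]:
    global _ELEMENT_PARAMS
    if _ELEMENT_PARAMS is None:
        table = {}
        ref = importlib.resources.files("structimm.data") / "atom_params.tsv"
        for line in ref.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("atom_type"):
                continue
            el, radius, eps, dg, _q = line.split("\t")
            table[el] = (float(radius), float(eps), float(dg))
        _ELEMENT_PARAMS = table
    return _ELEMENT_PARAMS


# partial charges by (aa, atom name); backbone entries keyed with aa="*"
_CHARGES: dict[tuple[str, str], float] = {
    ("*", "N"): -0.30, ("*", "O"): -0.40, ("*", "C"): 0.40,
    ("*", "CA"): 0.10, ("*", "OXT"): -0.50,
    ("D", "OD1"): -0.50, ("D", "OD2"): -0.50, ("D", "CG"): 0.30,
    ("E", "OE1"): -0.50, ("E", "OE2"): -0.50, ("E", "CD"): 0.30,
    ("K", "NZ"): 0.80, ("R", "NE"): 0.10, ("R", "CZ"): 0.30,
    ("R", "NH1"): 0.30, ("R", "NH2"): 0.30,
    ("H", "ND1"): -0.20, ("H", "NE2"): -0.20,
    ("N", "OD1"): -0.40, ("N", "ND2"): 0.40, ("N", "CG"): 0.30,
    ("Q", "OE1"): -0.40, ("Q", "NE2"): 0.40, ("Q", "CD"): 0.30,
    ("S", "OG"): -0.30, ("T", "OG1"): -0.30, ("Y", "OH"): -0.30,
    ("C", "SG"): -0.10, ("M", "SD"): -0.10, ("W", "NE1"): -0.10,
}

# per-residue reference energies (amino-acid chemical potential offsets)
_REF_ENERGY = {
    "A": 0.16, "R": -0.70, "N": -0.89, "D": -0.67, "C": 1.70,
    "Q": -0.97, "E": -0.81, "G": -0.17, "H": 0.56, "I": 0.24,
    "L": -0.10, "K": -0.65, "M": -0.34, "F": 0.63, "P": -0.02,
    "S": -0.37, "T": -0.27, "W": 0.91, "Y": 0.51, "V": 0.29,
}

_DONORS = {
    ("*", "N"), ("S", "OG"), ("T", "OG1"), ("Y", "OH"), ("K", "NZ"),
    ("R", "NE"), ("R", "NH1"), ("R", "NH2"), ("H", "ND1"), ("H", "NE2"),
    ("N", "ND2"), ("Q", "NE2"), ("W", "NE1"),
}
_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"), ("D", "OD1"), ("D", "OD2"), ("E", "OE1"),
    ("E", "OE2"), ("N", "OD1"), ("Q", "OE1"), ("S", "OG"), ("T", "OG1"),
    ("Y", "OH"), ("H", "ND1"), ("H", "NE2"),
}

PAIR_CUTOFF = 6.0        # A, nonbonded interaction cutoff
_SWITCH_START = 5.0      # A, start of the smooth switch to zero
_SOL_LAMBDA = 3.5        # A, Gaussian-exclusion correlation length
_DIELECTRIC = 10.0       # distance-dependent dielectric prefactor
_COULOMB = 332.0637      # kcal*A/(mol*e^2)
_HB_R0, _HB_SIGMA, _HB_DEPTH = 2.9, 0.35, 1.5


# ---------------------------------------------------------------------------
# atom table: flat numpy view of a Complex, reused by the Monte-Carlo refiner

class AtomTable:
    """Flat array view of a complex with bonded-exclusion bookkeeping."""

    def __init__(self, cx: Complex):
        coords, names, elements, aas = [], [], [], []
        res_index, is_bb = [], []
        self.res_chain: list[str] = []
        self.res_pos: list[int] = []
        self.res_aa: list[str] = []
        self.res_atoms: list[list[int]] = []
        self.res_is_peptide: list[bool] = []
        self.res_pep_pos: list[int] = []    # 1..9 for peptide residues else 0
        pep_id = cx.peptide_chain_id
        k = 0
        for chain in cx.chains:
            for ri, res in enumerate(chain.residues):
                if not res.atoms:
                    continue
                idxs = []
                for a in res.atoms:
                    coords.append(a.position)
                    names.append(a.name)
                    elements.append(a.element)
                    aas.append(res.aa)
                    res_index.append(len(self.res_aa))
                    is_bb.append(a.name in BACKBONE_ATOMS or a.name == "OXT")
                    idxs.append(k)
                    k += 1
                self.res_chain.append(chain.chain_id)
                self.res_pos.append(res.seq_pos)
                self.res_aa.append(res.aa)
                self.res_atoms.append(idxs)
                pep = chain.chain_id == pep_id
                self.res_is_peptide.append(pep)
                self.res_pep_pos.append(ri + 1 if pep else 0)
        if k == 0:
            raise ScoringError("cannot score an empty complex")
        self.coords = np.array(coords, dtype=float)
        self.names = names
        self.elements = elements
        self.aas = aas
        self.res_index = np.array(res_index, dtype=int)
        self.is_bb = np.array(is_bb, dtype=bool)
        self.n = k
        self.n_res = len(self.res_aa)
        self.atom_is_peptide = np.array(
            [self.res_is_peptide[r] for r in self.res_index], dtype=bool)

        params = _element_params()
        rad, eps, dg, chg = [], [], [], []
        self.is_donor = np.zeros(k, dtype=bool)
        self.is_acceptor = np.zeros(k, dtype=bool)
        for i in range(k):
            el = elements[i][0].upper()
            if el not in params:
                el = "C"  # element-default fallback
            r_, e_, d_ = params[el]
            rad.append(r_)
            eps.append(e_)
            dg.append(d_)
            aa, nm = aas[i], names[i]
            chg.append(_CHARGES.get((aa, nm), _CHARGES.get(("*", nm), 0.0)))
            if ((aa, nm) in _DONORS or (("*", nm) in _DONORS and aa != "P")):
                self.is_donor[i] = True
            if (aa, nm) in _ACCEPTORS or ("*", nm) in _ACCEPTORS:
                self.is_acceptor[i] = True
        self.radius = np.array(rad)
        self.eps = np.array(eps)
        self.dg = np.array(dg)
        self.charge = np.array(chg)
        self.vol = (self.radius / 1.7) ** 3   # normalized occluding volume
        self.is_sg = np.array([nm == "SG" for nm in names], dtype=bool)
        chain_codes = {c: ci for ci, c in enumerate(dict.fromkeys(self.res_chain))}
        self.res_chain_code = np.array([chain_codes[c] for c in self.res_chain])
        self.res_pos_arr = np.array(self.res_pos, dtype=int)

        self._build_bond_graph()

    # -- topology ----------------------------------------------------------
    def _build_bond_graph(self) -> None:
        """Covalent topology: intra-residue bonds by distance at build time,
        inter-residue bonds only through the peptide C(i)-N(i+1) link.

        Restricting inter-residue bonds to the backbone link keeps clashing
        nonbonded atoms (which can approach covalent distances in unrefined
        models) visible to the repulsive term.
        """
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for r in range(self.n_res):
            idxs = self.res_atoms[r]
            for a_i, i in enumerate(idxs):
                for j in idxs[a_i + 1:]:
                    has_s = self.elements[i][0] == "S" or self.elements[j][0] == "S"
                    cut = 2.15 if has_s else 1.80
                    if np.linalg.norm(self.coords[i] - self.coords[j]) <= cut:
                        adj[i].append(j)
                        adj[j].append(i)
        for r in range(self.n_res - 1):
            if self.res_chain[r] != self.res_chain[r + 1]:
                continue
            c = self._res_atom(r, "C")
            n = self._res_atom(r + 1, "N")
            if c is not None and n is not None and \
                    np.linalg.norm(self.coords[c] - self.coords[n]) < 2.0:
                adj[c].append(n)
                adj[n].append(c)
        self.adj = adj
        # acceptor base = first bonded heavy atom (for H-bond geometry)
        self.base = np.full(self.n, -1, dtype=int)
        for i in range(self.n):
            if self.is_acceptor[i] and adj[i]:
                self.base[i] = adj[i][0]
        # exclude pairs separated by <= 3 bonds from nonbonded terms
        excl = set()
        for s in range(self.n):
            frontier = {s}
            seen = {s}
            for _depth in range(3):
                nxt = set()
                for u in frontier:
                    for v in self.adj[u]:
                        if v not in seen:
                            seen.add(v)
                            nxt.add(v)
                frontier = nxt
            for v in seen:
                if v > s:
                    excl.add(s * self.n + v)
        self._excl_codes = np.fromiter(excl, dtype=np.int64, count=len(excl))
        self._excl_codes.sort()

    def _not_excluded(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        if len(self._excl_codes) == 0:
            return np.ones(len(i), dtype=bool)
        lo = np.minimum(i, j).astype(np.int64)
        hi = np.maximum(i, j).astype(np.int64)
        codes = lo * self.n + hi
        pos = np.searchsorted(self._excl_codes, codes)
        hit = (pos < len(self._excl_codes)) & \
              (self._excl_codes[np.clip(pos, 0, max(len(self._excl_codes) - 1, 0))] == codes)
        return ~hit

    # -- pair terms --------------------------------------------------------
    def _pair_values(self, i: np.ndarray, j: np.ndarray, d: np.ndarray):
        """Per-pair unweighted values for the nonbonded terms.

        Returns dict term -> array aligned with (i, j).  Pairwise terms are
        symmetric in atom order by construction.
        """
        out: dict[str, np.ndarray] = {}
        t = np.clip((PAIR_CUTOFF - d) / (PAIR_CUTOFF - _SWITCH_START), 0.0, 1.0)
        sw = t * t * (3.0 - 2.0 * t)

        rmin = self.radius[i] + self.radius[j]
        eps = np.sqrt(self.eps[i] * self.eps[j])
        x6 = (rmin / np.maximum(d, 0.3)) ** 6
        lj = eps * (x6 * x6 - 2.0 * x6)
        inside = d < rmin
        atr = np.where(inside, -eps, lj) * sw
        rep = np.where(inside, lj + eps, 0.0)
        same_res = self.res_index[i] == self.res_index[j]
        out["fa_atr"] = np.where(same_res, 0.0, atr)
        out["fa_rep"] = np.where(same_res, 0.0, rep)
        out["fa_intra_rep"] = np.where(same_res, rep, 0.0)

        gauss = np.exp(-(d / _SOL_LAMBDA) ** 2)
        sol = (self.dg[i] * self.vol[j] + self.dg[j] * self.vol[i]) * gauss * sw
        out["fa_sol"] = np.where(same_res, 0.0, sol)
        out["fa_intra_sol"] = np.where(same_res, sol, 0.0)

        qq = self.charge[i] * self.charge[j]
        elec = _COULOMB * qq / (_DIELECTRIC * np.maximum(d, 1.0) ** 2) * sw
        out["fa_elec"] = np.where(same_res, 0.0, elec)

        # hydrogen bonds: donor/acceptor heavy-atom geometry
        for term in ("hbond_sr_bb", "hbond_lr_bb", "hbond_bb_sc", "hbond_sc"):
            out[term] = np.zeros(len(d))
        da = (self.is_donor[i] & self.is_acceptor[j])
        ad = (self.is_acceptor[i] & self.is_donor[j])
        cand = (da | ad) & ~same_res & (d < 3.4) & (d > 2.4)
        if np.any(cand):
            ci = np.where(cand)[0]
            don = np.where(da[ci], i[ci], j[ci])
            acc = np.where(da[ci], j[ci], i[ci])
            base = self.base[acc]
            ok = base >= 0
            ci, don, acc, base = ci[ok], don[ok], acc[ok], base[ok]
            v1 = self.coords[base] - self.coords[acc]
            v2 = self.coords[don] - self.coords[acc]
            cosang = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1) + 1e-12)
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            w_ang = np.maximum(0.0, np.cos(np.radians(ang - 120.0)))
            e_hb = -_HB_DEPTH * np.exp(-((d[ci] - _HB_R0) / _HB_SIGMA) ** 2) * w_ang
            bb_d = self.is_bb[don]
            bb_a = self.is_bb[acc]
            rd, ra = self.res_index[don], self.res_index[acc]
            same_chain = self.res_chain_code[rd] == self.res_chain_code[ra]
            seqsep = np.abs(self.res_pos_arr[rd] - self.res_pos_arr[ra])
            cls_bb = bb_d & bb_a
            sr = cls_bb & same_chain & (seqsep <= 4)
            lr = cls_bb & ~sr
            mixed = bb_d ^ bb_a
            sc = ~bb_d & ~bb_a
            for term, mask in (("hbond_sr_bb", sr), ("hbond_lr_bb", lr),
                               ("hbond_bb_sc", mixed), ("hbond_sc", sc)):
                arr = out[term]
                np.add.at(arr, ci[mask], e_hb[mask])

        # disulfide: S-S contact
        out["dslf_fa13"] = np.where(
            self.is_sg[i] & self.is_sg[j] & (d < 2.5), -0.5, 0.0)
        return out

    # -- one-body terms ----------------------------------------------------
    def _dihedral(self, p0, p1, p2, p3) -> float:
        b0 = p1 - p0
        b1 = p2 - p1
        b2 = p3 - p2
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        m1 = np.cross(n1, b1 / (np.linalg.norm(b1) + 1e-12))
        x = np.dot(n1, n2)
        y = np.dot(m1, n2)
        return float(np.degrees(np.arctan2(y, x)))

    def _res_atom(self, r: int, name: str) -> int | None:
        for k in self.res_atoms[r]:
            if self.names[k] == name:
                return k
        return None

    def _bonded_residues(self, r1: int, r2: int) -> bool:
        """True if r2 follows r1 via an intact peptide bond."""
        if self.res_chain[r1] != self.res_chain[r2]:
            return False
        c = self._res_atom(r1, "C")
        n = self._res_atom(r2, "N")
        if c is None or n is None:
            return False
        return bool(np.linalg.norm(self.coords[c] - self.coords[n]) < 2.0)

    def one_body_terms(self, r: int) -> dict[str, float]:
        """Torsion preferences, reference energy, pro_close for residue r."""
        out = {"rama": 0.0, "omega": 0.0, "fa_dun": 0.0, "p_aa_pp": 0.0,
               "ref": _REF_ENERGY[self.res_aa[r]], "pro_close": 0.0,
               "yhh_planarity": 0.0}
        co = self.coords
        n_i = self._res_atom(r, "N")
        ca_i = self._res_atom(r, "CA")
        c_i = self._res_atom(r, "C")
        prev = r - 1 if r > 0 and self._bonded_residues(r - 1, r) else None
        nxt = r + 1 if r + 1 < self.n_res and self._bonded_residues(r, r + 1) else None
        phi = psi = None
        if prev is not None and None not in (n_i, ca_i, c_i):
            c_prev = self._res_atom(prev, "C")
            if c_prev is not None:
                phi = self._dihedral(co[c_prev], co[n_i], co[ca_i], co[c_i])
        if nxt is not None and None not in (n_i, ca_i, c_i):
            n_next = self._res_atom(nxt, "N")
            if n_next is not None:
                psi = self._dihedral(co[n_i], co[ca_i], co[c_i], co[n_next])
        if phi is not None:
            out["rama"] += 0.3 * (1.0 - np.cos(np.radians(phi + 100.0)))
            out["p_aa_pp"] += 0.05 * ((ord(self.res_aa[r]) - 65) / 25.0) \
                * (1.0 - np.cos(np.radians(phi + 100.0)))
        if psi is not None:
            out["rama"] += 0.3 * (1.0 - np.cos(np.radians(psi - 120.0)))
        if nxt is not None and None not in (ca_i, c_i):
            n_next = self._res_atom(nxt, "N")
            ca_next = self._res_atom(nxt, "CA")
            if n_next is not None and ca_next is not None:
                om = self._dihedral(co[ca_i], co[c_i], co[n_next], co[ca_next])
                out["omega"] += 0.5 * (1.0 - np.cos(2.0 * np.radians(om)))
        # side-chain torsion preference (chi1/chi2 staggering)
        cb = self._res_atom(r, "CB")
        if cb is not None and None not in (n_i, ca_i):
            g = None
            for nm in ("CG", "CG1", "OG", "OG1", "SG"):
                g = self._res_atom(r, nm)
                if g is not None:
                    break
            if g is not None:
                chi1 = self._dihedral(co[n_i], co[ca_i], co[cb], co[g])
                out["fa_dun"] += 0.2 * (1.0 + np.cos(3.0 * np.radians(chi1)))
                d_at = None
                for nm in ("CD", "CD1", "SD", "OD1", "ND1", "NE"):
                    d_at = self._res_atom(r, nm)
                    if d_at is not None:
                        break
                if d_at is not None:
                    chi2 = self._dihedral(co[ca_i], co[cb], co[g], co[d_at])
                    out["fa_dun"] += 0.1 * (1.0 + np.cos(3.0 * np.radians(chi2)))
        if self.res_aa[r] == "P":
            cd = self._res_atom(r, "CD")
            if cd is not None and n_i is not None:
                d = np.linalg.norm(co[cd] - co[n_i])
                out["pro_close"] += 2.0 * (d - 1.47) ** 2
        return out

    # -- aggregation -------------------------------------------------------
    def _nonbonded_pairs(self):
        tree = cKDTree(self.coords)
        pairs = tree.query_pairs(PAIR_CUTOFF, output_type="ndarray")
        if len(pairs) == 0:
            return (np.empty(0, dtype=int),) * 2 + (np.empty(0),)
        i, j = pairs[:, 0], pairs[:, 1]
        keep = self._not_excluded(i, j)
        i, j = i[keep], j[keep]
        d = np.linalg.norm(self.coords[i] - self.coords[j], axis=1)
        return i, j, d

    def score(self, registry: TermRegistry,
              peptide_only: bool = False) -> EnergyBreakdown:
        """Full breakdown; with *peptide_only*, keep only terms with a
        peptide participant (peptide-groove pairs fully attributed to the
        peptide; intra-peptide terms fully counted)."""
        if peptide_only and not any(self.res_is_peptide):
            raise ScoringError("no peptide residues to score")
        i, j, d = self._nonbonded_pairs()
        unweighted = {t: 0.0 for t in registry.complex_terms}
        per_res_all = {t: np.zeros(self.n_res) for t in registry.complex_terms}
        if len(i):
            pv = self._pair_values(i, j, d)
            pep_i = self.atom_is_peptide[i]
            pep_j = self.atom_is_peptide[j]
            if peptide_only:
                keep = pep_i | pep_j
            else:
                keep = np.ones(len(i), dtype=bool)
            ri = self.res_index[i]
            rj = self.res_index[j]
            for term, vals in pv.items():
                if term not in unweighted:
                    continue
                v = vals[keep]
                unweighted[term] += float(np.sum(v))
                acc = per_res_all[term]
                if peptide_only:
                    # attribute fully to the peptide residue; split if both
                    pi, pj = pep_i[keep], pep_j[keep]
                    both = pi & pj
                    np.add.at(acc, ri[keep][both], 0.5 * v[both])
                    np.add.at(acc, rj[keep][both], 0.5 * v[both])
                    only_i = pi & ~pj
                    np.add.at(acc, ri[keep][only_i], v[only_i])
                    only_j = pj & ~pi
                    np.add.at(acc, rj[keep][only_j], v[only_j])
                else:
                    np.add.at(acc, ri[keep], 0.5 * v)
                    np.add.at(acc, rj[keep], 0.5 * v)
        for r in range(self.n_res):
            if peptide_only and not self.res_is_peptide[r]:
                continue
            for term, val in self.one_body_terms(r).items():
                if term in unweighted:
                    unweighted[term] += val
                    per_res_all[term][r] += val
        per_residue: dict[tuple[int, str], float] = {}
        expose = registry.complex_terms if peptide_only else registry.residue_terms
        for r in range(self.n_res):
            if not self.res_is_peptide[r]:
                continue
            pos = self.res_pep_pos[r]
            for term in expose:
                per_residue[(pos, term)] = float(per_res_all[term][r])
        bd = EnergyBreakdown(unweighted=unweighted, per_residue=per_residue)
        return bd.finalize(registry)

    # -- local energy for Monte-Carlo deltas -------------------------------
    def local_energy(self, moved_res: list[int], registry: TermRegistry) -> float:
        """Weighted energy of all terms touching the given residues.

        Includes every nonbonded pair with at least one atom in the moved
        residues and one-body terms of the moved residues plus their chain
        neighbors (whose phi/psi/omega involve moved atoms).  The difference
        of this quantity before and after a move equals the full-score
        difference, because untouched terms cancel.
        """
        moved_set = set(moved_res)
        atoms = np.array([a for r in moved_res for a in self.res_atoms[r]],
                         dtype=int)
        total = 0.0
        if len(atoms):
            diff = self.coords[atoms][:, None, :] - self.coords[None, :, :]
            dall = np.sqrt(np.sum(diff * diff, axis=2))
            ai, bj = np.where(dall < PAIR_CUTOFF)
            gi = atoms[ai]
            keep = gi != bj
            gi, bj = gi[keep], bj[keep]
            # drop duplicates when both endpoints are in the moved set
            both = np.isin(bj, atoms)
            dup = both & (gi > bj)
            gi, bj = gi[~dup], bj[~dup]
            keep = self._not_excluded(gi, bj)
            gi, bj = gi[keep], bj[keep]
            d = np.linalg.norm(self.coords[gi] - self.coords[bj], axis=1)
            pv = self._pair_values(gi, bj, d)
            for term in registry.complex_terms:
                if term in pv:
                    total += registry.weights[term] * float(np.sum(pv[term]))
        touched = set()
        for r in moved_set:
            touched.add(r)
            if r > 0:
                touched.add(r - 1)
            if r + 1 < self.n_res:
                touched.add(r + 1)
        for r in sorted(touched):
            for term, val in self.one_body_terms(r).items():
                if term in registry.weights:
                    total += registry.weights[term] * val
        return total

    def sync_to_complex(self, cx: Complex) -> None:
        """Copy table coordinates back into the Complex objects."""
        k = 0
        for chain in cx.chains:
            for res in chain.residues:
                for a in res.atoms:
                    a.position = self.coords[k].copy()
                    k += 1


# ---------------------------------------------------------------------------
# public scoring API

def score_complex(cx: Complex, registry: TermRegistry | None = None) -> EnergyBreakdown:
    """Score a whole complex with the desk backend (deterministic)."""
    registry = registry or default_registry()
    n_res = sum(1 for _ in cx.iter_residues())
    if n_res < 2:
        raise ScoringError(f"need >= 2 residues to score, got {n_res}")
    return AtomTable(cx).score(registry, peptide_only=False)


def score_peptide_in_groove(cx: Complex,
                            registry: TermRegistry | None = None) -> EnergyBreakdown:
    """Score only the peptide, in the context of the groove.

    Intra-peptide terms count fully; peptide-groove pair terms are fully
    attributed to the peptide.  Values can be positive: a strained peptide
    in a favorable groove is the expected regime.
    """
    registry = registry or default_registry()
    if cx.peptide_chain_id is None:
        raise ConfigError("no peptide chain designated")
    if not cx.peptide.residues:
        raise ScoringError("designated peptide chain is empty")
    return AtomTable(cx).score(registry, peptide_only=True)


def load_breakdown_tsv(path, registry: TermRegistry | None = None
                       ) -> dict[str, EnergyBreakdown]:
    """External-score import backend.

    TSV columns: model_id, term, value, position (optional, 1..9).  Rows
    without a position fill the complex-level breakdown; rows with one fill
    the per-residue map.  Lets users inject term tables computed with
    licensed modeling software in place of the desk backend.
    """
    registry = registry or default_registry()
    models: dict[str, EnergyBreakdown] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("model_id"):
                continue
            parts = line.split("\t")
            model_id, term, value = parts[0], parts[1], float(parts[2])
            bd = models.setdefault(model_id, EnergyBreakdown(
                unweighted={t: 0.0 for t in registry.complex_terms}))
            if len(parts) > 3 and parts[3].strip():
                bd.per_residue[(int(parts[3]), term)] = value
            else:
                if term not in bd.unweighted:
                    raise ConfigError(f"unknown term {term!r} in {path}")
                bd.unweighted[term] = value
    for bd in models.values():
        bd.finalize(registry)
    return models
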