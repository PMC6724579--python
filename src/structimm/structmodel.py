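"""Data model for peptide/MHC structures and PDB I/O.

A :class:`Complex` holds one or more chains; one chain may be designated as
the presented peptide (nonamers in the standard class I MHC setting).  The
PDB reader handles the ATOM-record subset the pipeline needs: fixed-column
coordinates, altloc resolution by occupancy, HETATM/water skipping.  No
hydrogens are read or generated anywhere in the package; every downstream
term is heavy-atom parameterized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, EmptyStructureError, ParseError

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Atom:
    """A heavy atom: PDB name, element, position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    temp_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.occupancy, self.temp_factor)


@dataclass
class Residue:
    """One amino-acid residue (one-letter code) with its heavy atoms."""

    aa: str
    chain_id: str
    seq_pos: int
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain_id}{self.seq_pos} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(self.aa, self.chain_id, self.seq_pos,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Complex:
    """A peptide/MHC structure: groove chain(s) plus a designated peptide."""

    chains: list[Chain]
    peptide_chain_id: str | None = None
    template_id: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    @property
    def peptide(self) -> Chain:
        if self.peptide_chain_id is None:
            raise ConfigError("no peptide chain designated")
        return self.chain(self.peptide_chain_id)

    def groove_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.chain_id != self.peptide_chain_id]

    def iter_residues(self):
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self):
        for r in self.iter_residues():
            yield from r.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.iter_atoms()], dtype=float)

    def peptide_sequence(self) -> str:
        return "".join(r.aa for r in self.peptide.residues)

    def copy(self) -> "Complex":
        return Complex([c.copy() for c in self.chains],
                       self.peptide_chain_id, self.template_id)

    def validate(self, nonamer: bool = True) -> None:
        if self.peptide_chain_id is not None:
            pep = self.peptide
            if nonamer and len(pep.residues) != 9:
                raise ConfigError(
                    f"peptide chain {self.peptide_chain_id} has "
                    f"{len(pep.residues)} residues, expected 9")
            if not self.groove_chains():
                raise ConfigError("complex has no groove (non-peptide) chain")


def read_pdb(path, peptide_chain: str | None = None,
             template_id: str | None = None) -> Complex:
    """Parse ATOM records into a :class:`Complex`.

    Altloc conflicts are resolved to the highest-occupancy copy (ties go to
    the first occurrence); HETATM records (waters, ions, ligands) are
    skipped; hydrogens are dropped.  If *peptide_chain* is given, that chain
    is designated as the peptide and renumbered 1..n.
    """
    chains: list[Chain] = []
    chain_map: dict[str, Chain] = {}
    res_map: dict[tuple[str, int, str], Residue] = {}
    # (chain, resseq, atom name) -> (occupancy, Atom) for altloc resolution
    seen: dict[tuple[str, int, str], float] = {}
    n_atom_records = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if not rec.startswith("ATOM"):
                continue
            n_atom_records += 1
            try:
                name = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:20].strip()
                chain_id = line[21].strip() or "A"
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_field = line[54:60].strip()
                occupancy = float(occ_field) if occ_field else 1.0
                bfac_field = line[60:66].strip()
                temp_factor = float(bfac_field) if bfac_field else 0.0
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: malformed ATOM record at line {lineno}: "
                                 f"{exc}") from exc
            element = line[76:78].strip() or name[:1]
            if element == "H" or name.startswith(("H", "1H", "2H", "3H")):
                continue
            if resname not in THREE_TO_ONE:
                continue  # nonstandard residue: out of scope, skip
            key = (chain_id, resseq, name)
            if altloc and key in seen:
                if occupancy <= seen[key]:
                    continue  # keep earlier, higher-occupancy copy
                # replace the previously stored atom in place
                res = res_map[(chain_id, resseq, resname)]
                for i, a in enumerate(res.atoms):
                    if a.name == name:
                        res.atoms[i] = Atom(name, element, (x, y, z),
                                            occupancy, temp_factor)
                        break
                seen[key] = occupancy
                continue
            seen[key] = occupancy
            if chain_id not in chain_map:
                chain_map[chain_id] = Chain(chain_id)
                chains.append(chain_map[chain_id])
            rkey = (chain_id, resseq, resname)
            if rkey not in res_map:
                res_map[rkey] = Residue(THREE_TO_ONE[resname], chain_id, resseq)
                chain_map[chain_id].residues.append(res_map[rkey])
            if res_map[rkey].has_atom(name):
                continue  # duplicate atom name without altloc: keep first
            res_map[rkey].atoms.append(
                Atom(name, element, (x, y, z), occupancy, temp_factor))

    if n_atom_records == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")
    cx = Complex(chains, peptide_chain_id=peptide_chain,
                 template_id=template_id or str(path))
    if peptide_chain is not None:
        try:
            pep = cx.chain(peptide_chain)
        except KeyError as exc:
            raise ConfigError(f"designated peptide chain {peptide_chain!r} "
                              f"not present in {path}") from exc
        for i, res in enumerate(pep.residues, start=1):
            res.seq_pos = i  # normalize to p1..pN regardless of author numbering
    return cx


def write_pdb(cx: Complex, path) -> None:
    """Write fixed-column ATOM records with TER between chains."""
    if cx.n_atoms() == 0:
        raise EmptyStructureError("refusing to write an empty complex")
    serial = 1
    lines: list[str] = []
    for chain in cx.chains:
        last = None
        for res in chain.residues:
            resname = ONE_TO_THREE[res.aa]
            for a in res.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {resname:>3s} "
                    f"{chain.chain_id:1s}{res.seq_pos:4d}    "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.temp_factor:6.2f}"
                    f"          {a.element:>2s}")
                serial += 1
            last = res
        if last is not None:
            lines.append(f"TER   {serial:5d}      {ONE_TO_THREE[last.aa]:>3s} "
                         f"{chain.chain_id:1s}{last.seq_pos:4d}")
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def extract_peptide(cx: Complex) -> list[Residue]:
    """Return the peptide residues in order p1..p9 (no copy, no mutation)."""
    if cx.peptide_chain_id is None:
        raise ConfigError("no peptide chain designated")
    return list(cx.peptide.residues)
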