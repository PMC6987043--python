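"""Chemical structure I/O and structure-cleaning rules.

Molecules enter the pipeline as SDF records or SMILES strings and are
standardized by one of nine "cleaning rules": the Cartesian product of a
protonation treatment (``none``, ``dominant`` form at pH 7, ``neutralize``)
and a coordinate-generation method (2D depiction, 3D rebuild by distance
geometry + force-field refinement, or a second independent 3D embedding
pathway standing in for an external 3D generator).

The protonation heuristics and both 3D pathways are open-source functional
analogs of the commercial tools normally used for this step; outputs carry an
``analog`` provenance flag so they are never mistaken for bit-compatible
reproductions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "SUPPORTED_ELEMENTS",
    "Molecule",
    "CleaningRule",
    "ACTIVITY_PROPERTY",
    "read_sdf",
    "write_sdf",
    "parse_smiles",
    "enumerate_cleaning_rules",
    "apply_cleaning_rule",
]

#: Elements accepted in input structures (organic subset plus halogens).
SUPPORTED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "Si", "Se"]
)

#: Default SDF property holding the qHTS activity score.
ACTIVITY_PROPERTY = "Pubchem_activity_score"

_PROTONATIONS = ("none", "dominant", "neutralize")
_COORDINATES = ("depict2d", "rebuild3d", "corina_analog")

# canonical short labels used in rule names
_PROT_LABEL = {"none": "none", "dominant": "domi", "neutralize": "neut"}
_COORD_LABEL = {"depict2d": "2D", "rebuild3d": "3D", "corina_analog": "Corina"}


@dataclass
class Molecule:
    """A small molecule with explicit atoms, bonds and 3D coordinates.

    Parameters
    ----------
    id : str
        Stable identifier (SDF title line or user-assigned).
    atoms : list of (symbol, x, y, z)
        Element symbol plus Cartesian coordinates in Angstrom.
    bonds : list of (i, j, order)
        Zero-based atom indices and integer bond order.
    charges : list of int, optional
        Formal charge per atom; defaults to all zero.
    activity_score : int or None
        qHTS activity score in [0, 100] when known.
    provenance : dict
        Free-form metadata (cleaning rule applied, analog flags, seed).
    """

    id: str
    atoms: list[tuple[str, float, float, float]]
    bonds: list[tuple[int, int, int]]
    charges: list[int] = field(default_factory=list)
    activity_score: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.charges:
            self.charges = [0] * len(self.atoms)
        if len(self.charges) != len(self.atoms):
            raise ValueError(f"molecule {self.id!r}: charges/atoms length mismatch")
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"molecule {self.id!r}: invalid bond ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"molecule {self.id!r}: duplicate bond {key}")
            seen.add(key)
        for sym, x, y, z in self.atoms:
            if sym not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {sym!r} in molecule {self.id!r}")
            for c in (x, y, z):
                if not _finite(c):
                    raise ValueError(f"molecule {self.id!r}: non-finite coordinate")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def coordinates(self):
        import numpy as np

        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)

    def net_charge(self) -> int:
        return sum(self.charges)

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        """Convert to an RDKit Mol (keeps coordinates as a conformer)."""
        rw = Chem.RWMol()
        for (sym, _x, _y, _z), q in zip(self.atoms, self.charges):
            a = Chem.Atom(sym)
            a.SetFormalCharge(int(q))
            rw.AddAtom(a)
        for i, j, order in self.bonds:
            rw.AddBond(int(i), int(j), _bond_type(order))
        mol = rw.GetMol()
        conf = Chem.Conformer(len(self.atoms))
        for idx, (_sym, x, y, z) in enumerate(self.atoms):
            conf.SetAtomPosition(idx, (float(x), float(y), float(z)))
        mol.AddConformer(conf)
        if sanitize:
            Chem.SanitizeMol(mol)
        mol.SetProp("_Name", self.id)
        return mol

    @classmethod
    def from_rdkit(
        cls,
        mol: Chem.Mol,
        mol_id: str | None = None,
        activity_score: int | None = None,
        provenance: dict | None = None,
    ) -> "Molecule":
        if mol_id is None:
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if mol.GetNumConformers() > 0:
            conf = mol.GetConformer()
            coords = [conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms())]
        else:
            coords = [(0.0, 0.0, 0.0)] * mol.GetNumAtoms()
        atoms = []
        charges = []
        for atom, p in zip(mol.GetAtoms(), coords):
            sym = atom.GetSymbol()
            if sym not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {sym!r} in molecule {mol_id!r}")
            atoms.append((sym, float(p[0]), float(p[1]), float(p[2])))
            charges.append(atom.GetFormalCharge())
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _order_int(b))
            for b in mol.GetBonds()
        ]
        return cls(
            id=mol_id,
            atoms=atoms,
            bonds=bonds,
            charges=charges,
            activity_score=activity_score,
            provenance=dict(provenance or {}),
        )


@dataclass(frozen=True)
class CleaningRule:
    """One of the nine standardization recipes: protonation x coordinates."""

    protonation: str
    coordinates: str

    def __post_init__(self) -> None:
        if self.protonation not in _PROTONATIONS:
            raise ValueError(f"unknown protonation {self.protonation!r}")
        if self.coordinates not in _COORDINATES:
            raise ValueError(f"unknown coordinate method {self.coordinates!r}")

    @property
    def name(self) -> str:
        return f"{_PROT_LABEL[self.protonation]}_{_COORD_LABEL[self.coordinates]}"

    @property
    def is_analog(self) -> bool:
        """True when the coordinate pathway stands in for an external tool."""
        return self.coordinates == "corina_analog"


def enumerate_cleaning_rules() -> list[CleaningRule]:
    """All nine cleaning rules, 2D/3D/Corina varying fastest within protonation.

    Order: none_2D, domi_2D, neut_2D, none_3D, domi_3D, neut_3D,
    none_Corina, domi_Corina, neut_Corina.
    """
    return [
        CleaningRule(prot, coord)
        for coord in _COORDINATES
        for prot in _PROTONATIONS
    ]


# ---------------------------------------------------------------------------
# SDF / SMILES I/O
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path, activity_property: str = ACTIVITY_PROPERTY) -> list[Molecule]:
    """Read all records of a V2000/V3000 SDF file.

    The activity score is taken from ``activity_property`` when the record
    carries it. Malformed records raise with the failing record index;
    unsupported elements raise with the offending symbol.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    out: list[Molecule] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"malformed SDF record at index {idx} in {path}")
        score = None
        if mol.HasProp(activity_property):
            score = int(round(float(mol.GetProp(activity_property))))
        m = Molecule.from_rdkit(mol, activity_score=score)
        if not m.id:
            m.id = f"mol{idx}"
        out.append(m)
    return out


def write_sdf(
    mols: Iterable[Molecule],
    path: str | Path,
    activity_property: str = ACTIVITY_PROPERTY,
    sidecar: bool = False,
) -> Path:
    """Write molecules to a V2000 SDF; optional JSON provenance sidecar."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    prov: dict[str, dict] = {}
    for m in mols:
        rd = m.to_rdkit()
        if m.activity_score is not None:
            rd.SetProp(activity_property, str(int(m.activity_score)))
        writer.write(rd)
        if m.provenance:
            prov[m.id] = m.provenance
    writer.close()
    if sidecar:
        path.with_suffix(path.suffix + ".provenance.json").write_text(
            json.dumps(prov, indent=2, sort_keys=True)
        )
    return path


def parse_smiles(smiles: str, mol_id: str = "") -> Molecule:
    """Parse a SMILES string into a Molecule with all-zero coordinates.

    Coordinates stay at the origin until a cleaning rule assigns them.
    """
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"could not parse SMILES: {smiles!r}")
    return Molecule.from_rdkit(rd, mol_id=mol_id or smiles)


def read_smiles_file(path: str | Path) -> list[Molecule]:
    """Read one-SMILES-per-line text; optional second column is the id."""
    mols = []
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        mol_id = parts[1] if len(parts) > 1 else f"smi{ln}"
        mols.append(parse_smiles(parts[0], mol_id=mol_id))
    return mols


# ---------------------------------------------------------------------------
# Cleaning-rule application
# ---------------------------------------------------------------------------

def apply_cleaning_rule(mol: Molecule, rule: CleaningRule, seed: int = 0) -> Molecule:
    """Standardize protonation and (re)generate coordinates.

    protonation
        ``none`` leaves formal charges untouched; ``neutralize`` applies
        rule-based charge neutralization (protonate anions / deprotonate
        cations where chemically sensible); ``dominant`` applies pH-7
        dominant-form rules (carboxylic acids deprotonated, aliphatic amines
        protonated) — an open heuristic analog of commercial "wash" tools.
    coordinates
        ``depict2d`` computes a planar depiction (all z exactly 0);
        ``rebuild3d`` embeds with distance geometry (ETKDG) and refines with
        MMFF94; ``corina_analog`` is a second, independent pathway (plain DG
        random-coordinate embedding + UFF refinement) flagged
        ``analog=True`` in provenance.

    Both 3D pathways are deterministic under ``seed``.
    """
    rd = mol.to_rdkit()
    rd = _apply_protonation(rd, rule.protonation)
    rd = Chem.AddHs(rd)

    if rule.coordinates == "depict2d":
        AllChem.Compute2DCoords(rd)
    elif rule.coordinates == "rebuild3d":
        params = AllChem.ETKDGv3()
        params.randomSeed = _embed_seed(seed)
        if AllChem.EmbedMolecule(rd, params) != 0:
            raise RuntimeError(f"3D embedding failed for molecule {mol.id!r}")
        if AllChem.MMFFHasAllMoleculeParams(rd):
            AllChem.MMFFOptimizeMolecule(rd, maxIters=500)
    else:  # corina_analog: independent embedding + force-field pathway
        params = AllChem.EmbedParameters()
        params.useRandomCoords = True
        params.randomSeed = _embed_seed(seed) + 7919
        if AllChem.EmbedMolecule(rd, params) != 0:
            raise RuntimeError(f"3D embedding failed for molecule {mol.id!r}")
        AllChem.UFFOptimizeMolecule(rd, maxIters=500)

    prov = dict(mol.provenance)
    prov.update(
        {
            "cleaning_rule": rule.name,
            "protonation": rule.protonation,
            "coordinates": rule.coordinates,
            "analog": rule.is_analog,
            "seed": int(seed),
        }
    )
    out = Molecule.from_rdkit(
        rd, mol_id=mol.id, activity_score=mol.activity_score, provenance=prov
    )
    if rule.coordinates == "depict2d":
        # 2D depiction must be exactly planar
        out.atoms = [(s, x, y, 0.0) for s, x, y, _z in out.atoms]
    return out


def _apply_protonation(rd: Chem.Mol, mode: str) -> Chem.Mol:
    if mode == "none":
        return rd
    rd = Chem.RWMol(rd)
    for atom in rd.GetAtoms():
        q = atom.GetFormalCharge()
        if q == 0:
            continue
        if mode == "neutralize":
            _neutralize_atom(atom)
        elif mode == "dominant":
            # pH-7 dominant form: keep carboxylate anions and ammonium
            # cations charged, neutralize everything else.
            if q < 0 and _is_carboxylate_oxygen(atom):
                continue
            if q > 0 and _is_aliphatic_ammonium(atom):
                continue
            _neutralize_atom(atom)
    mol = rd.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _neutralize_atom(atom: Chem.Atom) -> None:
    q = atom.GetFormalCharge()
    h = atom.GetTotalNumHs()
    if q < 0:
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(h - q)  # add |q| protons
    elif q > 0 and h >= q:
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(h - q)  # remove q protons
    atom.UpdatePropertyCache(strict=False)


def _is_carboxylate_oxygen(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "O" or atom.GetFormalCharge() != -1:
        return False
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() == "C":
            for b in nb.GetBonds():
                other = b.GetOtherAtom(nb)
                if other.GetIdx() != atom.GetIdx() and other.GetSymbol() == "O" and (
                    b.GetBondType() == Chem.BondType.DOUBLE
                ):
                    return True
    return False


def _is_aliphatic_ammonium(atom: Chem.Atom) -> bool:
    return (
        atom.GetSymbol() == "N"
        and atom.GetFormalCharge() == 1
        and not atom.GetIsAromatic()
        and atom.GetTotalNumHs() >= 1
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def _bond_type(order: int) -> Chem.BondType:
    return {
        1: Chem.BondType.SINGLE,
        2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
        12: Chem.BondType.AROMATIC,
    }[order]


def _order_int(bond: Chem.Bond) -> int:
    t = bond.GetBondType()
    if t == Chem.BondType.AROMATIC:
        return 12
    return {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2, Chem.BondType.TRIPLE: 3}.get(t, 1)


def _embed_seed(seed: int) -> int:
    # RDKit embedding seeds must be positive 32-bit ints
    return (int(seed) % (2**31 - 2)) + 1
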