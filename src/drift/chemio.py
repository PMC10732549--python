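"""Molecule and protein IO: parse, represent, and write small molecules.

Molecules are held as :class:`MoleculeGraph`, a light graph view (atoms,
bonds, optional 3D conformers) over an RDKit molecule.  Ring perception is
run at load time with smallest-set-of-smallest-rings semantics; aromatic
bonds keep a distinct ``"aromatic"`` order rather than being Kekulized.
Atom indexing is 0-based internally; 1-based formats (SDF/MOL2) are
translated at the boundary by RDKit.

Hydrogens implicit in SMILES are recorded as counts on their heavy atom and
never added as explicit atoms; explicit hydrogens present in SDF/MOL2 input
are retained as atoms.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

#: elements with a dedicated one-hot slot; everything else maps to "other"
ELEMENT_VOCAB = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H")
#: bond counts 0..5 get a slot, >=6 shares the last slot
MAX_BOND_SLOT = 6

BOND_ORDERS = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "aromatic",
}


class MoleculeParseError(ValueError):
    """Raised when a molecule file or string cannot be parsed."""


@dataclass
class AtomRecord:
    element: str
    n_bonds: int
    mass: float
    formal_charge: int
    in_ring: bool
    n_hydrogens: int = 0

    @property
    def feature_vector(self) -> np.ndarray:
        """Concatenated one-hot element, one-hot bond count, mass, charge."""
        v = np.zeros(len(ELEMENT_VOCAB) + 1 + MAX_BOND_SLOT + 1 + 2)
        try:
            v[ELEMENT_VOCAB.index(self.element)] = 1.0
        except ValueError:
            v[len(ELEMENT_VOCAB)] = 1.0  # "other" slot
        slot = min(self.n_bonds, MAX_BOND_SLOT)
        v[len(ELEMENT_VOCAB) + 1 + slot] = 1.0
        v[-2] = self.mass / 100.0
        v[-1] = float(self.formal_charge)
        return v


@dataclass
class BondRecord:
    atom_i: int
    atom_j: int
    order: object  # 1, 2, 3 or "aromatic"
    in_ring: bool
    rotatable: bool | None = None  # assigned by drift.fragmenter


@dataclass
class Conformer:
    coords: np.ndarray  # N x 3, Angstrom
    seed: int


@dataclass
class MoleculeGraph:
    mol_id: str
    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    conformers: list[Conformer] = field(default_factory=list)
    source_format: str = "smiles"
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.atom_i == i:
                out.append(b.atom_j)
            elif b.atom_j == i:
                out.append(b.atom_i)
        return sorted(out)

    def bond_between(self, i: int, j: int) -> BondRecord | None:
        for b in self.bonds:
            if {b.atom_i, b.atom_j} == {i, j}:
                return b
        return None

    def validate(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("molecule must have at least one atom")
        seen = set()
        for b in self.bonds:
            if b.atom_i == b.atom_j:
                raise ValueError(f"self-bond on atom {b.atom_i}")
            if not (0 <= b.atom_i < self.n_atoms and 0 <= b.atom_j < self.n_atoms):
                raise ValueError("bond atom index out of range")
            key = frozenset((b.atom_i, b.atom_j))
            if key in seen:
                raise ValueError(f"duplicate bond {sorted(key)}")
            seen.add(key)


@dataclass
class ProteinSeq:
    prot_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("protein sequence must be nonempty")


def _mol_to_graph(mol: Chem.Mol, mol_id: str, source_format: str) -> MoleculeGraph:
    Chem.GetSSSR(mol)
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(
            AtomRecord(
                element=a.GetSymbol(),
                n_bonds=a.GetDegree(),
                mass=a.GetMass(),
                formal_charge=a.GetFormalCharge(),
                in_ring=a.IsInRing(),
                n_hydrogens=a.GetTotalNumHs(),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        order = BOND_ORDERS.get(b.GetBondType())
        if order is None:
            # dative / unknown orders collapse to single
            order = 1
        bonds.append(
            BondRecord(
                atom_i=b.GetBeginAtomIdx(),
                atom_j=b.GetEndAtomIdx(),
                order=order,
                in_ring=b.IsInRing(),
            )
        )
    g = MoleculeGraph(
        mol_id=mol_id, atoms=atoms, bonds=bonds, source_format=source_format, rdmol=mol
    )
    g.validate()
    return g


def read_molecule(path_or_string: str, fmt: str | None = None, mol_id: str | None = None) -> MoleculeGraph:
    """Parse a molecule from a SMILES string or an SDF/MOL2/SMILES file.

    Parameters
    ----------
    path_or_string:
        A SMILES string, or a path to a ``.smi``/``.sdf``/``.mol2`` file.
    fmt:
        One of ``"smiles"``, ``"sdf"``, ``"mol2"``.  Inferred from the file
        extension when a path is given; defaults to ``"smiles"`` for raw
        strings.
    mol_id:
        Identifier for the molecule; defaults to the record name in the file
        or the SMILES string itself.
    """
    if path_or_string == "" or path_or_string is None:
        raise MoleculeParseError("empty molecule input")
    is_path = os.path.exists(path_or_string) and (
        fmt in ("sdf", "mol2", "smiles", None)
    ) and any(path_or_string.endswith(e) for e in (".sdf", ".mol", ".mol2", ".smi", ".txt"))
    if fmt is None:
        if is_path:
            ext = os.path.splitext(path_or_string)[1].lower()
            fmt = {".sdf": "sdf", ".mol": "sdf", ".mol2": "mol2", ".smi": "smiles"}.get(ext, "smiles")
        else:
            fmt = "smiles"

    if fmt == "smiles":
        text = path_or_string
        if is_path:
            with open(path_or_string) as fh:
                text = fh.readline().strip()
        parts = text.split()
        if not parts:
            raise MoleculeParseError("empty SMILES input")
        smiles = parts[0]
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise MoleculeParseError(f"could not parse SMILES: {smiles!r}")
        return _mol_to_graph(mol, mol_id or (parts[1] if len(parts) > 1 else smiles), "smiles")

    if fmt == "sdf":
        if is_path:
            supplier = Chem.SDMolSupplier(path_or_string, removeHs=False, sanitize=True)
        else:
            supplier = Chem.SDMolSupplier()
            supplier.SetData(path_or_string, removeHs=False, sanitize=True)
        mols = [m for m in supplier]
        if not mols or mols[0] is None:
            raise MoleculeParseError("could not parse SDF input")
        mol = mols[0]
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else None
        return _mol_to_graph(mol, mol_id or name or "mol", "sdf")

    if fmt == "mol2":
        if is_path:
            mol = Chem.MolFromMol2File(path_or_string, removeHs=False, sanitize=True)
        else:
            mol = Chem.MolFromMol2Block(path_or_string, removeHs=False, sanitize=True)
        if mol is None:
            raise MoleculeParseError("could not parse MOL2 input")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else None
        return _mol_to_graph(mol, mol_id or name or "mol", "mol2")

    raise ValueError(f"unknown format {fmt!r}")


def read_molecules_smi(path: str) -> list[MoleculeGraph]:
    """Read a multi-record ``.smi`` file (``SMILES [id]`` per line)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mid = parts[1] if len(parts) > 1 else f"mol{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise MoleculeParseError(f"{path}:{lineno}: could not parse SMILES {smiles!r}")
            out.append(_mol_to_graph(mol, mid, "smiles"))
    return out


def write_sdf(mols: list[MoleculeGraph] | MoleculeGraph, path: str) -> None:
    """Write molecules (with any conformers) to an SDF (V2000) file."""
    if isinstance(mols, MoleculeGraph):
        mols = [mols]
    writer = Chem.SDWriter(path)
    writer.SetKekulize(True)
    try:
        for g in mols:
            if g.rdmol is None:
                raise ValueError(f"molecule {g.mol_id} has no structure backing")
            mol = Chem.Mol(g.rdmol)
            mol.SetProp("_Name", g.mol_id)
            mol.RemoveAllConformers()
            for ci, conf in enumerate(g.conformers):
                c = Chem.Conformer(mol.GetNumAtoms())
                for i, (x, y, z) in enumerate(np.asarray(conf.coords, dtype=float)):
                    c.SetAtomPosition(i, (float(x), float(y), float(z)))
                c.SetId(ci)
                mol.AddConformer(c, assignId=False)
            writer.write(mol)
    finally:
        writer.close()


def to_smiles(mol: MoleculeGraph) -> str:
    """Canonical SMILES of the molecule."""
    if mol.rdmol is None:
        raise ValueError("molecule has no structure backing")
    return Chem.MolToSmiles(mol.rdmol)


def generate_conformers(
    mol: MoleculeGraph, k: int, seed: int, max_atoms: int = 50
) -> MoleculeGraph:
    """Embed ``k`` 3D conformers with seeded distance geometry + MMFF relaxation.

    Repeated calls with the same seed are deterministic, and the first
    conformer of a ``k=10`` run equals the single conformer of a ``k=1`` run
    (per-conformer seeds are derived as ``seed + index``).

    Raises
    ------
    ValueError
        If ``k <= 0`` or the molecule exceeds ``max_atoms`` (pharmacophore
        indexing caps compound size; larger queries fall back to 2D search).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if mol.n_atoms > max_atoms:
        raise ValueError(
            f"molecule {mol.mol_id} has {mol.n_atoms} atoms, exceeds max_atoms={max_atoms}"
        )
    if mol.rdmol is None:
        raise ValueError("molecule has no structure backing")
    work = Chem.AddHs(Chem.Mol(mol.rdmol))
    n_heavy = mol.n_atoms
    confs: list[Conformer] = []
    for i in range(k):
        conf_seed = int(seed) + i
        params = AllChem.ETKDGv3()
        params.randomSeed = conf_seed
        params.useRandomCoords = False
        m = Chem.Mol(work)
        cid = AllChem.EmbedMolecule(m, params)
        if cid < 0:
            params.useRandomCoords = True
            cid = AllChem.EmbedMolecule(m, params)
        if cid < 0:
            raise ValueError(f"conformer embedding failed for {mol.mol_id} (seed {conf_seed})")
        try:
            AllChem.MMFFOptimizeMolecule(m, confId=cid, maxIters=200)
        except Exception:
            pass  # unparametrized atoms: keep raw DG coordinates
        coords = m.GetConformer(cid).GetPositions()[:n_heavy]
        confs.append(Conformer(coords=np.array(coords, dtype=float), seed=conf_seed))
    mol.conformers = confs
    return mol


def read_protein(path_or_string: str, prot_id: str | None = None) -> ProteinSeq:
    """Read one protein from a FASTA file/string or a raw sequence string.

    The sequence is uppercased; non-standard residue symbols are preserved.
    """
    if not path_or_string or not path_or_string.strip():
        raise ValueError("empty protein input")
    text = path_or_string
    if os.path.exists(path_or_string) and not path_or_string.lstrip().startswith(">"):
        with open(path_or_string) as fh:
            text = fh.read()
    text = text.strip()
    if text.startswith(">"):
        from Bio import SeqIO

        rec = next(SeqIO.parse(io.StringIO(text), "fasta"), None)
        if rec is None or len(rec.seq) == 0:
            raise ValueError("empty FASTA record")
        return ProteinSeq(prot_id=prot_id or rec.id, sequence=str(rec.seq).upper())
    seq = "".join(text.split()).upper()
    if not seq:
        raise ValueError("empty protein sequence")
    return ProteinSeq(prot_id=prot_id or "protein", sequence=seq)


def read_proteins_fasta(path: str) -> list[ProteinSeq]:
    """Read all records of a FASTA file."""
    from Bio import SeqIO

    out = [
        ProteinSeq(prot_id=r.id, sequence=str(r.seq).upper())
        for r in SeqIO.parse(path, "fasta")
    ]
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_proteins_fasta(prots: list[ProteinSeq], path: str) -> None:
    with open(path, "w") as fh:
        for p in prots:
            fh.write(f">{p.prot_id}\n{p.sequence}\n")
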