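"""Input encodings for the compound-protein interaction network.

Proteins: each residue row is its BLOSUM62 substitution profile over the 20
standard amino acids (non-standard symbols get all-zero substitution
features) concatenated with sinusoidal positional-encoding channels —
residue order carries structural information, so positions are encoded.

Compounds: each atom row concatenates a one-hot element type, a one-hot
bond count, atomic mass and formal charge; bonds enter as an order-weighted
adjacency matrix; a fragment map ties atoms to the rotatable-bond fragments
they belong to.  Fragment order in a compound is arbitrary, so no
positional channels are added on the compound side.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from drift.chemio import MoleculeGraph, ProteinSeq
from drift.fragmenter import FragmentPartition

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM_SCALE = 0.1  # keeps substitution features O(1) for training
DEFAULT_PE_DIM = 16

#: bond order -> adjacency weight (aromatic between single and double)
BOND_WEIGHTS = {1: 1.0, 2: 2.0, 3: 3.0, "aromatic": 1.5}


@dataclass
class ProteinEncoding:
    matrix: np.ndarray  # L x (20 + pe_dim)
    length: int
    pe_dim: int


@dataclass
class CompoundEncoding:
    atom_features: np.ndarray  # N x p
    adjacency: np.ndarray  # N x N, bond-order weighted, symmetric
    fragment_map: np.ndarray  # N, atom index -> fragment index
    n_fragments: int
    mol_id: str = ""


@lru_cache(maxsize=1)
def _blosum62_rows() -> dict[str, np.ndarray]:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    return {
        a: np.array([float(m[a, b]) for b in STANDARD_AA]) for a in STANDARD_AA
    }


def blosum62_row(residue: str) -> np.ndarray:
    """BLOSUM62 profile of one residue; zeros for non-standard symbols."""
    return _blosum62_rows().get(residue.upper(), np.zeros(len(STANDARD_AA)))


def positional_encoding(length: int, dim: int = DEFAULT_PE_DIM) -> np.ndarray:
    """Sinusoidal positional channels: pe[i, 2k] = sin(i / 10000^(2k/dim))."""
    if dim % 2 != 0:
        raise ValueError("positional-encoding dimension must be even")
    pos = np.arange(length)[:, None].astype(float)
    div = np.power(10000.0, np.arange(0, dim, 2) / dim)
    pe = np.zeros((length, dim))
    pe[:, 0::2] = np.sin(pos / div)
    pe[:, 1::2] = np.cos(pos / div)
    return pe


def encode_protein(seq: ProteinSeq, pe_dim: int = DEFAULT_PE_DIM) -> ProteinEncoding:
    """Encode a protein as BLOSUM62 profiles plus positional channels.

    Non-standard residues keep all-zero substitution features but real
    positional channels (only the substitution profile is undefined for
    them, not the position).
    """
    if not seq.sequence:
        raise ValueError("cannot encode an empty sequence")
    sub = np.stack([blosum62_row(r) for r in seq.sequence]) * BLOSUM_SCALE
    pe = positional_encoding(len(seq.sequence), pe_dim)
    return ProteinEncoding(
        matrix=np.hstack([sub, pe]), length=len(seq.sequence), pe_dim=pe_dim
    )


def encode_compound(mol: MoleculeGraph, partition: FragmentPartition) -> CompoundEncoding:
    """Encode a compound graph plus its fragment partition.

    Raises if the partition does not cover exactly this molecule's atoms.
    """
    if partition.mol_id != mol.mol_id:
        raise ValueError(
            f"partition is for {partition.mol_id!r}, molecule is {mol.mol_id!r}"
        )
    covered = set().union(*partition.clusters) if partition.clusters else set()
    if covered != set(range(mol.n_atoms)):
        raise ValueError("fragment partition does not cover the molecule's atoms")
    feats = np.stack([a.feature_vector for a in mol.atoms])
    adj = np.zeros((mol.n_atoms, mol.n_atoms))
    for b in mol.bonds:
        w = BOND_WEIGHTS.get(b.order, 1.0)
        adj[b.atom_i, b.atom_j] = w
        adj[b.atom_j, b.atom_i] = w
    fmap = np.zeros(mol.n_atoms, dtype=np.int64)
    for fi, cluster in enumerate(partition.clusters):
        for a in cluster:
            fmap[a] = fi
    return CompoundEncoding(
        atom_features=feats,
        adjacency=adj,
        fragment_map=fmap,
        n_fragments=len(partition.clusters),
        mol_id=mol.mol_id,
    )
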