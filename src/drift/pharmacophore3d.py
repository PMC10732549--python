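"""3D pharmacophore extraction and distance-binned key matching.

Pharmacophore features (aromatic ring, H-bond donor/acceptor, hydrophobic
cluster, positive/negative ionizable group) are extracted from a conformer
with documented SMARTS-style rules.  A molecule's searchable key hashes
every unordered feature triplet — sorted feature kinds plus pairwise
distances binned at 1.0 Angstrom, capped at 20 Angstrom — into a fixed
4096-bit vector; with fewer than three features, pairs or singletons are
hashed instead so small molecules stay searchable.  Keys depend only on
inter-feature distances, so they are invariant to rigid rotation and
translation of the conformer.

Database search scores each library key by bit overlap with the query,
maximised over the query's conformers: more conformers can only grow the
matched set, which is why retrieval recall rises monotonically with the
number of conformers searched.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from drift.chemio import MoleculeGraph
from drift.fingerprint2d import SimilarityHit, fnv1a

logger = logging.getLogger(__name__)

KEY_BITS = 4096
BIN_WIDTH = 1.0  # Angstrom
MAX_DIST = 20.0  # Angstrom
MIN_HYDROPHOBIC_CLUSTER = 2
MAX_PHARMACOPHORE_ATOMS = 50

FEATURE_KINDS = (
    "aromatic",
    "h-donor",
    "h-acceptor",
    "hydrophobic",
    "pos-ionizable",
    "neg-ionizable",
)

# SMARTS rules; each match contributes one feature at the matched atoms' centroid
_SMARTS_RULES: dict[str, tuple[str, ...]] = {
    "h-donor": ("[#7!H0]", "[#8!H0]", "[#16!H0]"),
    "h-acceptor": ("[#7;!+;!X4]", "[#8;!+]"),
    "pos-ionizable": ("[+;!$([+]~[-])]", "[NX3;H2;!$(NC=O);!$(N~a)]"),
    "neg-ionizable": ("[-;!$([-]~[+])]", "[CX3](=O)[OX2H1]"),
}


@dataclass
class PharmacophoreFeature:
    kind: str
    center: np.ndarray  # 3-vector, Angstrom
    member_atoms: tuple[int, ...]


@dataclass
class Pharmacophore3DKey:
    bits: np.ndarray  # uint8 of length KEY_BITS
    n_features: int

    @property
    def n_set(self) -> int:
        return int(self.bits.sum())

    def hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, h: str, n_features: int) -> "Pharmacophore3DKey":
        raw = np.frombuffer(bytes.fromhex(h), dtype=np.uint8)
        return cls(bits=np.unpackbits(raw)[:KEY_BITS].astype(np.uint8), n_features=n_features)


def _hydrophobic_clusters(mol: MoleculeGraph) -> list[tuple[int, ...]]:
    """Connected clusters of aliphatic carbons with no heteroatom neighbors."""
    eligible = set()
    for i, a in enumerate(mol.atoms):
        if a.element != "C" or a.in_ring:
            continue
        if all(mol.atoms[j].element in ("C", "H") for j in mol.neighbors(i)):
            eligible.add(i)
    clusters: list[tuple[int, ...]] = []
    seen: set[int] = set()
    for start in sorted(eligible):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(j for j in mol.neighbors(x) if j in eligible and j not in comp)
        seen |= comp
        if len(comp) >= MIN_HYDROPHOBIC_CLUSTER:
            clusters.append(tuple(sorted(comp)))
    return clusters


def extract_features(mol: MoleculeGraph, conformer_index: int = 0) -> list[PharmacophoreFeature]:
    """Extract pharmacophore features from one conformer.

    Aromatic rings yield one feature at the ring centroid; SMARTS rules
    cover donors, acceptors and ionizable groups; hydrophobic features are
    centroids of connected aliphatic-carbon clusters (>= 2 atoms).
    """
    if conformer_index >= len(mol.conformers):
        raise ValueError(
            f"molecule {mol.mol_id} has {len(mol.conformers)} conformer(s); "
            f"index {conformer_index} missing"
        )
    if mol.rdmol is None:
        raise ValueError("molecule has no structure backing")
    coords = np.asarray(mol.conformers[conformer_index].coords, dtype=float)
    feats: list[PharmacophoreFeature] = []

    def add(kind: str, atoms: tuple[int, ...]) -> None:
        atoms = tuple(sorted(set(atoms)))
        feats.append(
            PharmacophoreFeature(kind=kind, center=coords[list(atoms)].mean(axis=0), member_atoms=atoms)
        )

    ring_info = mol.rdmol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            add("aromatic", tuple(ring))

    seen: set[tuple[str, tuple[int, ...]]] = set()
    for kind, patterns in _SMARTS_RULES.items():
        for sma in patterns:
            patt = Chem.MolFromSmarts(sma)
            for match in mol.rdmol.GetSubstructMatches(patt):
                key = (kind, tuple(sorted(match)))
                if key not in seen:
                    seen.add(key)
                    add(kind, tuple(match))

    for cluster in _hydrophobic_clusters(mol):
        add("hydrophobic", cluster)

    feats.sort(key=lambda f: (f.kind, f.member_atoms))
    return feats


def _hash_tuple(kinds: tuple[str, ...], bins: tuple[int, ...]) -> int:
    desc = ",".join(kinds) + ";" + ",".join(map(str, bins))
    return fnv1a(desc.encode()) % KEY_BITS


def _bin(d: float) -> int:
    return int(min(d, MAX_DIST - 1e-9) // BIN_WIDTH)


def pharmacophore_key(features: list[PharmacophoreFeature]) -> Pharmacophore3DKey:
    """Hash feature triplets (or pairs/singletons for < 3 features) to a key.

    Triplet descriptor: the three (kind, opposite-side distance bin) pairs
    sorted lexicographically, which makes the descriptor independent of
    feature enumeration order.
    """
    bits = np.zeros(KEY_BITS, dtype=np.uint8)
    n = len(features)
    if n >= 3:
        for fa, fb, fc in itertools.combinations(features, 3):
            # pair each feature with the distance bin of the edge opposite it
            trio = [
                (fa.kind, _bin(float(np.linalg.norm(fb.center - fc.center)))),
                (fb.kind, _bin(float(np.linalg.norm(fa.center - fc.center)))),
                (fc.kind, _bin(float(np.linalg.norm(fa.center - fb.center)))),
            ]
            trio.sort()
            kinds = tuple(k for k, _ in trio)
            dbins = tuple(d for _, d in trio)
            bits[_hash_tuple(kinds, dbins)] = 1
    elif n == 2:
        fa, fb = features
        d = _bin(float(np.linalg.norm(fa.center - fb.center)))
        kinds = tuple(sorted((fa.kind, fb.kind)))
        bits[_hash_tuple(kinds, (d,))] = 1
    elif n == 1:
        bits[_hash_tuple((features[0].kind,), ())] = 1
    return Pharmacophore3DKey(bits=bits, n_features=n)


def key_overlap(query: Pharmacophore3DKey, entry: Pharmacophore3DKey) -> float:
    """Fraction of the query's set bits present in the entry's key."""
    q = query.n_set
    if q == 0:
        return 0.0
    return float(np.bitwise_and(query.bits, entry.bits).sum()) / q


def search_3d(
    query_mol: MoleculeGraph,
    k_conformers: int,
    db: list[tuple[str, Pharmacophore3DKey]],
    min_overlap: float = 0.5,
    seed: int = 7,
    max_atoms: int = MAX_PHARMACOPHORE_ATOMS,
) -> list[SimilarityHit] | None:
    """Pharmacophore search of a query against a prebuilt key database.

    A database molecule's score is the maximum, over the query's first
    ``k_conformers`` conformers, of the bit-overlap fraction of the query
    conformer's key in the database key.  Hits with score >= ``min_overlap``
    are returned sorted by score (ties by mol_id).

    Returns ``None`` — "no pharmacophore search performed" — when the query
    exceeds ``max_atoms``; callers fall back to 2D-only search.
    """
    if query_mol.n_atoms > max_atoms:
        logger.warning(
            "query %s has %d atoms (> %d): no pharmacophore search performed",
            query_mol.mol_id,
            query_mol.n_atoms,
            max_atoms,
        )
        return None
    from drift.chemio import generate_conformers

    if len(query_mol.conformers) < k_conformers:
        generate_conformers(query_mol, k_conformers, seed=seed, max_atoms=max_atoms)
    qkeys = [
        pharmacophore_key(extract_features(query_mol, ci)) for ci in range(k_conformers)
    ]
    hits = []
    for mol_id, entry in db:
        score = max((key_overlap(qk, entry) for qk in qkeys), default=0.0)
        if score >= min_overlap and score > 0.0:
            hits.append(SimilarityHit(mol_id=mol_id, tc=0.0, pharmacophore_score=score))
    hits.sort(key=lambda h: (-h.pharmacophore_score, h.mol_id))
    return hits


def build_pharmacophore_db(
    mols: list[MoleculeGraph],
    n_conformers: int = 10,
    seed: int = 7,
    max_atoms: int = MAX_PHARMACOPHORE_ATOMS,
) -> list[tuple[str, Pharmacophore3DKey]]:
    """Build the key database: per molecule, the union of its conformer keys.

    Molecules above ``max_atoms`` are skipped (the database stores compounds
    below the size cap only), with a logged notice.
    """
    from drift.chemio import generate_conformers

    db: list[tuple[str, Pharmacophore3DKey]] = []
    for mol in mols:
        if mol.n_atoms > max_atoms:
            logger.warning("skipping %s: %d atoms exceeds cap %d", mol.mol_id, mol.n_atoms, max_atoms)
            continue
        if len(mol.conformers) < n_conformers:
            generate_conformers(mol, n_conformers, seed=seed, max_atoms=max_atoms)
        bits = np.zeros(KEY_BITS, dtype=np.uint8)
        nf = 0
        for ci in range(n_conformers):
            feats = extract_features(mol, ci)
            key = pharmacophore_key(feats)
            bits |= key.bits
            nf = max(nf, key.n_features)
        db.append((mol.mol_id, Pharmacophore3DKey(bits=bits, n_features=nf)))
    return db


def save_pharmacophore_db(db: list[tuple[str, Pharmacophore3DKey]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#drift-phdb\tv1\n")
        for mol_id, key in db:
            fh.write(f"{mol_id}\t{key.n_features}\t{key.hex()}\n")


def load_pharmacophore_db(path: str) -> list[tuple[str, Pharmacophore3DKey]]:
    db = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#drift-phdb"):
            raise ValueError(f"{path} is not a drift pharmacophore database")
        for line in fh:
            mol_id, nf, hexkey = line.rstrip("\n").split("\t")
            db.append((mol_id, Pharmacophore3DKey.from_hex(hexkey, int(nf))))
    return db
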