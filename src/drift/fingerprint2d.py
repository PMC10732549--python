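"""Path-based 1024-bit 2D fingerprints and Tanimoto similarity search.

The fingerprint indexes linear fragments (simple paths) of one to seven
heavy atoms, under four generation conditions:

1. a fragment contains at most seven atoms;
2. single-atom fragments of C, O and N are ignored;
3. duplicate fragments (same canonical element/bond-order/ring descriptor)
   are recorded once;
4. fragment growth terminates at ring structures (see ``ring_termination``).

Each surviving fragment descriptor is hashed (FNV-1a over the canonical
string, reduced mod 1024) to a bit position; the fingerprint is the union of
those bits.  Similarity between fingerprints is the Tanimoto coefficient
Tc = c / (a + b - c) with a, b the set-bit counts of the operands and c the
count of shared bits.  Compounds with Tc >= 0.85 are conventionally called
structurally similar; that is the default search threshold.

The bit layout is this package's own stable hash of the stated conditions;
bit-exact compatibility with other FP2 implementations is not promised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from drift.chemio import MoleculeGraph

N_BITS = 1024
MAX_PATH_ATOMS = 7
IGNORED_SINGLETONS = frozenset({"C", "O", "N"})

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


def fnv1a(data: bytes) -> int:
    """64-bit FNV-1a hash."""
    h = _FNV_OFFSET
    for byte in data:
        h = ((h ^ byte) * _FNV_PRIME) & _MASK64
    return h


@dataclass
class Fingerprint2D:
    bits: np.ndarray  # uint8 vector of length 1024, values 0/1
    fragments: list[tuple[tuple[int, ...], int]] = field(default_factory=list)
    build_params: dict = field(default_factory=dict)

    @property
    def n_set(self) -> int:
        return int(self.bits.sum())

    def packed(self) -> np.ndarray:
        return np.packbits(self.bits)

    def hex(self) -> str:
        return self.packed().tobytes().hex()

    @classmethod
    def from_hex(cls, h: str, build_params: dict | None = None) -> "Fingerprint2D":
        raw = np.frombuffer(bytes.fromhex(h), dtype=np.uint8)
        bits = np.unpackbits(raw)[:N_BITS].astype(np.uint8)
        return cls(bits=bits, build_params=build_params or {})


@dataclass
class SimilarityHit:
    mol_id: str
    tc: float
    pharmacophore_score: float | None = None


def _ring_systems(mol: MoleculeGraph) -> dict[int, int]:
    """Map atom index -> fused-ring-system id (ring atoms only).

    Ring systems are the connected components of the subgraph of ring bonds.
    """
    parent = {i: i for i in range(mol.n_atoms) if mol.atoms[i].in_ring}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in mol.bonds:
        if b.in_ring:
            ri, rj = find(b.atom_i), find(b.atom_j)
            if ri != rj:
                parent[ri] = rj
    return {i: find(i) for i in parent}


def _adjacency(mol: MoleculeGraph, heavy_only: bool) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    keep = [
        i
        for i in range(mol.n_atoms)
        if not (heavy_only and mol.atoms[i].element == "H")
    ]
    keepset = set(keep)
    for i in keep:
        adj[i] = []
    for b in mol.bonds:
        if b.atom_i in keepset and b.atom_j in keepset:
            adj[b.atom_i].append(b.atom_j)
            adj[b.atom_j].append(b.atom_i)
    for i in adj:
        adj[i].sort()
    return adj


def path_descriptor(mol: MoleculeGraph, path: tuple[int, ...]) -> str:
    """Canonical descriptor of a path: elements, bond orders, ring flags.

    The lexicographically smaller of the two read directions is used, so a
    path and its reverse share one descriptor.
    """

    def one_direction(p: tuple[int, ...]) -> str:
        toks = []
        for k, idx in enumerate(p):
            a = mol.atoms[idx]
            toks.append(f"{a.element}{'@' if a.in_ring else ''}")
            if k + 1 < len(p):
                b = mol.bond_between(idx, p[k + 1])
                toks.append(f"[{b.order}{'@' if b.in_ring else ''}]")
        return "|".join(toks)

    fwd = one_direction(path)
    rev = one_direction(path[::-1])
    return min(fwd, rev)


def enumerate_paths(
    mol: MoleculeGraph,
    heavy_only: bool = True,
    ring_termination: str = "ring-system",
) -> list[tuple[int, ...]]:
    """Enumerate the fragment paths that feed the fingerprint.

    Returns one representative atom-index path per unique canonical
    descriptor.  Paths are simple, have 1..7 atoms, exclude single C/O/N
    atoms, and terminate at rings:

    - ``ring_termination="ring-system"`` (default): a path may run through a
      fused ring system contiguously but may not re-enter a ring system it
      has already left;
    - ``ring_termination="closure"``: growth stops as soon as the candidate
      atom is bonded to any non-terminal atom already on the path (the step
      that would close a cycle).
    """
    if ring_termination not in ("ring-system", "closure"):
        raise ValueError(f"unknown ring_termination {ring_termination!r}")
    adj = _adjacency(mol, heavy_only)
    systems = _ring_systems(mol)
    seen_desc: dict[str, tuple[int, ...]] = {}

    def admissible(path: list[int], nxt: int) -> bool:
        if nxt in path:
            return False
        if ring_termination == "closure":
            for earlier in path[:-1]:
                if nxt in adj[earlier]:
                    return False
            return True
        sys_next = systems.get(nxt)
        if sys_next is not None:
            prev_sys = systems.get(path[-1])
            if prev_sys != sys_next and any(
                systems.get(a) == sys_next for a in path
            ):
                return False  # re-entering a ring system after leaving it
        return True

    def grow(path: list[int]) -> None:
        if len(path) > 1 or mol.atoms[path[0]].element not in IGNORED_SINGLETONS:
            desc = path_descriptor(mol, tuple(path))
            if desc not in seen_desc:
                seen_desc[desc] = tuple(path)
        if len(path) == MAX_PATH_ATOMS:
            return
        for nxt in adj[path[-1]]:
            if admissible(path, nxt):
                path.append(nxt)
                grow(path)
                path.pop()

    for start in sorted(adj):
        grow([start])
    return list(seen_desc.values())


def hash_fragment(descriptor: str, n_bits: int = N_BITS) -> int:
    """Hash a canonical fragment descriptor to a bit position."""
    if not descriptor:
        raise ValueError("empty fragment descriptor")
    return fnv1a(descriptor.encode()) % n_bits


def fingerprint(
    mol: MoleculeGraph,
    heavy_only: bool = True,
    ring_termination: str = "ring-system",
) -> Fingerprint2D:
    """Compute the 1024-bit path fingerprint of a molecule."""
    bits = np.zeros(N_BITS, dtype=np.uint8)
    provenance = []
    for path in enumerate_paths(mol, heavy_only=heavy_only, ring_termination=ring_termination):
        desc = path_descriptor(mol, path)
        h = hash_fragment(desc)
        bits[h] = 1
        provenance.append((path, h))
    return Fingerprint2D(
        bits=bits,
        fragments=provenance,
        build_params={
            "n_bits": N_BITS,
            "max_path_atoms": MAX_PATH_ATOMS,
            "heavy_only": heavy_only,
            "ring_termination": ring_termination,
            "hash": "fnv1a",
        },
    )


def tanimoto(fa: Fingerprint2D, fb: Fingerprint2D) -> float:
    """Tanimoto coefficient c / (a + b - c) of two fingerprints.

    Both all-zero operands return 1.0 (identity convention for the 0/0
    case), with a warning.
    """
    if fa.build_params and fb.build_params and fa.build_params != fb.build_params:
        raise ValueError("fingerprints built with different parameters")
    a = fa.n_set
    b = fb.n_set
    c = int(np.bitwise_and(fa.bits, fb.bits).sum())
    if a == 0 and b == 0:
        warnings.warn("Tanimoto of two empty fingerprints; returning 1.0 by convention")
        return 1.0
    return c / (a + b - c)


@dataclass
class FastIndex:
    """Prebuilt similarity-search index: packed fingerprints of a library."""

    mol_ids: list[str]
    packed: np.ndarray  # n x 128 uint8, packed 1024-bit fingerprints
    n_set: np.ndarray  # per-entry popcount
    build_params: dict

    def __len__(self) -> int:
        return len(self.mol_ids)

    def save(self, path: str) -> None:
        """Write the index as a small self-describing TSV."""
        import json

        with open(path, "w") as fh:
            fh.write("#drift-fpidx\tv1\t" + json.dumps(self.build_params) + "\n")
            for mid, row in zip(self.mol_ids, self.packed):
                fh.write(f"{mid}\t{row.tobytes().hex()}\n")

    @classmethod
    def load(cls, path: str) -> "FastIndex":
        import json

        mol_ids: list[str] = []
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 3 or header[0] != "#drift-fpidx":
                raise ValueError(f"{path} is not a drift fingerprint index")
            params = json.loads(header[2])
            for line in fh:
                mid, hexfp = line.rstrip("\n").split("\t")
                mol_ids.append(mid)
                rows.append(np.frombuffer(bytes.fromhex(hexfp), dtype=np.uint8))
        packed = np.vstack(rows) if rows else np.zeros((0, N_BITS // 8), np.uint8)
        n_set = np.bitwise_count(packed).sum(axis=1).astype(np.int64)
        return cls(mol_ids=mol_ids, packed=packed, n_set=n_set, build_params=params)


def build_index(
    mols: list[MoleculeGraph],
    heavy_only: bool = True,
    ring_termination: str = "ring-system",
) -> FastIndex:
    """Fingerprint every molecule and pack the bits for fast scanning."""
    if not mols:
        raise ValueError("cannot build an index from an empty library")
    ids = [m.mol_id for m in mols]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate mol_id(s) in library: {dupes}")
    fps = [fingerprint(m, heavy_only=heavy_only, ring_termination=ring_termination) for m in mols]
    packed = np.vstack([fp.packed() for fp in fps])
    n_set = np.array([fp.n_set for fp in fps], dtype=np.int64)
    return FastIndex(
        mol_ids=ids, packed=packed, n_set=n_set, build_params=fps[0].build_params
    )


def search_2d(
    query: Fingerprint2D, index: FastIndex, tc_min: float = 0.85
) -> list[SimilarityHit]:
    """Rank index entries by Tanimoto to the query; keep tc >= tc_min.

    Ties in Tc are broken by lexicographic mol_id, so results are fully
    deterministic.
    """
    if not 0.0 <= tc_min <= 1.0:
        raise ValueError("tc_min must be in [0, 1]")
    if query.build_params and index.build_params and query.build_params != index.build_params:
        raise ValueError("query fingerprint and index built with different parameters")
    qp = query.packed()
    a = query.n_set
    common = np.bitwise_count(np.bitwise_and(index.packed, qp)).sum(axis=1).astype(np.int64)
    denom = a + index.n_set - common
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(denom > 0, common / np.maximum(denom, 1), 1.0)
    hits = [
        SimilarityHit(mol_id=index.mol_ids[i], tc=float(tc[i]))
        for i in np.nonzero(tc >= tc_min)[0]
    ]
    hits.sort(key=lambda h: (-h.tc, h.mol_id))
    return hits
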