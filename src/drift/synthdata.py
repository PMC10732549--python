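"""Synthetic compound libraries, annotation databases and affinity data.

Every downstream module is testable without external database downloads:
this module plants known structure and emits the ground truth alongside.

The world it emulates:

- a compound library built by decorating a small set of scaffolds with
  substituents; compounds sharing a scaffold form a similarity cluster
  (high within-cluster Tanimoto, lower between clusters), mimicking the
  bait-compound neighbourhoods a similarity search retrieves;
- a protein panel of random sequences over the 20-letter alphabet, where
  each cluster's primary target carries a planted k-mer motif;
- a bilinear affinity model: pKd is a bilinear form of the compound's
  fingerprint bits and the protein's motif-count vector plus Gaussian
  noise, so compounds bind their own cluster's motif-bearing target
  tightly (pKd near 8) and everything else weakly (pKd near 4);
- an annotation table of Kd-positive, single-protein records, a fraction
  of which are validated under two distinct assay ids to exercise the
  multi-assay confidence rule.

What it does not emulate: realistic medicinal-chemistry property
distributions, assay heterogeneity beyond the duplicated assay ids, or
protein-family structure beyond the planted motifs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from drift.chemio import MoleculeGraph, ProteinSeq, _mol_to_graph
from drift.cpinet.model import CPIPrediction, display_score
from drift.fingerprint2d import Fingerprint2D, fingerprint
from drift.targetpipe import InteractionRecord

AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_SCAFFOLDS = (
    "c1ccccc1",  # benzene
    "C1CCCCC1",  # cyclohexane
    "c1ccncc1",  # pyridine
    "C1CCOC1",  # tetrahydrofuran
    "c1ccsc1",  # thiophene
    "C1CCNCC1",  # piperidine
)

DEFAULT_SUBSTITUENTS = (
    "C",
    "CC",
    "CCC",
    "O",
    "OC",
    "N",
    "NC",
    "F",
    "Cl",
    "CO",
    "CCO",
    "CN",
    "S",
    "C=O",
)


@dataclass
class SynthConfig:
    n_compounds: int = 300
    n_proteins: int = 50
    seed: int = 0
    scaffold_set: tuple[str, ...] = DEFAULT_SCAFFOLDS
    decoration_rules: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    similarity_clusters: int = 6
    noise_sd: float = 0.3  # Gaussian noise on planted pKd, log10 units
    affinity_base: float = 3.5  # pKd floor of the bilinear map
    affinity_gain: float = 1.6  # slope per (scaffold overlap x motif count)
    motif_length: int = 4
    motif_copies: int = 3
    protein_length_range: tuple[int, int] = (40, 80)
    duplicate_assay_fraction: float = 0.3
    decoy_annotation_rate: float = 0.6
    n_affinity: int = 2000
    matched_fraction: float = 0.5  # affinity pairs drawn against cluster primaries

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.similarity_clusters > len(self.scaffold_set):
            raise ValueError("need at least one scaffold per cluster")


def random_molecule(
    rng: np.random.Generator, max_atoms: int = 12, mol_id: str = "rnd"
) -> MoleculeGraph:
    """Random connected molecule for property testing: a spanning tree of
    C/N/O/S with occasional double bonds and one optional ring closure,
    resampled until RDKit sanitization accepts it."""
    elements = ["C", "C", "C", "N", "O", "S"]
    while True:
        n = int(rng.integers(2, max_atoms + 1))
        rw = Chem.RWMol()
        for _ in range(n):
            rw.AddAtom(Chem.Atom(str(rng.choice(elements))))
        for i in range(1, n):
            j = int(rng.integers(0, i))
            order = Chem.BondType.DOUBLE if rng.random() < 0.15 else Chem.BondType.SINGLE
            rw.AddBond(i, j, order)
        if n >= 4 and rng.random() < 0.5:
            a, b = sorted(rng.choice(n, size=2, replace=False))
            if rw.GetBondBetweenAtoms(int(a), int(b)) is None:
                rw.AddBond(int(a), int(b), Chem.BondType.SINGLE)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        return _mol_to_graph(mol, mol_id, "smiles")


def cluster_of(mol_id: str) -> int:
    """Cluster index encoded in a synthetic mol_id (``c{cluster}_m{i}``)."""
    return int(mol_id.split("_")[0][1:])


def _decorate(scaffold: Chem.Mol, subs: list[str], rng: np.random.Generator) -> Chem.Mol | None:
    mol = Chem.RWMol(scaffold)
    for sub_smiles in subs:
        sub = Chem.MolFromSmiles(sub_smiles)
        anchors = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetTotalNumHs() > 0 and a.GetIdx() < scaffold.GetNumAtoms()
        ]
        if not anchors:
            return None
        anchor = int(rng.choice(anchors))
        offset = mol.GetNumAtoms()
        mol = Chem.RWMol(Chem.CombineMols(mol.GetMol(), sub))
        mol.AddBond(anchor, offset, Chem.BondType.SINGLE)
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return None
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def gen_compound_library(cfg: SynthConfig) -> list[MoleculeGraph]:
    """Decorate scaffolds into a clustered compound library.

    Compound ``i`` belongs to cluster ``i % similarity_clusters`` and is the
    corresponding scaffold with 1-3 random substituents; the cluster index
    is encoded in the mol_id (``c{cluster}_m{i:04d}``).
    """
    rng = np.random.default_rng(cfg.seed)
    scaffolds = []
    for s in cfg.scaffold_set[: cfg.similarity_clusters]:
        m = Chem.MolFromSmiles(s)
        if m is None:
            raise ValueError(f"invalid scaffold SMILES: {s!r}")
        scaffolds.append(m)
    library: list[MoleculeGraph] = []
    for i in range(cfg.n_compounds):
        cluster = i % cfg.similarity_clusters
        mol = None
        while mol is None:
            n_subs = int(rng.integers(1, 4))
            subs = [str(rng.choice(cfg.decoration_rules)) for _ in range(n_subs)]
            mol = _decorate(scaffolds[cluster], subs, rng)
        library.append(_mol_to_graph(mol, f"c{cluster}_m{i:04d}", "smiles"))
    return library


def gen_proteins(cfg: SynthConfig) -> tuple[list[ProteinSeq], list[str]]:
    """Random protein panel; the first ``similarity_clusters`` proteins are
    the primary targets, each carrying ``motif_copies`` inserts of its
    cluster's planted motif.

    Returns ``(proteins, motifs)``; ``motifs[c]`` is cluster c's k-mer.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.protein_length_range
    motifs = [
        "".join(rng.choice(list(AA), size=cfg.motif_length)) for _ in range(cfg.similarity_clusters)
    ]
    proteins: list[ProteinSeq] = []
    for p in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(AA), size=length))
        if p < cfg.similarity_clusters:
            motif = motifs[p]
            for _ in range(cfg.motif_copies):
                pos = int(rng.integers(0, len(seq) - cfg.motif_length + 1))
                seq[pos : pos + cfg.motif_length] = list(motif)
        proteins.append(ProteinSeq(prot_id=f"P{p:03d}", sequence="".join(seq)))
    return proteins, motifs


class PlantedAffinityModel:
    """The planted bilinear affinity map, usable as an oracle scorer.

    pKd(x, p) = base + gain * sum_c overlap_c(x) * motifcount_c(p), where
    overlap_c(x) is the fraction of cluster c's scaffold fingerprint bits
    present in x's fingerprint and motifcount_c(p) counts occurrences of
    cluster c's motif in p's sequence.  This is a bilinear form of the
    compound's fingerprint bit vector and the protein's motif-count vector.
    """

    def __init__(self, cfg: SynthConfig):
        self.cfg = cfg
        self.scaffold_fps: list[Fingerprint2D] = []
        for s in cfg.scaffold_set[: cfg.similarity_clusters]:
            g = _mol_to_graph(Chem.MolFromSmiles(s), s, "smiles")
            self.scaffold_fps.append(fingerprint(g))
        _, self.motifs = gen_proteins(cfg)
        self._fp_cache: dict[str, Fingerprint2D] = {}

    def motif_counts(self, prot: ProteinSeq) -> np.ndarray:
        return np.array(
            [prot.sequence.count(m) for m in self.motifs], dtype=float
        )

    def _fp(self, mol: MoleculeGraph) -> Fingerprint2D:
        fp = self._fp_cache.get(mol.mol_id)
        if fp is None:
            fp = fingerprint(mol)
            self._fp_cache[mol.mol_id] = fp
        return fp

    def overlaps(self, mol: MoleculeGraph) -> np.ndarray:
        fp = self._fp(mol)
        out = np.zeros(len(self.scaffold_fps))
        for c, sfp in enumerate(self.scaffold_fps):
            shared = int(np.bitwise_and(fp.bits, sfp.bits).sum())
            out[c] = shared / max(sfp.n_set, 1)
        return out

    def affinity(self, mol: MoleculeGraph, prot: ProteinSeq) -> float:
        """Noiseless planted pKd."""
        return float(
            self.cfg.affinity_base
            + self.cfg.affinity_gain * self.overlaps(mol) @ self.motif_counts(prot)
        )

    def predict(self, mol: MoleculeGraph, prot: ProteinSeq) -> CPIPrediction:
        aff = self.affinity(mol, prot)
        attn = np.full((1, len(prot.sequence)), 1.0 / len(prot.sequence))
        return CPIPrediction(affinity=aff, score=display_score(aff), attention=attn)

    predict_affinity = predict


def gen_annotation_db(
    cfg: SynthConfig,
    library: list[MoleculeGraph],
    proteins: list[ProteinSeq],
) -> tuple[list[InteractionRecord], dict[str, list[str]]]:
    """Annotation records plus the planted compound -> true-target table.

    Each compound is annotated with its cluster's primary target (the
    planted truth); a ``decoy_annotation_rate`` fraction get 1-2 extra
    weak-affinity records against random other proteins.  A
    ``duplicate_assay_fraction`` of interactions appear under two distinct
    assay ids (multi-assay validated).  All Kd values are positive and all
    targets are single proteins, so every record passes ingest filtering.
    """
    if not library or not proteins:
        raise ValueError("library and protein panel must be nonempty")
    rng = np.random.default_rng(cfg.seed + 2)
    planted = PlantedAffinityModel(cfg)
    records: list[InteractionRecord] = []
    truth: dict[str, list[str]] = {}
    assay_counter = 0

    def add_interaction(mol: MoleculeGraph, prot: ProteinSeq) -> None:
        nonlocal assay_counter
        pkd = planted.affinity(mol, prot) + rng.normal(0, cfg.noise_sd)
        kd_nm = float(10 ** (9.0 - pkd))
        n_assays = 2 if rng.random() < cfg.duplicate_assay_fraction else 1
        smiles = Chem.MolToSmiles(mol.rdmol)
        for _ in range(n_assays):
            assay_counter += 1
            records.append(
                InteractionRecord(
                    compound_id=mol.mol_id,
                    smiles=smiles,
                    target_id=prot.prot_id,
                    target_sequence=prot.sequence,
                    affinity_value=kd_nm,
                    measure_type="Kd",
                    assay_id=f"A{assay_counter:05d}",
                )
            )

    for mol in library:
        c = cluster_of(mol.mol_id)
        primary = proteins[c]
        add_interaction(mol, primary)
        truth[mol.mol_id] = [primary.prot_id]
        if rng.random() < cfg.decoy_annotation_rate:
            for _ in range(int(rng.integers(1, 3))):
                other = proteins[int(rng.integers(cfg.similarity_clusters, len(proteins)))]
                add_interaction(mol, other)
    return records, truth


def gen_affinity_data(
    cfg: SynthConfig,
    library: list[MoleculeGraph],
    proteins: list[ProteinSeq],
) -> list[tuple[MoleculeGraph, ProteinSeq, float]]:
    """Sample (compound, protein, pKd) triples from the planted map.

    A ``matched_fraction`` of pairs are drawn against cluster primary
    targets (high affinity when the compound's own cluster matches, low
    otherwise); the rest are uniform over the panel.  Noise is Gaussian
    with sd ``noise_sd``.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    planted = PlantedAffinityModel(cfg)
    out = []
    for _ in range(cfg.n_affinity):
        mol = library[int(rng.integers(len(library)))]
        if rng.random() < cfg.matched_fraction:
            prot = proteins[int(rng.integers(cfg.similarity_clusters))]
        else:
            prot = proteins[int(rng.integers(len(proteins)))]
        pkd = planted.affinity(mol, prot)
        if cfg.noise_sd > 0:
            pkd += rng.normal(0, cfg.noise_sd)
        out.append((mol, prot, float(pkd)))
    return out


def write_world(cfg: SynthConfig, out_dir: str) -> dict[str, str]:
    """Generate everything and write the standard file set to ``out_dir``."""
    import os

    from drift.chemio import write_proteins_fasta

    os.makedirs(out_dir, exist_ok=True)
    library = gen_compound_library(cfg)
    proteins, motifs = gen_proteins(cfg)
    records, truth = gen_annotation_db(cfg, library, proteins)
    triples = gen_affinity_data(cfg, library, proteins)
    paths = {
        "library": os.path.join(out_dir, "library.smi"),
        "proteins": os.path.join(out_dir, "proteins.fasta"),
        "anno": os.path.join(out_dir, "anno.tsv"),
        "affinities": os.path.join(out_dir, "affinities.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    with open(paths["library"], "w") as fh:
        for mol in library:
            fh.write(f"{Chem.MolToSmiles(mol.rdmol)}\t{mol.mol_id}\n")
    write_proteins_fasta(proteins, paths["proteins"])
    from drift.targetpipe import write_annotation_db

    write_annotation_db(records, paths["anno"])
    with open(paths["affinities"], "w") as fh:
        fh.write("compound_id\tprot_id\tsmiles\tsequence\taffinity\n")
        for mol, prot, pkd in triples:
            fh.write(
                f"{mol.mol_id}\t{prot.prot_id}\t{Chem.MolToSmiles(mol.rdmol)}"
                f"\t{prot.sequence}\t{pkd:.4f}\n"
            )
    with open(paths["truth"], "w") as fh:
        json.dump({"motifs": motifs, "targets": truth}, fh, indent=1)
    return paths
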