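# Methods

This note documents the models and procedures implemented in `drift`, the
parameters that matter, the synthetic data the package is validated on, and
the design choices made where the design was genuinely open.

## Molecule and protein representation

Molecules are parsed with RDKit from SMILES, SDF (V2000) or MOL2 into a
light graph view: ordered atom records (element, bond count, mass, formal
charge, ring flag, implicit-H count) and bond records (order in {1, 2, 3,
aromatic}, ring flag). Ring perception runs at load time with
smallest-set-of-smallest-rings semantics; aromatic bonds keep a distinct
order value rather than being Kekulized, because both the fingerprint's
ring-termination rule and the fragmenter consume ring membership, not a
Kekulé structure. Atom indexing is 0-based internally; 1-based file formats
are translated at the boundary. Hydrogens implicit in SMILES are stored as
counts and never materialized; explicit hydrogens present in SDF/MOL2 are
kept as atoms. Fingerprinting operates on heavy atoms only and
fragmentation merges hydrogens into their heavy atom's cluster (bonds to H
are non-rotatable by default) — both switchable.

Conformers are generated by seeded ETKDG distance-geometry embedding
followed by MMFF relaxation; conformer *i* of a run uses seed `seed + i`,
so the first conformer of a k=10 run equals the k=1 conformer and repeated
runs are bit-stable on one platform. Compounds above `max_atoms` (default
50, the pharmacophore database's size cap) are rejected by the 3D arm and
handled 2D-only by the pipeline.

Proteins are FASTA records or raw strings, uppercased, with non-standard
residue symbols preserved.

## 2D fingerprint

A path-based 1024-bit fingerprint over linear fragments of 1–7 heavy
atoms, generated under four conditions: (i) at most seven atoms per
fragment; (ii) single-atom fragments of C, O and N are ignored; (iii)
duplicate fragments are recorded once; (iv) fragment growth terminates at
ring structures. Each fragment's canonical descriptor (element sequence,
bond orders, ring flags, read in the lexicographically smaller direction)
is hashed with FNV-1a modulo 1024. Bit-exact compatibility with other
path-fingerprint implementations is not promised — the hash is this
package's own documented, stable choice; what is contracted is the
generation conditions, which the tests check exhaustively against an
independent enumerator on small molecules.

Condition (iv) is ambiguous in isolation; two readings are implemented
behind `ring_termination`:

- `"ring-system"` (default): a path may run through a fused ring system
  contiguously but may never re-enter a ring system it has left.
  Equivalently: each ring system's atoms occupy contiguous positions along
  the path. This keeps ring bonds path-eligible, so ring-containing bits
  exist.
- `"closure"`: growth stops at the step that would close a cycle — the
  candidate atom may not be bonded to any non-terminal path atom.

Tanimoto similarity is c/(a+b−c) over set bits. The 0/0 case (two empty
fingerprints, e.g. two methane queries in heavy-atom mode) is defined as
1.0 — the identity convention — with a warning. The search index stores
packed fingerprints and scans them vectorised; search output is contracted
to equal a brute-force all-pairs scan, with ties in Tc broken by mol_id.
The default search threshold is Tc ≥ 0.85, the conventional similarity
cutoff; it is a parameter.

## 3D pharmacophore key

Features are extracted from a conformer by documented rules: one aromatic
feature per aromatic ring at its centroid; H-donors (N/O/S with an H),
H-acceptors (uncharged, non-quaternary N; uncharged O), positive/negative
ionizable groups (formal charges, primary aliphatic amines, carboxylic
acids), and hydrophobic features as centroids of connected clusters of ≥ 2
aliphatic carbons with no heteroatom neighbours. For every unordered
feature triplet, the sorted (kind, opposite-edge distance bin) descriptor —
bin width 1.0 Å, capped at 20 Å — is hashed into a 4096-bit key; molecules
with fewer than three features hash pairs or singletons so they remain
searchable. Keys depend only on inter-feature distances and are therefore
invariant to rigid motion.

A library molecule's database key is the union of its conformer keys; a
query is scored by the fraction of its conformer key's bits present in the
database key, maximised over query conformers. Because conformer seeds are
nested, raising the query conformer count can only add keys, so every
molecule's score — and hence retrieval recall — is non-decreasing in the
number of conformers searched (the package's tests fix seeds and check
k ∈ {1, 2, 5, 10}). The default acceptance overlap is 0.5; the proprietary
tetrahedral layout of published pharmacophore-fingerprint tools is
deliberately not reproduced — acceptance here is behavioural
(self-retrieval, monotonicity), not bit compatibility.

## Fragmentation

Bonds are labelled non-rotatable iff they are in a ring or have order
above single (plus bonds to hydrogen by default). Amide and conjugated
single bonds stay rotatable — no chemistry-aware exceptions are added to
the stated rule — with a `strict_amide` flag for the medicinal-chemistry
convention. Fragments are the connected components of the non-rotatable
subgraph, computed by iterative cluster merging (union-find); the
invariants (disjoint cover, rotatable cut set) are asserted on every call,
and the tests cross-check against an independent connected-components
oracle. Cross-molecule fragment identity uses RDKit's canonical fragment
SMILES of the cluster-induced subgraph, a deterministic canonical
labeling; frequency ranking across a pool sorts by count with
deterministic key tie-breaks.

## Interaction network

Protein input: per-residue BLOSUM62 substitution profiles over the 20
standard amino acids (scaled by 0.1 to keep features O(1)), zeros for
non-standard residues, concatenated with sinusoidal positional channels
(default 16). Positions are encoded on the protein side only: residue
order determines structure, whereas fragment order in a compound is
arbitrary, and the affinity is contracted to be invariant under fragment
permutation (tested) while sensitive to residue order (tested).

Architecture: three 1D convolutions (kernel 7, ReLU, same padding) on the
protein; two graph convolutions with order-weighted sum message passing
(aromatic bonds weigh 1.5) on the compound; mean-pooling of atom
embeddings into fragments; five feature-wise fully connected layers on
each side; a single-head cross-attention in which fragments attend over
residues (softmax over residues, scaled dot product); the attended context
gates the fragment embeddings elementwise, the gated embeddings are
mean-pooled and a small ReLU head emits pKd. Attention rows are
non-negative and sum to 1 within 1e-5 by construction. The display score
is `1/(1+exp(-(pKd-6)))` — a logistic squashing centred at pKd 6 (1 µM),
mapping tight binders toward 1.

Defaults where no external constraint exists: hidden width 128, learning
rate 1e-4, single attention head, mean joint pooling — all surfaced in
`ModelConfig`/`TrainConfig`. Training minimises MSE on pKd with Adam,
mini-batch 8 (gradient accumulation over variable-size graphs), and a
seeded 8:2 split; NaN loss aborts with a diagnostic. The whole network is
NumPy with hand-written analytic gradients, checked in the tests against
central finite differences at 1e-4 relative tolerance (with an absolute
floor of 1e-6 for near-zero gradients, where finite differences lose
precision).

Fragment ranking: softmax rows each sum to 1, so plain attention row mass
cannot separate fragments; the default statistic is therefore the
attention-weighted residue salience, with salience the norm of the
residue's value vector — the fragment whose attention mass sits on
residues that contribute most to the prediction ranks first. `"max"` (peak
attention weight) and `"uniform"` (row mass, which degrades to the
documented fragment-index tie order) are selectable.

## Pipeline

Bait search is the deduplicated union of the 2D and 3D arms (both scores
kept as provenance); oversize queries trigger a logged 2D-only fallback.
Target retrieval groups the baits' annotation records by target;
`n_assays` is the largest number of distinct assay ids supporting any
single bait–target link, and the confidence rule is exactly: more than one
assay → high, otherwise low. Ranking uses the interaction model's score
alone — similarity scores are reported, not blended (a deliberate default;
the candidate set is already similarity-gated). An `exclude_self` mode
drops the query's own annotation records before retrieval and can only
shrink the candidate set. The report (baits, ranked targets, fragment
frequency profile over query plus baits, notices) is validated by pydantic
models whose published JSON schema is `docs/report.schema.json`; reruns
with the same config are byte-identical.

Dataset compilation rules for evaluation: keep proteins with ≥ 20
associated compounds (similar-compound retrieval datasets) or compounds
with ≥ 5 associated targets (target-identification datasets); both filters
only ever subset their input. Metrics: recall/precision/F over predicted
vs true target sets (ranked output is cut at display score 0.5 by default,
configurable), ROC AUC in the Mann–Whitney formulation with ties counted
half (contracted to equal exhaustive pair counting), and Pearson
correlation for affinity regression.

## Synthetic data: what it emulates and what it does not

The generator plants recoverable structure end to end. Compounds are
scaffold decorations — cluster c is scaffold c with 1–3 random
substituents — giving high within-cluster and low between-cluster
Tanimoto. Proteins are random 40–80-mers over the 20-letter alphabet; the
first `similarity_clusters` proteins each carry 3 copies of a planted
4-mer motif. Affinity is a bilinear form of fingerprint bits and
motif-count features: pKd = 3.5 + 1.6 · Σ_c overlap_c(compound) ·
motifcount_c(protein), putting a compound's own primary target near pKd 8
and everything else near 4, plus Gaussian noise with sd 0.3 pKd units —
the order of typical inter-assay variability. Annotation records (all
Kd-positive, single-protein) include the primary-target link per compound,
decoy links to random proteins at rate 0.6, and a 0.3 fraction of
interactions duplicated under two assay ids to exercise the confidence
rule. The planted map itself is exposed as an oracle scorer; with zero
noise it ranks the planted target first for every query, which separates
retrieval defects from model-fitting defects.

What the generator does not emulate: realistic medicinal-chemistry
property distributions, assay heterogeneity beyond duplicated ids,
protein-family structure, or activity cliffs. Passing tests therefore
demonstrate that the machinery is correct and that the network can recover
a planted signal at desk scale; they do not certify accuracy on real
annotation databases, which differ in size, noise structure and chemistry.

## Problem sizes and numerical choices

The trained-network checks use a deliberate desk-scale study: 120
compounds in 4 clusters, 20 proteins, 400 affinity triples, hidden width
32, positional dim 8, learning rate 1e-3, 80 epochs, batch 8 — chosen so
the full suite trains in well under a minute on one CPU while leaving a
wide margin over the 0.6 held-out correlation bar (typically r ≈ 0.85) and
ranking the planted target first for ≥ 80% of queries end to end (the
pharmacophore arm of that experiment uses 3 conformers; the monotonicity
experiment uses the full 1/2/5/10 ladder). Degenerate inputs are defined,
not left to chance: empty-vs-empty Tanimoto is 1.0 with a warning, empty
pharmacophore feature sets give all-zero keys and score 0, single-fragment
attention ranking returns weight 1, ties everywhere break by identifier or
index.

## Known limitations

- Fingerprint and pharmacophore layouts are self-consistent but not
  interchange formats; indexes must be rebuilt to compare across tools.
- The 3D feature rules are minimal SMARTS-style definitions; tautomers,
  protonation states and stereochemistry-aware matching are out of scope.
- The fragmenter follows the stated rotatable-bond rule; amide rigidity is
  opt-in only.
- Training is CPU-NumPy and intended for desk-scale experiments, not for
  full public-database-scale benchmarks.
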