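# drift

Proteome-wide compound–target identification by chemical similarity search
and attention-based interaction ranking.

Off-target binding is a leading cause of toxic side effects and failed
trials, but screening a compound against the whole proteome experimentally
is prohibitively expensive. `drift` addresses this computationally, for
medicinal chemists and computational biologists: given a query compound, it

1. **finds chemically similar annotated "bait" compounds** — by 2D
   path-based 1024-bit fingerprints under the Tanimoto coefficient
   *Tc(A,B) = c / (a + b − c)* (with *a*, *b* the set-bit counts of the two
   fingerprints and *c* their shared bits; *Tc* ≥ 0.85 is the conventional
   similarity threshold), unioned with a 3D pharmacophore arm that matches
   hashed feature triplets (donor/acceptor/aromatic/hydrophobic/ionizable
   kinds with distance-binned geometry) over multiple seeded conformers;
2. **retrieves the baits' annotated protein targets** from a curated
   interaction table (positive Kd, single-protein targets);
3. **ranks the candidate targets** with a compound–protein interaction
   network: the protein is encoded residue-wise by BLOSUM62 profiles plus
   sinusoidal positional channels and passed through three 1D convolutions;
   the compound graph (atom features *V*, bond orders *E*) passes through
   two graph convolutions and is pooled into rotatable-bond fragments; both
   sides go through five feature-wise fully connected layers, and a
   fragment-over-residue cross-attention head produces a binding affinity
   (pKd = −log₁₀ Kd[M]) plus an F×L attention map. Targets validated in
   more than one assay are labelled **high confidence**;
4. **identifies the compound fragments that drive the interaction** — the
   fragments are maximal clusters of atoms joined by non-rotatable bonds
   (ring bonds and bonds of order > 1), ranked by the attention layer, and
   profiled by frequency across the bait pool (a Zipf-like distribution in
   which single –C– and –O– fragments lead and scaffold cores follow).

The network is a NumPy implementation with hand-written analytic gradients
(verified against finite differences in the test suite) trained by MSE on
pKd with Adam, mini-batches of 8, and a seeded 8:2 train/test split.

## Worked example

`examples/end_to_end_targets.py` builds a synthetic annotated world with a
planted ground truth and runs the full pipeline:

```
query c0_m0000: 1 baits, 3 targets
  P000  score=0.909  high  via 1 bait(s)
  P004  score=0.076  low  via 1 bait(s)
  P009  score=0.076  low  via 1 bait(s)
planted true target: P000 (should rank first)
top fragments: C, N, S
```

The query's bait (itself, Tc = 1.0) is annotated against three proteins;
the scorer puts the planted true target P000 first with display score 0.909
(the logistic squashing of pKd centred at 6), and its multi-assay support
earns the high-confidence label. `examples/train_interaction_model.py`
trains the network on 400 planted affinity triples and prints

```
epoch  0: train MSE 3.030  test MSE 2.632
epoch 39: train MSE 0.396  test MSE 0.714
held-out Pearson r = 0.851
```

— the held-out correlation against the planted bilinear affinity map, well
above the 0.6 recovery bar. The other examples cover similarity search and
fragmentation. A thin CLI mirrors the library:
`drift synth | index build | index pharma | fragment | train | targets | eval`.

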