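"""Similarity search: find annotated neighbours of a query compound.

Builds a small clustered library, indexes its 1024-bit path fingerprints,
and searches it with one of its own members.  The Tanimoto coefficient
Tc = c/(a+b-c) is 1.0 for an identical fingerprint and conventionally
>= 0.85 for "structurally similar" compounds.
"""

from drift.fingerprint2d import build_index, fingerprint, search_2d
from drift.synthdata import SynthConfig, gen_compound_library

library = gen_compound_library(SynthConfig(n_compounds=60, similarity_clusters=3, seed=5))
index = build_index(library)

query = library[0]
hits = search_2d(fingerprint(query), index, tc_min=0.5)

print(f"query: {query.mol_id}")
for hit in hits[:8]:
    print(f"  {hit.mol_id}  Tc={hit.tc:.3f}")
print(
    f"{len(hits)} library compounds have Tc >= 0.5; the top hit is the query "
    "itself (Tc=1.0), and the next hits share its scaffold cluster."
)
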