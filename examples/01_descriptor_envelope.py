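"""Stage 1: derive a descriptor envelope from actives and filter a library.

Generates a synthetic drug-like library, derives the per-descriptor [min,max]
box from the bundled query actives, and keeps only compounds inside the box
on all six axes (MW, TPSA, logP, HBD, HBA, rotatable bonds).
"""

from rdkit import Chem

from vsfunnel import (
    MoleculeRecord,
    apply_envelope_filter,
    compute_descriptors,
    derive_envelope,
    lipinski_pass,
    standardize,
)
from vsfunnel.datasets import TNF_ACTIVES_ENVELOPE, query_actives_smiles_synthetic
from vsfunnel.synthetic import generate_library

library = generate_library(500, seed=11)
actives = [
    standardize(MoleculeRecord(qid, Chem.MolFromSmiles(smi)))
    for qid, smi in query_actives_smiles_synthetic()
]

derived = derive_envelope([compute_descriptors(a) for a in actives])
print("envelope derived from", len(actives), "actives:")
for name, (lo, hi) in derived.bounds.items():
    print(f"  {name:>5}: [{lo:.2f}, {hi:.2f}]")

survivors = apply_envelope_filter(library, TNF_ACTIVES_ENVELOPE)
print(f"\nreference envelope keeps {len(survivors)}/{len(library)} compounds")
# survivors sit in the property box spanned by known actives — the cheap
# first triage of a screening funnel

first = survivors.records[0]
passed, violations = lipinski_pass(compute_descriptors(first))
print(f"rule-of-five on {first.id}: pass={passed} violations={violations}")
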