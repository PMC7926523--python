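"""166-bit structural-key fingerprints and Tanimoto similarity screening.

The second funnel stage keeps compounds whose best Tanimoto similarity to any
query active reaches a threshold (default 0.85, applied as ≥). Fingerprints
are the public 166 MDL-style structural keys as defined by the cheminformatics
toolkit (dialect recorded in :data:`FINGERPRINT_DIALECT`); the Tanimoto
coefficient |A∩B| / |A∪B| is computed here on the on-bit sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd
from rdkit.Chem import MACCSkeys

from .chemio import CompoundLibrary, MoleculeRecord

logger = logging.getLogger("vsfunnel")

__all__ = [
    "StructuralKeyFingerprint",
    "FINGERPRINT_DIALECT",
    "fingerprint",
    "tanimoto",
    "similarity_screen",
]

FINGERPRINT_DIALECT = "rdkit-maccs-166"
N_KEYS = 166


@dataclass(frozen=True)
class StructuralKeyFingerprint:
    """Set of on keys, indices in 1..166."""

    bits: frozenset

    def __post_init__(self):
        if any(b < 1 or b > N_KEYS for b in self.bits):
            raise ValueError("key index outside 1..166")

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def __len__(self) -> int:
        return N_KEYS


def fingerprint(mol_or_record) -> StructuralKeyFingerprint:
    """Structural-key fingerprint of a standardized molecule (deterministic)."""
    mol = mol_or_record.mol if isinstance(mol_or_record, MoleculeRecord) else mol_or_record
    if mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, index 0 unused
    return StructuralKeyFingerprint(frozenset(int(b) for b in bv.GetOnBits() if b >= 1))


def tanimoto(a: StructuralKeyFingerprint, b: StructuralKeyFingerprint) -> float:
    """|A∩B| / |A∪B|; 0 by convention when both key sets are empty."""
    if len(a) != len(b):
        raise ValueError("fingerprint length mismatch")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def similarity_screen(
    library: CompoundLibrary,
    queries,
    threshold: float = 0.85,
):
    """Keep records whose max similarity over the queries is ≥ threshold.

    Returns ``(hits_library, hits_table)``; the table has columns
    id, best_query, similarity. Each hit record carries its best-matching
    query id and similarity in ``properties`` (ties broken by query order).
    """
    queries = list(queries)
    if not queries:
        raise ValueError("similarity screen requires at least one query")
    query_fps = [(q.id, fingerprint(q)) for q in queries]

    survivors, rows = [], []
    for rec in library:
        fp = fingerprint(rec)
        best_sim, best_query = -1.0, None
        for qid, qfp in query_fps:
            sim = tanimoto(fp, qfp)
            if sim > best_sim:
                best_sim, best_query = sim, qid
        if best_sim >= threshold:
            annotated = replace(
                rec,
                properties=dict(
                    rec.properties,
                    best_query=best_query,
                    best_similarity=best_sim,
                    fingerprint_dialect=FINGERPRINT_DIALECT,
                ),
            )
            survivors.append(annotated)
            rows.append({"id": rec.id, "best_query": best_query, "similarity": best_sim})

    logger.info("stage=similarity_screen in=%d out=%d", len(library), len(survivors))
    hits = CompoundLibrary(survivors, provenance=library.provenance)
    return hits, pd.DataFrame(rows, columns=["id", "best_query", "similarity"])
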