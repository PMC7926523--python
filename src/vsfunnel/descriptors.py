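"""Physicochemical descriptors, active-set envelopes and envelope filtering.

The first funnel stage reduces a large library to the region of descriptor
space occupied by known actives: six descriptors (molecular weight, TPSA,
logP, H-bond donors/acceptors, rotatable bonds) are computed per compound,
a closed per-descriptor [min, max] interval box ("envelope") is derived from
the actives, and only compounds inside the box on every axis survive.

Counting convention: hbd is the number of N/O atoms bearing at least one
hydrogen (so water counts 1 donor group), hba the number of N plus O atoms —
the classic rule-of-five convention. The same convention is used for the
envelope and for the Lipinski check, and is deliberately group-based rather
than RDKit's stricter pharmacophoric donor/acceptor typing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .chemio import CompoundLibrary, MoleculeRecord

logger = logging.getLogger("vsfunnel")

__all__ = [
    "DescriptorVector",
    "DescriptorEnvelope",
    "DESCRIPTOR_NAMES",
    "compute_descriptors",
    "derive_envelope",
    "apply_envelope_filter",
    "lipinski_pass",
    "descriptor_table",
]

DESCRIPTOR_NAMES = ("mw", "tpsa", "logp", "hbd", "hba", "rotb")

_HBD_QUERY = Chem.MolFromSmarts("[#7,#8;!H0]")
_HBA_QUERY = Chem.MolFromSmarts("[#7,#8]")


@dataclass(frozen=True)
class DescriptorVector:
    """Six physicochemical descriptors of one compound."""

    mw: float      # molecular weight, Da
    tpsa: float    # topological polar surface area, Å²
    logp: float    # octanol/water partition (atomic-contribution estimate)
    hbd: int       # N/O atoms bearing ≥1 H
    hba: int       # N + O atom count
    rotb: int      # rotatable bonds (amide and ring bonds excluded)

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if self.tpsa < 0 or self.hbd < 0 or self.hba < 0 or self.rotb < 0:
            raise ValueError("descriptor out of range")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class DescriptorEnvelope:
    """Closed [min, max] interval per descriptor."""

    bounds: dict  # name -> (lo, hi)

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if name not in DESCRIPTOR_NAMES:
                raise ValueError(f"unknown descriptor {name!r}")
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")

    def contains(self, vec: DescriptorVector) -> bool:
        values = vec.as_dict()
        return all(lo <= values[name] <= hi for name, (lo, hi) in self.bounds.items())

    def __getitem__(self, name: str):
        return self.bounds[name]


def compute_descriptors(mol_or_record) -> DescriptorVector:
    """Descriptor vector for a standardized molecule.

    TPSA follows the fragment-contribution scheme, logP the atomic-contribution
    (Crippen) scheme; both are deterministic and atom-order independent.
    """
    mol = mol_or_record.mol if isinstance(mol_or_record, MoleculeRecord) else mol_or_record
    if mol.GetNumAtoms() == 0:
        raise ValueError("molecule has no atoms")
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        tpsa=Descriptors.TPSA(mol),
        logp=Crippen.MolLogP(mol),
        hbd=len(mol.GetSubstructMatches(_HBD_QUERY)),
        hba=len(mol.GetSubstructMatches(_HBA_QUERY)),
        rotb=Descriptors.NumRotatableBonds(mol),
    )


def derive_envelope(actives) -> DescriptorEnvelope:
    """Per-descriptor min/max over a nonempty list of active descriptor vectors."""
    actives = list(actives)
    if not actives:
        raise ValueError("cannot derive an envelope from zero actives")
    bounds = {}
    for name in DESCRIPTOR_NAMES:
        values = [getattr(v, name) for v in actives]
        bounds[name] = (min(values), max(values))
    return DescriptorEnvelope(bounds)


def apply_envelope_filter(library: CompoundLibrary, env: DescriptorEnvelope) -> CompoundLibrary:
    """Keep exactly the records whose every descriptor lies inside the envelope."""
    survivors = [rec for rec in library if env.contains(compute_descriptors(rec))]
    logger.info("stage=descriptor_filter in=%d out=%d", len(library), len(survivors))
    return CompoundLibrary(survivors, provenance=library.provenance)


def lipinski_pass(desc: DescriptorVector):
    """Rule-of-five check: pass iff at most one violation.

    Returns ``(passed, violations)`` where violations lists the failed rules.
    """
    violations = []
    if desc.mw > 500:
        violations.append("mw > 500")
    if desc.logp > 5:
        violations.append("logp > 5")
    if desc.hbd > 5:
        violations.append("hbd > 5")
    if desc.hba > 10:
        violations.append("hba > 10")
    return len(violations) <= 1, violations


def descriptor_table(library: CompoundLibrary) -> pd.DataFrame:
    """Descriptor CSV export: columns id,mw,tpsa,logp,hbd,hba,rotb."""
    rows = []
    for rec in library:
        row = {"id": rec.id}
        row.update(compute_descriptors(rec).as_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", *DESCRIPTOR_NAMES])
    if df.isna().any().any() or any(
        not math.isfinite(x) for x in df[list(DESCRIPTOR_NAMES)].to_numpy().ravel()
    ):
        raise ValueError("non-finite descriptor value")
    return df
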