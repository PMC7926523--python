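"""Molecule data model, standardization, conformer embedding and file I/O.

Molecules are carried as RDKit ``Mol`` objects wrapped in :class:`MoleculeRecord`
together with a stable identifier and a free-form property map (SDF tags, screen
annotations). Libraries preserve record order and enforce unique ids, so a
read→write→read round trip is the identity on ids and connection tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("vsfunnel")

__all__ = [
    "MoleculeRecord",
    "CompoundLibrary",
    "ParseReport",
    "StandardizationError",
    "read_library",
    "write_library",
    "standardize",
    "standardize_library",
    "embed_conformers",
]


class StandardizationError(ValueError):
    """Raised when a molecule cannot be brought to a valid standard form."""


@dataclass
class MoleculeRecord:
    """A single compound: identifier, RDKit molecule, property map.

    Conformers (3D coordinate sets, Å) live on the RDKit molecule itself.
    """

    id: str
    mol: Chem.Mol
    properties: dict = field(default_factory=dict)

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def num_bonds(self) -> int:
        return self.mol.GetNumBonds()

    @property
    def num_conformers(self) -> int:
        return self.mol.GetNumConformers()

    def conformer(self, index: int = 0):
        """Coordinates of one conformer as an (n_atoms, 3) float array (Å)."""
        import numpy as np

        return np.asarray(self.mol.GetConformer(index).GetPositions(), dtype=float)

    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.mol))


@dataclass
class ParseReport:
    kept: int = 0
    dropped: int = 0
    reasons: list = field(default_factory=list)

    def log(self, stage: str = "read") -> None:
        logger.info("stage=%s kept=%d dropped=%d", stage, self.kept, self.dropped)


@dataclass
class CompoundLibrary:
    """Ordered collection of records with unique ids."""

    records: list
    provenance: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate compound id in library: {dup!r}")
        self._index = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def get(self, rec_id: str) -> MoleculeRecord:
        return self._index[rec_id]

    @property
    def ids(self) -> list:
        return [r.id for r in self.records]

    def subset(self, keep_ids, provenance: str = "") -> "CompoundLibrary":
        keep = set(keep_ids)
        return CompoundLibrary(
            [r for r in self.records if r.id in keep],
            provenance or self.provenance,
        )


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".smi", ".smiles", ".txt"):
        return "smiles"
    if suffix in (".sdf", ".sd", ".mol"):
        return "sdf"
    raise ValueError(f"cannot infer library format from {path.name!r}")


def read_library(path, fmt: str | None = None) -> CompoundLibrary:
    """Read a compound library from a SMILES (.smi) or SDF (V2000) file.

    Entries that fail to parse are skipped and counted in the parse report
    attached as ``library.report``. Raises if the file is unreadable or yields
    zero valid records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    report = ParseReport()
    records: list[MoleculeRecord] = []

    if fmt == "smiles":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smi = parts[0]
                rec_id = parts[1].strip() if len(parts) > 1 else f"MOL{lineno:06d}"
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    report.dropped += 1
                    report.reasons.append(f"line {lineno}: unparsable SMILES")
                    continue
                records.append(MoleculeRecord(rec_id, mol))
                report.kept += 1
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                report.dropped += 1
                report.reasons.append(f"entry {i}: unparsable mol block")
                continue
            rec_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"MOL{i + 1:06d}"
            props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
            records.append(MoleculeRecord(rec_id, mol, props))
            report.kept += 1
    else:
        raise ValueError(f"unknown format {fmt!r}")

    report.log("read")
    if not records:
        raise ValueError(f"zero valid records in {path} (dropped {report.dropped})")
    lib = CompoundLibrary(records, provenance=f"{path.name} [{fmt}]")
    lib.report = report
    return lib


def write_library(library: CompoundLibrary, path, fmt: str | None = None) -> None:
    """Write a library as SMILES lines or an SDF file."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "smiles":
        with open(path, "w") as fh:
            for rec in library:
                fh.write(f"{rec.smiles()}\t{rec.id}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        for rec in library:
            mol = Chem.Mol(rec.mol)
            if mol.GetNumConformers() == 0:
                AllChem.Compute2DCoords(mol)
            mol.SetProp("_Name", rec.id)
            for key, value in rec.properties.items():
                mol.SetProp(str(key), str(value))
            writer.write(mol)
        writer.close()
    else:
        raise ValueError(f"unknown format {fmt!r}")


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Return the record in standard form.

    Keeps the largest covalent fragment, neutralizes charges where a neutral
    form exists, and makes hydrogens explicit. Idempotent and deterministic.
    """
    mol = Chem.Mol(record.mol)
    try:
        mol = Chem.RemoveHs(mol)
        mol = rdMolStandardize.FragmentParent(mol)
        mol = rdMolStandardize.Uncharger().uncharge(mol)
        Chem.SanitizeMol(mol)
        mol = Chem.AddHs(mol)
    except Exception as exc:  # RDKit raises several internal types
        raise StandardizationError(f"{record.id}: {exc}") from exc
    return replace(record, mol=mol)


def standardize_library(library: CompoundLibrary) -> CompoundLibrary:
    """Standardize every record; records that fail are dropped and logged."""
    kept, dropped = [], 0
    for rec in library:
        try:
            kept.append(standardize(rec))
        except StandardizationError as exc:
            dropped += 1
            logger.info("stage=standardize dropped id=%s reason=%s", rec.id, exc)
    logger.info("stage=standardize in=%d out=%d", len(library), len(kept))
    return CompoundLibrary(kept, provenance=library.provenance)


def embed_conformers(record: MoleculeRecord, n: int = 10, seed: int = 0) -> MoleculeRecord:
    """Attach up to ``n`` 3D conformers (ETKDG embedding, MMFF relaxation).

    The same seed yields identical coordinates. Records for which embedding
    fails after a random-coordinate retry are returned with zero conformers
    and ``properties['embed_failed'] = True``.
    """
    mol = Chem.Mol(record.mol)
    if not any(atom.GetAtomicNum() == 1 for atom in mol.GetAtoms()):
        mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=int(n), params=params)
    if len(conf_ids) == 0:
        params.useRandomCoords = True
        conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=int(n), params=params)
    if len(conf_ids) == 0:
        out = replace(record, properties=dict(record.properties, embed_failed=True))
        logger.info("stage=embed failed id=%s", record.id)
        return out
    try:
        AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    except Exception:
        AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
    return replace(record, mol=mol)
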