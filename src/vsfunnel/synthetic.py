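"""Seeded generators that emulate every external input of the funnel.

The screening campaign this package models consumed a drug-like vendor
library, four docking programs' score tables, crystal-derived pharmacophore
geometry, MD trajectories and MM-PBSA frame tables — none of which are
shippable. Each generator here produces a statistically controlled stand-in:

* drug-like libraries from a fragment grammar (scaffolds × substituents)
  spanning the reference descriptor envelope;
* planted actives as small structural edits of query compounds, so both the
  2D-similarity and pharmacophore stages see realistic positives;
* Gaussian-shift score tables whose discriminative power has the closed form
  AUC = Φ(δ/(σ√2)), giving an exact oracle for the enrichment statistics;
* jittered/rigid-moved feature clouds and Cα trajectories with known noise
  scales, giving closed-form expectations for matching and RMSD/RMSF;
* per-frame energy tables with known component means.

Every generator is a pure function of its arguments including the seed.
The default decoy/active design (10,000 decoys, 42 planted actives) mirrors
the campaign's validation experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial.transform import Rotation

from .chemio import CompoundLibrary, MoleculeRecord, standardize
from .consensus import ScoreTable
from .energetics import EnergyComponents
from .pharmacophore import FEATURE_KINDS, PharmacophoreFeature, PharmacophoreModel
from .traj_metrics import Trajectory

__all__ = [
    "SyntheticSpec",
    "SCAFFOLDS",
    "generate_library",
    "plant_actives",
    "generate_score_tables",
    "generate_feature_sets",
    "generate_trajectory",
    "generate_energy_frames",
]


@dataclass
class SyntheticSpec:
    """Bundle of generator parameters (defaults mirror the modeled campaign)."""

    seed: int = 0
    n_compounds: int = 10_000
    n_actives: int = 42
    # score model: decoy ~ N(mu, sigma), active ~ N(mu - delta, sigma), lower better
    score_mu: float = -7.0
    score_sigma: float = 1.0
    score_delta: float = 2.0
    n_programs: int = 4
    jitter: float = 0.3          # Å, feature clouds
    n_frames: int = 100
    n_atoms: int = 200
    traj_sigma: float = 0.1      # Å per coordinate
    rigid_amplitude: float = 5.0  # Å translation scale per frame

    def __post_init__(self):
        if self.score_sigma <= 0 or self.traj_sigma < 0:
            raise ValueError("noise scales must be positive")
        if not 0 <= self.n_actives <= max(self.n_compounds, 0):
            raise ValueError("n_actives must fit in the library")


# Fragment grammar: scaffolds with two attachment points, substituent pools
# per point. Chosen once to span the reference descriptor envelope.
SCAFFOLDS = (
    "O=C(Nc1ccc([*:1])cc1)c1ccc([*:2])cc1OC",
    "O=S(=O)(Nc1ccc([*:1])cc1C)c1ccc([*:2])cc1",
    "O=C(c1ccc(Oc2ccc([*:1])cc2)cc1)N[*:2]",
    "c1cc([*:1])ccc1-c1nc2ccc([*:2])cc2n1CC(N)=O",
    "O=C(N1CCN(c2ccc([*:1])cc2)CC1)c1ccc([*:2])cc1",
    "O=c1n([*:2])cnc2cc([*:1])ccc12",
    "c1cc([*:1])ccc1Nc1ncnc2cc([*:2])ccc12",
    "O=C(N[*:2])c1cc([*:1])ccc1-n1cccn1",
)
_SUB1 = (
    "[*:1]OC", "[*:1]Cl", "[*:1]C(F)(F)F", "[*:1]N1CCOCC1", "[*:1]N1CCN(C)CC1",
    "[*:1]OCC", "[*:1]S(C)(=O)=O", "[*:1]C#N", "[*:1]N(C)C", "[*:1]OC(F)F",
    "[*:1]C(N)=O", "[*:1]O",
)
_SUB2 = (
    "[*:2]CCN1CCOCC1", "[*:2]c1ccccc1", "[*:2]c1ccc(F)cc1", "[*:2]CCO",
    "[*:2]Cc1ccccc1", "[*:2]c1ccc(OC)cc1", "[*:2]CCN(C)C", "[*:2]c1ccncc1",
    "[*:2]Cc1ccco1", "[*:2]c1ccc(S(C)(=O)=O)cc1", "[*:2]CC(=O)N1CCOCC1",
    "[*:2]c1ccc(C#N)cc1",
)


def _assemble(scaffold: str, sub1: str, sub2: str) -> Chem.Mol:
    combined = Chem.CombineMols(
        Chem.CombineMols(Chem.MolFromSmiles(scaffold), Chem.MolFromSmiles(sub1)),
        Chem.MolFromSmiles(sub2),
    )
    mol = Chem.molzip(combined)
    Chem.SanitizeMol(mol)
    return mol


def generate_library(n: int, seed: int = 0, id_prefix: str = "SYN") -> CompoundLibrary:
    """Drug-like library of ``n`` valid molecules from the fragment grammar.

    Deterministic under the seed; every molecule standardizes cleanly by
    construction. Distinct records may share a structure (the grammar is
    finite), but ids are unique.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(int(n)):
        scaffold = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
        sub1 = _SUB1[rng.integers(len(_SUB1))]
        sub2 = _SUB2[rng.integers(len(_SUB2))]
        mol = _assemble(scaffold, sub1, sub2)
        records.append(MoleculeRecord(f"{id_prefix}{i:06d}", mol, {"source": "synthetic"}))
    return CompoundLibrary(records, provenance=f"synthetic grammar seed={seed}")


_EDIT_FRAGMENTS = ("F", "Cl", "C", "O")  # attach to an aromatic/aliphatic C-H


def _edit_once(mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    """One small structural edit: attach F/Cl/CH3/OH at a random C bearing H."""
    candidates = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
    ]
    if not candidates:
        return mol
    target = int(rng.choice(candidates))
    symbol = _EDIT_FRAGMENTS[rng.integers(len(_EDIT_FRAGMENTS))]
    rw = Chem.RWMol(mol)
    new_idx = rw.AddAtom(Chem.Atom(symbol))
    rw.AddBond(target, new_idx, Chem.BondType.SINGLE)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return mol
    return out


def plant_actives(
    library: CompoundLibrary,
    queries,
    n: int,
    seed: int = 0,
    edit_depth: int = 1,
    id_prefix: str = "ACT",
):
    """Replace ``n`` random library members with actives derived from queries.

    Each active is a query structure with ``edit_depth`` random small edits
    (edit depth 0 inserts exact copies, Tanimoto 1 to their query). Returns
    ``(library, labels)`` where labels maps every id to ``"active"`` or
    ``"decoy"``.
    """
    queries = list(queries)
    if not queries:
        raise ValueError("need at least one query to derive actives from")
    if n > len(library):
        raise ValueError("cannot plant more actives than library capacity")
    rng = np.random.default_rng(seed)
    slots = rng.choice(len(library), size=int(n), replace=False)
    records = list(library.records)
    active_ids = []
    for k, slot in enumerate(sorted(int(s) for s in slots)):
        query = queries[int(rng.integers(len(queries)))]
        mol = Chem.Mol(query.mol)
        for _ in range(int(edit_depth)):
            mol = _edit_once(mol, rng)
        rec_id = f"{id_prefix}{k:04d}"
        records[slot] = MoleculeRecord(
            rec_id, mol, {"source": "planted_active", "parent_query": query.id}
        )
        active_ids.append(rec_id)
    out = CompoundLibrary(records, provenance=library.provenance + " +planted")
    labels = {r.id: ("active" if r.id in set(active_ids) else "decoy") for r in out}
    return out, labels


def generate_score_tables(
    labels: dict,
    seed: int = 0,
    n_programs: int = 4,
    mu: float = -7.0,
    sigma: float = 1.0,
    delta: float = 2.0,
) -> list:
    """Per-program Gaussian-shift score tables (lower is better).

    Decoys score N(mu, sigma), actives N(mu − delta, sigma), independently
    across programs; the analytic AUC per program is Φ(δ/(σ√2)).
    """
    ids = list(labels)
    is_active = np.array([str(labels[i]).lower() in ("active", "true", "1") for i in ids])
    root = np.random.default_rng(seed)
    streams = root.spawn(n_programs)
    tables = []
    for p, rng in enumerate(streams):
        scores = rng.normal(mu, sigma, size=len(ids))
        scores[is_active] -= delta
        tables.append(ScoreTable(f"prog{p + 1}", dict(zip(ids, scores.tolist()))))
    return tables


def generate_feature_sets(
    model: PharmacophoreModel,
    jitter: float,
    n: int,
    seed: int = 0,
    n_distractors: int = 3,
):
    """Labeled feature clouds for matcher benchmarking.

    Positives: the model's features jittered by N(0, jitter) per coordinate,
    rigidly rotated/translated, plus random distractor features. Negatives:
    the same construction with feature kinds cyclically reassigned, so no
    kind-consistent correspondence of min_match features exists at small
    jitter. Returns a list of ``(features, label)`` with label in {1, 0}.
    """
    rng = np.random.default_rng(seed)
    base = np.array([f.xyz for f in model.features])
    kinds = [f.kind for f in model.features]
    span = max(float(np.ptp(base, axis=0).max()), 5.0)
    sets = []
    for label in (1, 0):
        for _ in range(int(n)):
            points = base + rng.normal(0.0, jitter, size=base.shape)
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            shift = rng.uniform(-20, 20, size=3)
            points = points @ rot.T + shift
            if label == 1:
                used_kinds = list(kinds)
            else:
                shift_by = 1 + int(rng.integers(len(FEATURE_KINDS) - 1))
                order = {k: i for i, k in enumerate(FEATURE_KINDS)}
                used_kinds = [
                    FEATURE_KINDS[(order[k] + shift_by) % len(FEATURE_KINDS)] for k in kinds
                ]
            feats = [
                PharmacophoreFeature(k, tuple(p)) for k, p in zip(used_kinds, points)
            ]
            for _ in range(int(n_distractors)):
                feats.append(
                    PharmacophoreFeature(
                        FEATURE_KINDS[rng.integers(len(FEATURE_KINDS))],
                        tuple(shift + rng.uniform(-2 * span, 2 * span, size=3)),
                    )
                )
            sets.append((feats, label))
    return sets


def generate_trajectory(
    n_frames: int = 100,
    n_atoms: int = 200,
    sigma: float = 0.1,
    rigid_amplitude: float = 5.0,
    seed: int = 0,
    stride_ps: float = 1.0,
) -> Trajectory:
    """Cα trajectory: a fixed coil conformation plus per-frame isotropic
    Gaussian jitter and a random rigid motion per frame.

    Frame 0 is the unperturbed conformation (so RMSD against the default
    reference has mean ≈ σ√3 per frame); two chain ids split the positions in
    half, mimicking dimer bookkeeping. With sigma=0 the internal structure
    never changes, so superposed RMSD is exactly zero despite the rigid motion.
    """
    rng = np.random.default_rng(seed)
    # helix-like coil with ~3.8 Å neighbor spacing
    t = np.arange(n_atoms) * 0.6
    base = np.stack(
        [6.0 * np.cos(t), 6.0 * np.sin(t), 1.5 * t + 2.0 * np.sin(0.15 * t)], axis=1
    )
    frames = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        noise = 0.0 if f == 0 else rng.normal(0.0, sigma, size=base.shape)
        coords = base + noise
        rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        shift = rng.uniform(-rigid_amplitude, rigid_amplitude, size=3)
        frames[f] = coords @ rot.T + shift
    half = n_atoms // 2
    chain_ids = np.array(["A"] * half + ["B"] * (n_atoms - half))
    res_ids = np.concatenate([np.arange(1, half + 1), np.arange(1, n_atoms - half + 1)])
    return Trajectory(frames, chain_ids=chain_ids, res_ids=res_ids, stride_ps=stride_ps)


def generate_energy_frames(
    true_components: EnergyComponents,
    noise_sigma: float,
    n_frames: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-frame MM-PBSA component table with components ~ N(true, sigma)."""
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    data = {"frame": np.arange(int(n_frames))}
    for name in ("vdw", "eel", "epb", "enpolar", "edisper"):
        data[name] = rng.normal(getattr(true_components, name), noise_sigma, size=int(n_frames))
    return pd.DataFrame(data)
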