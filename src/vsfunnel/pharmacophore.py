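"""3D pharmacophore perception, model construction, matching and validation.

A pharmacophore model is a set of typed 3D features (hydrophobe, H-bond
donor/acceptor, cation, anion, aromatic centroid), each with a spherical
tolerance radius, plus a minimum number of features a candidate must match.

Matching is alignment-free: a correspondence graph pairs each model feature
with every same-kind candidate feature, two pairings are compatible when
their model-side and candidate-side inter-feature distances agree within the
sum of the two tolerance radii, and the largest clique of mutually compatible
pairings is found exactly. Pairwise distances are invariant under rigid
motion, so the match result is too; the price is that mirror-image
arrangements also match (a documented limitation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
from rdkit import Chem
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .chemio import CompoundLibrary, MoleculeRecord

logger = logging.getLogger("vsfunnel")

__all__ = [
    "FEATURE_KINDS",
    "DEFAULT_RADIUS",
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "MatchResult",
    "RetrievalReport",
    "perceive_features",
    "build_model_from_overlay",
    "match_features",
    "screen_by_model",
    "validate_model",
    "save_model",
    "load_model",
]

FEATURE_KINDS = ("HYD", "HBD", "HBA", "CAT", "ANI", "ARO")
DEFAULT_RADIUS = 1.5  # Å tolerance sphere


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    center: tuple  # (x, y, z) in Å
    radius: float = DEFAULT_RADIUS

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if len(self.center) != 3:
            raise ValueError("center must be a 3D point")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class PharmacophoreModel:
    features: tuple
    min_match: int = 4
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        if not self.features:
            raise ValueError("model has no features")
        if not (1 <= self.min_match <= len(self.features)):
            raise ValueError("min_match must be within 1..n_features")

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class MatchResult:
    passed: bool
    mapping: tuple  # pairs (model feature index, candidate feature index)
    matched: int
    deviation: float  # mean pairwise-distance discrepancy over the clique, Å


@dataclass
class RetrievalReport:
    actives_total: int
    actives_retrieved: int
    decoys_total: int
    decoys_retrieved: int
    retrieved_active_ids: list = field(default_factory=list)

    @property
    def percent_retrieval(self) -> float:
        return 100.0 * self.actives_retrieved / self.actives_total


# --- feature perception ------------------------------------------------------
# Rule set: anchors are SMARTS whose first matched atom (or the centroid of all
# matched atoms, for group features) carries the feature point.

_HBD_SMARTS = Chem.MolFromSmarts("[#7,#8;!H0]")
# acceptors: any O except nitro/N-oxide O; neutral N with a lone pair, but not
# amide/sulfonamide N and not pyrrole-type aromatic NH
_HBA_SMARTS = Chem.MolFromSmarts(
    "[$([#8;X1,X2;!$([OX1]N=O);!$([OX1][N+])]),"
    "$([#7;+0;!X4;!$([N][C,S]=[O,S,N]);!$([n;H1]);!$([N;H0;X3](a)(a))])]"
)
_CAT_SMARTS = Chem.MolFromSmarts(
    "[$([#7;+;!$([N+][O-])]),"                       # protonated N (not nitro)
    "$([NX3;+0;H2,H1;!$(N[a]);!$(N[C,S]=[O,S,N]);!$(N[C]=[C,N])]),"  # aliphatic amine
    "$([NX2;H0]=[CX3][NX3])]"                         # amidine / guanidine N
)
# group anions: charged O/S, carboxylate/carboxylic acid, sulfonate, tetrazole
_ANI_GROUPS = [
    Chem.MolFromSmarts("[CX3](=O)[OX1H0-,OX2H1]"),
    Chem.MolFromSmarts("[SX4](=O)(=O)[OX1H0-,OX2H1]"),
    Chem.MolFromSmarts("c1nnn[nH,n-]1"),
]
_HALOGENS = {9, 17, 35, 53}


def _conformer_coords(mol: Chem.Mol, conf_index: int) -> np.ndarray:
    return np.asarray(mol.GetConformer(conf_index).GetPositions(), dtype=float)


def perceive_features(
    record: MoleculeRecord,
    conf_index: int = 0,
    radius: float = DEFAULT_RADIUS,
) -> list:
    """Rule-based feature perception on one conformer.

    HBD at N/O bearing H; HBA at N/O with an available lone pair (amide N and
    pyrrole-type NH excluded); CAT at positively ionizable nitrogens; ANI at
    centroids of negatively ionizable groups (carboxylate, sulfonate,
    tetrazole) and at formally negative O/S; ARO at aromatic ring centroids;
    HYD at centroids of connected clusters of ≥3 carbon/halogen atoms with no
    attached heteroatom.
    """
    mol = record.mol
    if mol.GetNumConformers() <= conf_index:
        raise ValueError(f"{record.id}: conformer {conf_index} does not exist")
    xyz = _conformer_coords(mol, conf_index)
    feats: list[PharmacophoreFeature] = []

    def add(kind, point):
        feats.append(PharmacophoreFeature(kind, tuple(point), radius))

    for (idx,) in mol.GetSubstructMatches(_HBD_SMARTS):
        add("HBD", xyz[idx])
    for (idx,) in mol.GetSubstructMatches(_HBA_SMARTS):
        add("HBA", xyz[idx])
    for (idx, *_rest) in mol.GetSubstructMatches(_CAT_SMARTS):
        add("CAT", xyz[idx])

    ani_atoms: set[int] = set()
    for query in _ANI_GROUPS:
        for match in mol.GetSubstructMatches(query):
            if ani_atoms.isdisjoint(match):
                add("ANI", xyz[list(match)].mean(axis=0))
                ani_atoms.update(match)
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() < 0 and atom.GetAtomicNum() in (8, 16):
            if atom.GetIdx() not in ani_atoms:
                add("ANI", xyz[atom.GetIdx()])
                ani_atoms.add(atom.GetIdx())

    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            add("ARO", xyz[list(ring)].mean(axis=0))

    # hydrophobes: connected C/halogen clusters untouched by heteroatoms
    eligible = set()
    for atom in mol.GetAtoms():
        num = atom.GetAtomicNum()
        if num == 6 or num in _HALOGENS:
            neighbors = [n.GetAtomicNum() for n in atom.GetNeighbors()]
            if all(n in (1, 6) or n in _HALOGENS for n in neighbors):
                eligible.add(atom.GetIdx())
    graph = nx.Graph()
    graph.add_nodes_from(eligible)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in eligible and j in eligible:
            graph.add_edge(i, j)
    for component in nx.connected_components(graph):
        if len(component) >= 3:
            add("HYD", xyz[sorted(component)].mean(axis=0))

    return feats


# --- model construction ------------------------------------------------------

def build_model_from_overlay(
    overlaid,
    consensus_fraction: float = 0.75,
    default_radius: float = DEFAULT_RADIUS,
    min_match: int = 4,
    name: str = "overlay-consensus",
) -> PharmacophoreModel:
    """Consensus model from pre-overlaid conformers.

    ``overlaid`` is a list of ``(MoleculeRecord, conformer_index)`` pairs (or
    pre-perceived feature lists) sharing one coordinate frame. Features of the
    same kind are single-linkage clustered with link distance ≤ 2×default
    radius; a cluster present in at least ``consensus_fraction`` of the
    molecules becomes a model feature at the cluster centroid with radius
    max(default, RMS spread).
    """
    if len(overlaid) < 2:
        raise ValueError("overlay needs at least two molecules")
    per_mol_features = []
    for entry in overlaid:
        if isinstance(entry, (list, tuple)) and entry and isinstance(entry[0], PharmacophoreFeature):
            per_mol_features.append(list(entry))
        else:
            record, conf_index = entry
            per_mol_features.append(perceive_features(record, conf_index, default_radius))
    n_mols = len(per_mol_features)

    model_feats: list[PharmacophoreFeature] = []
    for kind in FEATURE_KINDS:
        points, owners = [], []
        for mol_idx, feats in enumerate(per_mol_features):
            for f in feats:
                if f.kind == kind:
                    points.append(f.xyz)
                    owners.append(mol_idx)
        if not points:
            continue
        points = np.asarray(points)
        if len(points) == 1:
            labels = np.array([1])
        else:
            labels = fcluster(
                linkage(pdist(points), method="single"),
                t=2.0 * default_radius,
                criterion="distance",
            )
        for label in np.unique(labels):
            sel = labels == label
            support = len({owners[i] for i in np.nonzero(sel)[0]})
            if support / n_mols < consensus_fraction:
                continue
            centroid = points[sel].mean(axis=0)
            spread = float(np.sqrt(np.mean(np.sum((points[sel] - centroid) ** 2, axis=1))))
            model_feats.append(
                PharmacophoreFeature(kind, tuple(centroid), max(default_radius, spread))
            )
    if not model_feats:
        raise ValueError("no consensus features survived clustering")
    return PharmacophoreModel(tuple(model_feats), min_match=min(min_match, len(model_feats)), name=name)


# --- matching ----------------------------------------------------------------

def match_features(candidate, model: PharmacophoreModel) -> MatchResult:
    """Largest distance-consistent assignment of model features to candidate
    features of the same kind (exact clique search on the correspondence graph).

    Passes iff the clique size reaches ``model.min_match``. The deviation is
    the mean over clique pairs of |model distance − candidate distance| (0 for
    cliques of size ≤ 1).
    """
    candidate = list(candidate)
    if not candidate:
        return MatchResult(False, (), 0, math.inf)

    model_xyz = np.array([f.xyz for f in model.features])
    cand_xyz = np.array([f.xyz for f in candidate])
    nodes = [
        (i, j)
        for i, mf in enumerate(model.features)
        for j, cf in enumerate(candidate)
        if mf.kind == cf.kind
    ]
    if not nodes:
        return MatchResult(False, (), 0, math.inf)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    for a in range(len(nodes)):
        i, j = nodes[a]
        for b in range(a + 1, len(nodes)):
            k, l = nodes[b]
            if i == k or j == l:
                continue
            d_model = float(np.linalg.norm(model_xyz[i] - model_xyz[k]))
            d_cand = float(np.linalg.norm(cand_xyz[j] - cand_xyz[l]))
            tol = model.features[i].radius + model.features[k].radius
            if abs(d_model - d_cand) <= tol:
                graph.add_edge(a, b)

    clique, _ = nx.max_weight_clique(graph, weight=None)
    pairs = tuple(sorted(nodes[a] for a in clique))
    matched = len(pairs)
    if matched >= 2:
        deviations = []
        for x in range(matched):
            i, j = pairs[x]
            for y in range(x + 1, matched):
                k, l = pairs[y]
                deviations.append(
                    abs(
                        float(np.linalg.norm(model_xyz[i] - model_xyz[k]))
                        - float(np.linalg.norm(cand_xyz[j] - cand_xyz[l]))
                    )
                )
        deviation = float(np.mean(deviations))
    else:
        deviation = 0.0
    return MatchResult(matched >= model.min_match, pairs, matched, deviation)


def screen_by_model(library: CompoundLibrary, model: PharmacophoreModel) -> CompoundLibrary:
    """Keep records for which any conformer's perceived features match the model.

    The best conformer index, matched-feature count and deviation are stored
    in the record properties.
    """
    survivors = []
    for rec in library:
        best = None
        for conf_index in range(rec.num_conformers):
            result = match_features(perceive_features(rec, conf_index), model)
            if result.passed and (
                best is None
                or result.matched > best[1].matched
                or (result.matched == best[1].matched and result.deviation < best[1].deviation)
            ):
                best = (conf_index, result)
        if best is not None:
            conf_index, result = best
            survivors.append(
                replace(
                    rec,
                    properties=dict(
                        rec.properties,
                        pharmacophore_conformer=conf_index,
                        pharmacophore_matched=result.matched,
                        pharmacophore_deviation=result.deviation,
                    ),
                )
            )
    logger.info("stage=pharmacophore_screen in=%d out=%d", len(library), len(survivors))
    return CompoundLibrary(survivors, provenance=library.provenance)


def validate_model(
    model: PharmacophoreModel,
    actives: CompoundLibrary,
    decoys: CompoundLibrary,
) -> RetrievalReport:
    """Active/decoy retrieval experiment for one model.

    Screens the union and reports how many actives and decoys are retrieved;
    percent retrieval is 100·(actives retrieved)/(actives total).
    """
    if len(actives) == 0:
        raise ValueError("validation requires at least one active")
    if set(actives.ids) & set(decoys.ids):
        raise ValueError("active and decoy id sets overlap")
    retrieved_actives = screen_by_model(actives, model)
    retrieved_decoys = screen_by_model(decoys, model)
    report = RetrievalReport(
        actives_total=len(actives),
        actives_retrieved=len(retrieved_actives),
        decoys_total=len(decoys),
        decoys_retrieved=len(retrieved_decoys),
        retrieved_active_ids=retrieved_actives.ids,
    )
    logger.info(
        "stage=model_validation actives=%d/%d decoys=%d/%d percent=%.2f",
        report.actives_retrieved,
        report.actives_total,
        report.decoys_retrieved,
        report.decoys_total,
        report.percent_retrieval,
    )
    return report


# --- serialization -----------------------------------------------------------

def save_model(model: PharmacophoreModel, path) -> None:
    """Write a model as text: header line with min_match, one feature per line."""
    with open(path, "w") as fh:
        fh.write(f"# pharmacophore model {model.name}\n")
        fh.write(f"min_match {model.min_match}\n")
        for f in model.features:
            x, y, z = f.center
            fh.write(f"{f.kind} {x:.4f} {y:.4f} {z:.4f} {f.radius:.4f}\n")


def load_model(path) -> PharmacophoreModel:
    path = Path(path)
    name = path.stem
    min_match = 4
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "min_match":
                min_match = int(parts[1])
            else:
                kind, x, y, z, radius = parts[0], *map(float, parts[1:5])
                feats.append(PharmacophoreFeature(kind, (x, y, z), radius))
    return PharmacophoreModel(tuple(feats), min_match=min_match, name=name)
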