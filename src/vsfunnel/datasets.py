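"""Bundled reference data for the TNF-α screening campaign this package models.

Three kinds of reference objects are shipped:

* the descriptor envelope derived from the campaign's known TNF-α inhibitors,
  used as the stage-1 filter when no active table is supplied;
* the consensus docking results (per-program scores and ranks) of the 17
  reported hit compounds, used to exercise the rank-intersection stage;
* the MM-PBSA energy decomposition of the ten simulated complexes, used to
  exercise the energy bookkeeping and affinity ranking.

The structure-based pharmacophore model shipped here is *synthetic*: the
feature census (three hydrophobes, one donor, one acceptor, one cation,
minimum match 4) mirrors the campaign's crystal-structure-derived model, but
the coordinates are plausible placeholder geometry, since the crystal
complexes themselves are external data.
"""

from __future__ import annotations

import pandas as pd

from .consensus import RankTable, ScoreTable
from .descriptors import DescriptorEnvelope
from .energetics import BindingEnergyRecord, EnergyComponents
from .pharmacophore import PharmacophoreFeature, PharmacophoreModel

__all__ = [
    "TNF_ACTIVES_ENVELOPE",
    "consensus_hit_table",
    "consensus_rank_tables",
    "consensus_score_tables",
    "mmpbsa_table",
    "mmpbsa_records",
    "structure_based_model_synthetic",
    "query_actives_smiles_synthetic",
]

#: Descriptor envelope of the campaign's known TNF-α inhibitors (41 actives;
#: one high-molecular-weight outlier was excluded upstream of derivation).
TNF_ACTIVES_ENVELOPE = DescriptorEnvelope(
    {
        "mw": (269.0, 549.0),
        "tpsa": (32.59, 176.51),
        "hba": (2, 10),
        "hbd": (0, 5),
        "rotb": (1, 12),
        "logp": (-1.0, 5.96),
    }
)

# Consensus docking results of the 17 hit compounds: per-program score and
# rank within each program's full docked library (~25K compounds).
_HITS = [
    # (compound, zinc_id, fred, fred_rank, vina, vina_rank, moe, moe_rank, mvd, mvd_rank)
    ("1", "ZINC04914424", -89.32, 1, -13.74, 2, -23.65, 5, -90.05, 8),
    ("2", "ZINC17090251", -85.29, 2, -13.93, 1, -20.23, 11, -81.23, 24),
    ("3", "ZINC04914300", -84.08, 3, -12.77, 3, -19.01, 24, -74.56, 41),
    ("4", "ZINC16000225", -82.55, 5, -12.34, 7, -23.44, 8, -89.88, 11),
    ("5", "ZINC49717234", -80.65, 10, -12.56, 5, -26.88, 1, -90.89, 4),
    ("6", "ZINC00785143", -80.26, 11, -12.58, 4, -20.05, 15, -77.73, 35),
    ("7", "ZINC09345795", -79.69, 13, -11.52, 48, -18.98, 29, -89.09, 12),
    ("8", "ZINC18200859", -79.68, 14, -11.81, 26, -20.11, 12, -80.60, 29),
    ("9", "ZINC49717263", -79.25, 16, -12.48, 12, -22.65, 9, -85.64, 17),
    ("10", "ZINC62240601", -77.64, 23, -12.10, 10, -16.01, 55, -72.65, 46),
    ("11", "ZINC40159471", -76.00, 29, -11.66, 35, -24.59, 4, -91.05, 2),
    ("12", "ZINC31819567", -75.81, 30, -12.33, 8, -15.05, 89, -90.85, 5),
    ("13", "ZINC05604236", -75.50, 34, -11.68, 33, -15.90, 63, -81.24, 25),
    ("14", "ZINC31839368", -75.19, 36, -11.88, 20, -15.55, 71, -80.56, 30),
    ("15", "ZINC33462852", -75.05, 37, -12.48, 6, -16.23, 45, -90.01, 9),
    ("16", "ZINC04214135", -74.89, 38, -11.58, 41, -19.89, 18, -74.22, 42),
    ("17", "ZINC04914400", -74.84, 39, -11.85, 22, -19.23, 21, -85.22, 19),
]

_PROGRAMS = ("FRED", "Vina", "MOE", "MVD")


def consensus_hit_table() -> pd.DataFrame:
    """The 17 reference hits with per-program docking scores and ranks."""
    return pd.DataFrame(
        _HITS,
        columns=[
            "compound", "zinc_id",
            "FRED_score", "FRED_rank", "Vina_score", "Vina_rank",
            "MOE_score", "MOE_rank", "MVD_score", "MVD_rank",
        ],
    )


def consensus_rank_tables() -> list:
    """The four per-program rank columns as :class:`RankTable` objects."""
    df = consensus_hit_table()
    return [
        RankTable(p, dict(zip(df["zinc_id"], df[f"{p}_rank"].astype(int))))
        for p in _PROGRAMS
    ]


def consensus_score_tables() -> list:
    """The four per-program score columns (all lower-is-better)."""
    df = consensus_hit_table()
    return [
        ScoreTable(p, dict(zip(df["zinc_id"], df[f"{p}_score"].astype(float))))
        for p in _PROGRAMS
    ]


# MM-PBSA summary of the ten simulated ligand–TNF-α complexes (kcal/mol).
_MMPBSA = [
    # (compound, zinc_id, binding energy, sd, vdw, eel, epb, enpolar)
    ("4", "ZINC16000225", -31.43, 3.49, -43.07, -15.72, 30.96, -3.60),
    ("5", "ZINC49717234", -30.37, 3.97, -46.47, -9.91, 29.89, -3.88),
    ("7", "ZINC09345795", -35.23, 3.15, -48.51, -6.43, 23.64, -3.93),
    ("8", "ZINC18200859", -27.06, 3.93, -41.82, -6.91, 25.22, -3.55),
    ("9", "ZINC49717263", -32.16, 4.06, -47.36, -12.14, 31.30, -3.97),
    ("10", "ZINC62240601", -14.75, 2.99, -24.44, -66.08, 78.55, -2.78),
    ("11", "ZINC40159471", -20.83, 3.08, -30.42, -2.54, 15.13, -3.00),
    ("13", "ZINC05604236", -26.87, 2.67, -38.87, -14.68, 29.78, -3.10),
    ("14", "ZINC31839368", -24.40, 3.74, -39.63, -6.03, 24.99, -3.73),
    ("15", "ZINC33462852", -22.66, 2.93, -36.62, -8.87, 26.28, -3.45),
]


def mmpbsa_table() -> pd.DataFrame:
    """Reference MM-PBSA decomposition of the ten simulated complexes."""
    return pd.DataFrame(
        _MMPBSA,
        columns=["compound", "zinc_id", "binding_energy", "sd", "vdw", "eel", "epb", "enpolar"],
    )


def mmpbsa_records() -> list:
    """The reference table as :class:`BindingEnergyRecord` objects
    (compound number as ligand id)."""
    return [
        BindingEnergyRecord(
            ligand_id=row[0],
            mean=row[2],
            sd=row[3],
            components=EnergyComponents(vdw=row[4], eel=row[5], epb=row[6], enpolar=row[7]),
        )
        for row in _MMPBSA
    ]


def structure_based_model_synthetic(min_match: int = 4) -> PharmacophoreModel:
    """Six-feature structure-based model with synthetic placeholder geometry.

    Feature census mirrors the campaign's crystal-derived model (3 HYD,
    1 HBD, 1 HBA, 1 CAT); coordinates are plausible synthetic geometry at
    binding-site length scales, NOT crystallographic.
    """
    feats = (
        PharmacophoreFeature("HYD", (0.0, 0.0, 0.0)),
        PharmacophoreFeature("HYD", (4.2, 1.0, 0.5)),
        PharmacophoreFeature("HYD", (2.1, 3.9, -1.2)),
        PharmacophoreFeature("HBD", (-2.5, 2.0, 1.5)),
        PharmacophoreFeature("HBA", (5.5, 4.0, 2.0)),
        PharmacophoreFeature("CAT", (1.0, -3.5, 2.5)),
    )
    return PharmacophoreModel(feats, min_match=min_match, name="sbpm-synthetic")


def query_actives_smiles_synthetic() -> list:
    """Synthetic stand-ins for the five most-active query inhibitors.

    Drug-like structures inside the reference envelope, used as default 2D
    query set; NOT the campaign's proprietary active structures.

    Returns ``(id, smiles)`` pairs.
    """
    return [
        ("QRY1", "COc1ccc(C(=O)Nc2ccc(N3CCOCC3)cc2)cc1Cl"),
        ("QRY2", "O=S(=O)(Nc1ccc(F)cc1)c1ccc(-c2nc3ccccc3[nH]2)cc1"),
        ("QRY3", "CN1CCN(c2ccc(NC(=O)c3ccc(Oc4ccccc4)cc3)cc2)CC1"),
        ("QRY4", "COc1ccc(-c2nc3ccc(C(N)=O)cc3n2Cc2ccccc2)cc1"),
        ("QRY5", "O=C(Nc1ccc(N2CCOCC2)cc1)c1cccc(C(F)(F)F)c1-n1cccn1"),
    ]
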