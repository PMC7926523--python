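"""MM-PBSA binding-energy bookkeeping.

The binding free energy of a ligand–protein association is the difference

    ΔG_bind = ⟨G_complex⟩ − ⟨G_protein⟩ − ⟨G_ligand⟩,

and each free energy decomposes into van der Waals (VDW), electrostatic (EEL),
polar solvation (EPB, Poisson–Boltzmann), non-polar solvation (ENPOLAR,
SASA-linear) and an optional cavity-dispersion term (EDISPER, default 0 since
summary tables commonly omit it). This module consumes per-frame component
tables as emitted by standard MM-PBSA tools, aggregates them (mean ± sample
standard deviation, n−1 denominator — configurable to population sd), and
ranks ligands by affinity (most negative mean ΔG first).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EnergyComponents",
    "BindingEnergyRecord",
    "binding_energy_eq1",
    "total_from_components",
    "aggregate_frames",
    "rank_by_affinity",
    "read_energy_frames_csv",
    "summarize_frames",
    "summary_table",
]

_COMPONENT_COLUMNS = ("vdw", "eel", "epb", "enpolar", "edisper")


@dataclass(frozen=True)
class EnergyComponents:
    """One set of MM-PBSA energy terms, kcal/mol."""

    vdw: float
    eel: float
    epb: float
    enpolar: float
    edisper: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise ValueError(f"non-finite component {f.name}")


@dataclass(frozen=True)
class BindingEnergyRecord:
    ligand_id: str
    mean: float  # kcal/mol
    sd: float
    components: EnergyComponents | None = None
    n_frames: int = 0


def binding_energy_eq1(g_complex: float, g_protein: float, g_ligand: float) -> float:
    """ΔG_bind = G_complex − G_protein − G_ligand (kcal/mol)."""
    return g_complex - g_protein - g_ligand


def total_from_components(c: EnergyComponents) -> float:
    """Sum of the decomposition terms (kcal/mol)."""
    return c.vdw + c.eel + c.epb + c.enpolar + c.edisper


def aggregate_frames(series, ddof: int = 1):
    """Mean and standard deviation of a per-frame energy series.

    Sample sd (n−1) by default; requires ≥2 frames for the sd.
    """
    values = np.asarray(list(series), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two frames to aggregate")
    return float(values.mean()), float(values.std(ddof=ddof))


def rank_by_affinity(records) -> list:
    """Ligand ids ordered by ascending mean ΔG (strongest binder first);
    ties broken by id."""
    records = list(records)
    if not records:
        raise ValueError("no records to rank")
    return [r.ligand_id for r in sorted(records, key=lambda r: (r.mean, str(r.ligand_id)))]


def read_energy_frames_csv(path) -> pd.DataFrame:
    """Per-frame component CSV: columns frame,vdw,eel,epb,enpolar[,edisper]."""
    df = pd.read_csv(path)
    required = {"frame", "vdw", "eel", "epb", "enpolar"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if "edisper" not in df.columns:
        df["edisper"] = 0.0
    return df


def summarize_frames(frames: pd.DataFrame, ligand_id: str = "", ddof: int = 1) -> BindingEnergyRecord:
    """Aggregate a per-frame component table into one binding-energy record.

    Component means are averaged per term; the per-frame total (sum of terms)
    is aggregated into mean ± sd. By linearity the mean total equals the total
    of the mean components.
    """
    totals = frames[list(_COMPONENT_COLUMNS)].sum(axis=1)
    mean, sd = aggregate_frames(totals, ddof=ddof)
    comp_means = EnergyComponents(*(float(frames[c].mean()) for c in _COMPONENT_COLUMNS))
    return BindingEnergyRecord(ligand_id, mean, sd, comp_means, n_frames=len(frames))


def summary_table(records, path=None) -> pd.DataFrame:
    """Summary in affinity order: id, mean ΔG ± sd and component means."""
    order = rank_by_affinity(records)
    by_id = {r.ligand_id: r for r in records}
    rows = []
    for cid in order:
        r = by_id[cid]
        row = {"id": cid, "binding_energy": r.mean, "sd": r.sd}
        if r.components is not None:
            row.update({c: getattr(r.components, c) for c in _COMPONENT_COLUMNS})
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
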