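"""End-to-end funnel orchestration and the validation harness.

The funnel applies, in order: descriptor-envelope filter → 2D similarity
screen → pharmacophore screen → consensus over docking score tables →
optional manual exclusions. Every stage is skippable by configuration, logs
one ``stage=<name> in=<n> out=<m>`` line, and only ever removes compounds, so
survivor counts are monotone nonincreasing along the funnel.

Docking itself is an external boundary: the consensus stage consumes score
CSVs (real or synthetic), never computes scores.

The validation harness reproduces the decoy-embedding experiment: known
actives are mixed into a decoy set, a ranking is produced per score table,
and EF / ideal EF / %EF at the requested depths plus ROC/AUC and the success
flag are reported per program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .chemio import (
    CompoundLibrary,
    embed_conformers,
    read_library,
    standardize_library,
    write_library,
)
from .consensus import ConsensusHitSet, ScoreTable, consensus_top_n, read_score_csv
from .descriptors import (
    DescriptorEnvelope,
    apply_envelope_filter,
    compute_descriptors,
    derive_envelope,
)
from .enrichment import EnrichmentReport, ScreenOutcome, enrichment_report
from .pharmacophore import PharmacophoreModel, load_model, screen_by_model
from .similarity import similarity_screen

logger = logging.getLogger("vsfunnel")

__all__ = ["FunnelConfig", "FunnelReport", "run_funnel", "run_validation"]


@dataclass
class FunnelConfig:
    """Flat configuration of one funnel run.

    Any stage input left as ``None`` skips that stage. Defaults mirror the
    modeled campaign: similarity threshold 0.85, minimum pharmacophore match
    4, consensus top-N 100.
    """

    library_path: str | None = None
    library_format: str | None = None
    # stage 1: either explicit envelope bounds or a path to an actives file
    envelope: dict | None = None
    actives_path: str | None = None
    # stage 2
    queries_path: str | None = None
    sim_threshold: float = 0.85
    # stage 3
    model_path: str | None = None
    min_match: int = 4
    n_conformers: int = 10
    # stage 4
    score_csvs: list = field(default_factory=list)
    top_n: int = 100
    # post
    exclude_ids: list = field(default_factory=list)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.sim_threshold <= 1.0:
            raise ValueError("sim_threshold must be in [0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be positive")

    @classmethod
    def from_yaml(cls, path) -> "FunnelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class FunnelReport:
    stage_counts: list  # (stage name, n_in, n_out)
    hits: CompoundLibrary
    consensus: ConsensusHitSet | None = None

    @property
    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_counts, columns=["stage", "in", "out"])


def _resolve_envelope(config: FunnelConfig) -> DescriptorEnvelope | None:
    if config.envelope is not None:
        return DescriptorEnvelope(
            {k: (float(v[0]), float(v[1])) for k, v in config.envelope.items()}
        )
    if config.actives_path is not None:
        actives = standardize_library(read_library(config.actives_path))
        return derive_envelope([compute_descriptors(r) for r in actives])
    return None


def run_funnel(config: FunnelConfig, library: CompoundLibrary | None = None) -> FunnelReport:
    """Run the staged funnel under one configuration.

    ``library`` may be passed directly (e.g. a generated one); otherwise it is
    read from ``config.library_path``. Raises with the stage name when a
    configured stage is missing its input.
    """
    if library is None:
        if config.library_path is None:
            raise ValueError("stage=input missing library")
        library = read_library(config.library_path, config.library_format)
        library = standardize_library(library)
    current = library
    stage_counts: list[tuple[str, int, int]] = []

    env = _resolve_envelope(config)
    if env is not None:
        before = len(current)
        current = apply_envelope_filter(current, env)
        stage_counts.append(("descriptor_filter", before, len(current)))

    if config.queries_path is not None:
        queries = standardize_library(read_library(config.queries_path))
        before = len(current)
        current, _ = similarity_screen(current, list(queries), config.sim_threshold)
        stage_counts.append(("similarity_screen", before, len(current)))

    if config.model_path is not None:
        model = load_model(config.model_path)
        model = PharmacophoreModel(model.features, min_match=config.min_match, name=model.name)
        needs_embedding = any(rec.num_conformers == 0 for rec in current)
        if needs_embedding:
            current = CompoundLibrary(
                [
                    embed_conformers(rec, n=config.n_conformers, seed=config.seed)
                    if rec.num_conformers == 0
                    else rec
                    for rec in current
                ],
                provenance=current.provenance,
            )
        before = len(current)
        current = screen_by_model(current, model)
        stage_counts.append(("pharmacophore_screen", before, len(current)))

    consensus_hits = None
    if config.score_csvs:
        tables = [read_score_csv(p) for p in config.score_csvs]
        consensus_hits = consensus_top_n(tables, n=config.top_n)
        before = len(current)
        current = current.subset(consensus_hits.ids)
        stage_counts.append(("consensus", before, len(current)))

    if config.exclude_ids:
        before = len(current)
        current = current.subset(set(current.ids) - set(config.exclude_ids))
        stage_counts.append(("manual_exclusion", before, len(current)))
        logger.info("stage=manual_exclusion in=%d out=%d", before, len(current))

    report = FunnelReport(stage_counts=stage_counts, hits=current, consensus=consensus_hits)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.counts_frame.to_csv(out / "stage_counts.csv", index=False)
        write_library(current, out / "hits.smi", "smiles")
        if consensus_hits is not None:
            consensus_hits.per_program_ranks.reset_index().to_csv(
                out / "consensus_ranks.csv", index=False
            )
    return report


def run_validation(
    score_tables,
    labels: dict,
    depth_fractions=(0.01, 0.05, 0.10),
    min_recall: float = 0.5,
    ideal_n_total: int | None = None,
) -> dict:
    """Decoy-embedding validation: one enrichment report per score table.

    ``labels`` maps every scored id to active/decoy (strings or booleans).
    Returns ``{program: EnrichmentReport}``.
    """
    bool_labels = {
        k: (str(v).lower() in ("active", "true", "1")) if not isinstance(v, bool) else v
        for k, v in labels.items()
    }
    if not any(bool_labels.values()) or all(bool_labels.values()):
        raise ValueError("validation needs both actives and decoys")
    reports: dict[str, EnrichmentReport] = {}
    for table in score_tables:
        outcome = ScreenOutcome.from_scores(
            table.scores, bool_labels, lower_is_better=table.lower_is_better
        )
        reports[table.program] = enrichment_report(
            outcome, depth_fractions, min_recall, ideal_n_total=ideal_n_total
        )
    return reports
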