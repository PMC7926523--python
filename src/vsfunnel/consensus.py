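"""Consensus hit selection across docking programs.

Each docking program contributes a score table over the docked library; the
tables are independently converted to ordinal ranks (1 = best) and the
consensus hit set is the intersection of the per-program top-N lists —
compounds ranked ≤ N by *every* program. A compound missing from any program's
table (a docking failure) is excluded and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("vsfunnel")

__all__ = [
    "ScoreTable",
    "RankTable",
    "ConsensusHitSet",
    "rank_scores",
    "consensus_top_n",
    "read_score_csv",
    "write_score_csv",
    "consensus_report",
]


@dataclass
class ScoreTable:
    """Per-program docking scores: id → score.

    ``lower_is_better`` defaults to True (more negative = stronger binding,
    the convention of all common docking scoring functions).
    """

    program: str
    scores: dict
    lower_is_better: bool = True

    def __post_init__(self):
        if not self.scores:
            raise ValueError(f"{self.program}: empty score table")
        for cid, value in self.scores.items():
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValueError(f"{self.program}: NaN score for id {cid!r}")
            if not math.isfinite(float(value)):
                raise ValueError(f"{self.program}: non-finite score for id {cid!r}")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class RankTable:
    """Per-program ordinal ranks: id → rank (1 = best).

    Ranks must be distinct positive integers; when the table covers a whole
    docked library they form a permutation of 1..n, but a table may also hold
    the ranks of a subset of a larger ranking (e.g. a published hit list).
    """

    program: str
    ranks: dict

    def __post_init__(self):
        values = sorted(self.ranks.values())
        if any(int(v) != v or v < 1 for v in values):
            raise ValueError(f"{self.program}: ranks must be positive integers")
        if len(set(values)) != len(values):
            raise ValueError(f"{self.program}: duplicate ranks")

    def __len__(self) -> int:
        return len(self.ranks)

    def top_n(self, n: int) -> set:
        return {cid for cid, rank in self.ranks.items() if rank <= n}


@dataclass
class ConsensusHitSet:
    ids: list
    per_program_ranks: pd.DataFrame
    n: int
    excluded_missing: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ids)


def rank_scores(table: ScoreTable) -> RankTable:
    """Ordinal ranks from scores; ties broken lexicographically by id."""
    key = (lambda item: (item[1], str(item[0]))) if table.lower_is_better else (
        lambda item: (-item[1], str(item[0]))
    )
    ordered = sorted(table.scores.items(), key=key)
    return RankTable(table.program, {cid: i + 1 for i, (cid, _) in enumerate(ordered)})


def consensus_top_n(tables, n: int = 100) -> ConsensusHitSet:
    """Ids ranked ≤ n in every rank table.

    ``tables`` may mix :class:`RankTable` and :class:`ScoreTable` (scores are
    ranked first). Ids absent from any table are excluded.
    """
    tables = [rank_scores(t) if isinstance(t, ScoreTable) else t for t in tables]
    if not tables:
        raise ValueError("consensus requires at least one rank table")
    common = set(tables[0].ranks)
    union = set(tables[0].ranks)
    for t in tables[1:]:
        common &= set(t.ranks)
        union |= set(t.ranks)
    missing = sorted(union - common)
    if missing:
        logger.info("stage=consensus excluded_missing=%d", len(missing))

    hits = set(common)
    for t in tables:
        hits &= t.top_n(n)
    ids = sorted(hits)
    frame = pd.DataFrame(
        {f"rank_{t.program}": [t.ranks[cid] for cid in ids] for t in tables},
        index=pd.Index(ids, name="id"),
    )
    logger.info("stage=consensus in=%d out=%d n=%d", len(common), len(ids), n)
    return ConsensusHitSet(ids=ids, per_program_ranks=frame, n=n, excluded_missing=missing)


def read_score_csv(path, program: str | None = None, lower_is_better: bool = True) -> ScoreTable:
    """Read a per-program score CSV with columns id,score."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"id", "score"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns id,score")
    return ScoreTable(
        program or path.stem,
        dict(zip(df["id"].astype(str), df["score"].astype(float))),
        lower_is_better=lower_is_better,
    )


def write_score_csv(table: ScoreTable, path) -> None:
    pd.DataFrame(
        {"id": list(table.scores), "score": list(table.scores.values())}
    ).to_csv(path, index=False)


def consensus_report(hits: ConsensusHitSet, path=None) -> pd.DataFrame:
    """Consensus report table (id + per-program ranks), optionally written to CSV."""
    df = hits.per_program_ranks.reset_index()
    if path is not None:
        df.to_csv(path, index=False)
    return df
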