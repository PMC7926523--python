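"""Virtual-screening validation statistics on labeled rankings.

Given a ranked library with known actives, the enrichment factor at depth n is

    EF(n) = (HITS_sampled / HITS_total) / (N_sampled / N_total),

its ideal value is what a perfect ranking would achieve at the same depth, and
%EF = 100·EF/EF_ideal. Discrimination over the whole ranking is summarized by
ROC/AUC, where the AUC is computed with the rank-sum (Mann–Whitney) estimator:
the probability that a random active outranks a random decoy, ties counting ½.
A screen "succeeds" at a depth when it recovers at least a required fraction
of the actives there (default one half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "ScreenOutcome",
    "EnrichmentReport",
    "enrichment_factor",
    "ideal_enrichment_factor",
    "percent_enrichment_factor",
    "roc_auc",
    "success_criterion",
    "enrichment_report",
]


@dataclass
class ScreenOutcome:
    """A ranked id list (best first) with binary activity labels.

    Optional per-id scores allow tie-aware AUC; without scores the explicit
    ranking is used (no ties).
    """

    ranked_ids: list
    labels: dict  # id -> bool (True = active)
    scores: dict | None = None  # id -> score, lower is better if from docking

    def __post_init__(self):
        missing = [i for i in self.ranked_ids if i not in self.labels]
        if missing:
            raise ValueError(f"labels missing for {len(missing)} ids (e.g. {missing[0]!r})")
        if len(set(self.ranked_ids)) != len(self.ranked_ids):
            raise ValueError("duplicate ids in ranking")

    @property
    def n_total(self) -> int:
        return len(self.ranked_ids)

    @property
    def hits_total(self) -> int:
        return sum(bool(self.labels[i]) for i in self.ranked_ids)

    @classmethod
    def from_scores(cls, scores: dict, labels: dict, lower_is_better: bool = True) -> "ScreenOutcome":
        ordered = sorted(
            scores.items(),
            key=(lambda kv: (kv[1], str(kv[0]))) if lower_is_better else (lambda kv: (-kv[1], str(kv[0]))),
        )
        oriented = {k: (v if lower_is_better else -v) for k, v in scores.items()}
        return cls([k for k, _ in ordered], labels, scores=oriented)

    def hits_sampled(self, n_sampled: int) -> int:
        return sum(bool(self.labels[i]) for i in self.ranked_ids[:n_sampled])


def enrichment_factor(outcome: ScreenOutcome, n_sampled: int) -> float:
    """EF at a sampling depth given as a count of top-ranked compounds."""
    if not (1 <= n_sampled <= outcome.n_total):
        raise ValueError("n_sampled must be within 1..N_total")
    hits_total = outcome.hits_total
    if hits_total == 0:
        raise ValueError("outcome contains zero actives")
    return (outcome.hits_sampled(n_sampled) / hits_total) / (n_sampled / outcome.n_total)


def ideal_enrichment_factor(n_total: int, hits_total: int, n_sampled: int) -> float:
    """EF of a perfect ranking: all actives first, saturating at n_sampled."""
    if n_total <= 0 or hits_total <= 0 or n_sampled <= 0:
        raise ValueError("counts must be positive")
    if n_sampled > n_total:
        raise ValueError("n_sampled exceeds n_total")
    return (min(n_sampled, hits_total) / hits_total) / (n_sampled / n_total)


def percent_enrichment_factor(ef: float, ideal: float) -> float:
    if ideal <= 0:
        raise ValueError("ideal EF must be positive")
    return 100.0 * ef / ideal


def roc_auc(outcome: ScreenOutcome):
    """ROC points and AUC for an outcome.

    Returns ``(fpr, tpr, auc)``. The AUC uses the rank-sum estimator on the
    (oriented) scores when present, otherwise on the explicit ranking; tied
    scores contribute ½ per active–decoy pair.
    """
    y = np.array([bool(outcome.labels[i]) for i in outcome.ranked_ids])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both actives and decoys")
    if outcome.scores is not None:
        raw = np.array([float(outcome.scores[i]) for i in outcome.ranked_ids])
    else:
        raw = np.arange(outcome.n_total, dtype=float)  # explicit ranking, no ties
    # orient so larger = more active-like
    strength = -raw
    ranks = rankdata(strength)  # ties get average rank
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y.astype(int), strength)
    return fpr, tpr, float(auc)


def success_criterion(outcome: ScreenOutcome, depth_fraction: float, min_recall: float = 0.5) -> bool:
    """True iff the screen recovers ≥ min_recall of the actives in the top
    ``depth_fraction`` of the library (depth floored to a compound count)."""
    n_sampled = max(1, math.floor(depth_fraction * outcome.n_total))
    return outcome.hits_sampled(n_sampled) / outcome.hits_total >= min_recall


@dataclass
class EnrichmentReport:
    rows: pd.DataFrame  # per depth: n_sampled, hits_sampled, ef, ideal_ef, pct_ef, success
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    auc: float = float("nan")


def enrichment_report(
    outcome: ScreenOutcome,
    depth_fractions=(0.01, 0.05, 0.10),
    min_recall: float = 0.5,
    ideal_n_total: int | None = None,
) -> EnrichmentReport:
    """EF/ideal EF/%EF at each depth plus ROC/AUC and success flags.

    ``ideal_n_total`` overrides the library size used in the ideal-EF
    denominator, for reproducing round reference values quoted against a
    nominal library size (e.g. 10,000 rather than 10,042).
    """
    rows = []
    n_total = outcome.n_total
    for frac in depth_fractions:
        n_sampled = max(1, math.floor(frac * n_total))
        ef = enrichment_factor(outcome, n_sampled)
        ideal = ideal_enrichment_factor(ideal_n_total or n_total, outcome.hits_total, n_sampled)
        rows.append(
            {
                "depth_fraction": frac,
                "n_sampled": n_sampled,
                "hits_sampled": outcome.hits_sampled(n_sampled),
                "ef": ef,
                "ideal_ef": ideal,
                "pct_ef": percent_enrichment_factor(ef, ideal),
                "success": success_criterion(outcome, frac, min_recall),
            }
        )
    fpr, tpr, auc = roc_auc(outcome)
    return EnrichmentReport(rows=pd.DataFrame(rows), fpr=fpr, tpr=tpr, auc=auc)
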