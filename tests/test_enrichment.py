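import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from vsfunnel.enrichment import (
    ScreenOutcome,
    enrichment_factor,
    enrichment_report,
    ideal_enrichment_factor,
    percent_enrichment_factor,
    roc_auc,
    success_criterion,
)
from vsfunnel.synthetic import generate_score_tables


def outcome_from_pattern(pattern):
    """'a' = active, 'd' = decoy, best rank first."""
    ids = [f"m{i}" for i in range(len(pattern))]
    labels = {f"m{i}": c == "a" for i, c in enumerate(pattern)}
    return ScreenOutcome(ids, labels)


def test_ef_hand_count():
    # 10 compounds, 2 actives both in the top 5
    outcome = outcome_from_pattern("adaddddddd")
    assert enrichment_factor(outcome, 5) == pytest.approx(2.0)


def test_ef_at_full_depth_is_one():
    for pattern in ("adad", "ddaa", "aadd", "adddddddda"):
        outcome = outcome_from_pattern(pattern)
        assert enrichment_factor(outcome, outcome.n_total) == pytest.approx(1.0)


def test_ef_zero_when_no_actives_sampled():
    assert enrichment_factor(outcome_from_pattern("ddda"), 2) == 0.0


def test_ef_requires_actives():
    with pytest.raises(ValueError):
        enrichment_factor(outcome_from_pattern("dddd"), 2)


@pytest.mark.parametrize(
    "n_total, hits_total, n_sampled, expected",
    [
        (10000, 42, 100, 100.0),
        (10000, 42, 500, 20.0),
        (10000, 42, 1000, 10.0),
        (100, 10, 5, 10.0),  # saturated: min(5,10)/10 / (5/100)
    ],
)
def test_ideal_ef_reference_values(n_total, hits_total, n_sampled, expected):
    assert ideal_enrichment_factor(n_total, hits_total, n_sampled) == pytest.approx(expected)


def test_percent_ef():
    assert percent_enrichment_factor(10.0, 20.0) == pytest.approx(50.0)
    assert percent_enrichment_factor(20.0, 20.0) == pytest.approx(100.0)
    assert percent_enrichment_factor(0.0, 20.0) == 0.0
    with pytest.raises(ValueError):
        percent_enrichment_factor(1.0, 0.0)


def test_ef_bounded_by_ideal_on_random_outcomes():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(20, 200))
        k = int(rng.integers(1, n // 2))
        pattern = np.array(["d"] * n)
        pattern[rng.choice(n, k, replace=False)] = "a"
        outcome = outcome_from_pattern("".join(pattern))
        for depth in (1, n // 10 + 1, n // 2, n):
            ef = enrichment_factor(outcome, depth)
            ideal = ideal_enrichment_factor(n, k, depth)
            assert 0.0 <= ef <= ideal + 1e-12
            assert 0.0 <= percent_enrichment_factor(ef, ideal) <= 100.0 + 1e-9


def test_auc_perfect_ranking():
    assert roc_auc(outcome_from_pattern("aaddd"))[2] == 1.0


def test_auc_hand_case():
    # ranking a,d,a,d: 3 of 4 active-decoy pairs correctly ordered
    assert roc_auc(outcome_from_pattern("adad"))[2] == pytest.approx(0.75)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc(outcome_from_pattern("aaaa"))


def test_auc_null_distribution():
    rng = np.random.default_rng(11)
    scores = {f"m{i}": float(s) for i, s in enumerate(rng.normal(size=10_000))}
    labels = {k: bool(rng.random() < 0.3) for k in scores}
    outcome = ScreenOutcome.from_scores(scores, labels)
    assert roc_auc(outcome)[2] == pytest.approx(0.5, abs=0.02)


def test_auc_invariant_under_monotone_score_transform():
    rng = np.random.default_rng(4)
    scores = {f"m{i}": float(s) for i, s in enumerate(rng.normal(size=500))}
    labels = {k: bool(rng.random() < 0.2) for k in scores}
    labels[next(iter(scores))] = True  # ensure both classes
    labels[list(scores)[-1]] = False
    base = roc_auc(ScreenOutcome.from_scores(scores, labels))[2]
    warped = {k: np.expm1(v / 2) * 3 + 1 for k, v in scores.items()}
    assert roc_auc(ScreenOutcome.from_scores(warped, labels))[2] == pytest.approx(base)


def test_auc_handles_ties_as_half():
    scores = {"a1": -1.0, "d1": -1.0, "a2": -2.0, "d2": 0.0}
    labels = {"a1": True, "a2": True, "d1": False, "d2": False}
    outcome = ScreenOutcome.from_scores(scores, labels)
    # pairs: (a1,d1) tie=0.5, (a1,d2) win, (a2,d1) win, (a2,d2) win -> 3.5/4
    assert roc_auc(outcome)[2] == pytest.approx(3.5 / 4)
    assert roc_auc(outcome)[2] == pytest.approx(roc_auc_score(
        [labels[k] for k in scores], [-scores[k] for k in scores]
    ))


def test_gaussian_shift_auc_matches_closed_form():
    """Empirical AUC of Gaussian-shift tables converges to Φ(δ/(σ√2))."""
    delta, sigma, n = 2.0, 1.0, 10_000
    labels = {f"m{i}": ("active" if i < 42 else "decoy") for i in range(n)}
    tables = generate_score_tables(labels, seed=9, n_programs=2, delta=delta, sigma=sigma)
    analytic = norm.cdf(delta / (sigma * np.sqrt(2)))
    bool_labels = {k: v == "active" for k, v in labels.items()}
    # Monte-Carlo SE of the AUC with 42 positives
    se = np.sqrt(analytic * (1 - analytic) / 42)
    for table in tables:
        outcome = ScreenOutcome.from_scores(table.scores, bool_labels)
        assert roc_auc(outcome)[2] == pytest.approx(analytic, abs=3 * se)


def test_success_criterion_fractions():
    # 42 actives, 30 in the top 10% of 420 compounds
    pattern = ["d"] * 420
    for i in range(30):
        pattern[i] = "a"
    for i in range(12):
        pattern[400 + i] = "a"
    outcome = outcome_from_pattern("".join(pattern))
    assert success_criterion(outcome, 0.10, 0.5) is True  # 30/42 >= 0.5
    # 20 in top 10%
    pattern = ["d"] * 420
    for i in range(20):
        pattern[i] = "a"
    for i in range(22):
        pattern[300 + i] = "a"
    outcome = outcome_from_pattern("".join(pattern))
    assert success_criterion(outcome, 0.10, 0.5) is False  # 20/42 < 0.5
    assert success_criterion(outcome, 0.10, 0.0) is True  # vacuous


def test_enrichment_report_surfaces_invariants():
    outcome = outcome_from_pattern("aadadddddd" * 5)
    report = enrichment_report(outcome, depth_fractions=(0.1, 0.5, 1.0))
    assert (report.rows["ef"] <= report.rows["ideal_ef"] + 1e-12).all()
    assert report.rows["pct_ef"].between(0, 100 + 1e-9).all()
    assert 0.0 <= report.auc <= 1.0


def test_ideal_n_total_override_reproduces_round_reference_values():
    # 42 actives in 10,042 compounds, nominal library size 10,000
    pattern = "a" * 42 + "d" * 10_000
    outcome = outcome_from_pattern(pattern)
    report = enrichment_report(
        outcome, depth_fractions=(0.05,), ideal_n_total=10_000
    )
    row = report.rows.iloc[0]
    assert row["n_sampled"] == 502
    assert row["ideal_ef"] == pytest.approx(
        ideal_enrichment_factor(10_000, 42, 502)
    )
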