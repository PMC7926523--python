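import numpy as np
import pytest

from vsfunnel.chemio import standardize
from vsfunnel.datasets import TNF_ACTIVES_ENVELOPE, structure_based_model_synthetic
from vsfunnel.descriptors import compute_descriptors
from vsfunnel.energetics import EnergyComponents, summarize_frames, total_from_components
from vsfunnel.pharmacophore import PharmacophoreModel, match_features
from vsfunnel.similarity import fingerprint, tanimoto
from vsfunnel.synthetic import (
    SyntheticSpec,
    generate_energy_frames,
    generate_feature_sets,
    generate_library,
    generate_score_tables,
    generate_trajectory,
    plant_actives,
)


def test_library_deterministic_under_seed():
    a = generate_library(100, seed=7)
    b = generate_library(100, seed=7)
    assert a.ids == b.ids
    assert [r.smiles() for r in a] == [r.smiles() for r in b]
    c = generate_library(100, seed=8)
    assert [r.smiles() for r in a] != [r.smiles() for r in c]


def test_all_generated_molecules_standardize():
    lib = generate_library(60, seed=1)
    for rec in lib:
        out = standardize(rec)
        assert out.num_heavy_atoms > 0


def test_generated_library_spans_reference_envelope():
    lib = generate_library(200, seed=11)
    inside = sum(
        TNF_ACTIVES_ENVELOPE.contains(compute_descriptors(r)) for r in lib
    )
    assert inside / len(lib) >= 0.80


def test_planted_actives_identity_at_depth_zero(query_records):
    lib = generate_library(50, seed=2)
    planted, labels = plant_actives(lib, query_records, 5, seed=3, edit_depth=0)
    actives = [planted.get(k) for k, v in labels.items() if v == "active"]
    assert len(actives) == 5
    qfp = {q.id: fingerprint(q) for q in query_records}
    for rec in actives:
        assert tanimoto(fingerprint(rec), qfp[rec.properties["parent_query"]]) == 1.0


def test_planted_actives_high_similarity_at_depth_one(query_records):
    lib = generate_library(100, seed=4)
    planted, labels = plant_actives(lib, query_records, 20, seed=5, edit_depth=1)
    actives = [planted.get(k) for k, v in labels.items() if v == "active"]
    qfps = [fingerprint(q) for q in query_records]
    high = sum(
        max(tanimoto(fingerprint(r), q) for q in qfps) >= 0.85 for r in actives
    )
    assert high / len(actives) >= 0.90
    assert len(planted) == len(lib)  # replacement, not growth


def test_plant_actives_validates_inputs(query_records):
    lib = generate_library(5, seed=0)
    with pytest.raises(ValueError):
        plant_actives(lib, [], 2)
    with pytest.raises(ValueError):
        plant_actives(lib, query_records, 10)


def test_score_tables_deterministic_and_shifted():
    labels = {f"m{i}": ("active" if i < 20 else "decoy") for i in range(500)}
    a = generate_score_tables(labels, seed=3, delta=2.0)
    b = generate_score_tables(labels, seed=3, delta=2.0)
    for ta, tb in zip(a, b):
        assert ta.scores == tb.scores
    actives_mean = np.mean([a[0].scores[f"m{i}"] for i in range(20)])
    decoys_mean = np.mean([a[0].scores[f"m{i}"] for i in range(20, 500)])
    assert actives_mean < decoys_mean  # shifted toward better (lower) scores


def test_null_scores_do_not_discriminate():
    from vsfunnel.enrichment import ScreenOutcome, roc_auc

    labels = {f"m{i}": ("active" if i < 500 else "decoy") for i in range(10_000)}
    table = generate_score_tables(labels, seed=8, n_programs=1, delta=0.0)[0]
    outcome = ScreenOutcome.from_scores(
        table.scores, {k: v == "active" for k, v in labels.items()}
    )
    assert roc_auc(outcome)[2] == pytest.approx(0.5, abs=0.02)


def test_feature_sets_jitter_contract():
    model = structure_based_model_synthetic()
    exact = generate_feature_sets(model, jitter=0.0, n=5, seed=1)
    for feats, label in exact:
        if label == 1:
            assert match_features(feats, model).passed
    far = generate_feature_sets(model, jitter=15.0, n=5, seed=2, n_distractors=0)
    strict = PharmacophoreModel(model.features, min_match=len(model))
    for feats, label in far:
        if label == 1:
            assert not match_features(feats, strict).passed


def test_scrambled_negatives_fail_full_match():
    model = structure_based_model_synthetic()
    strict = PharmacophoreModel(model.features, min_match=len(model))
    sets = generate_feature_sets(model, jitter=0.0, n=5, seed=3, n_distractors=0)
    for feats, label in sets:
        if label == 0:
            assert not match_features(feats, strict).passed


def test_trajectory_determinism_and_chains():
    a = generate_trajectory(10, 50, sigma=0.2, seed=5)
    b = generate_trajectory(10, 50, sigma=0.2, seed=5)
    np.testing.assert_array_equal(a.coords, b.coords)
    assert set(a.chain_ids) == {"A", "B"}


def test_energy_frames_noiseless_and_recovery():
    truth = EnergyComponents(-45.0, -10.0, 28.0, -3.7)
    clean = generate_energy_frames(truth, 0.0, 10, seed=0)
    rec = summarize_frames(clean, "x")
    assert rec.mean == pytest.approx(total_from_components(truth), abs=1e-12)
    noisy = generate_energy_frames(truth, 3.0, 10_000, seed=1)
    rec = summarize_frames(noisy, "x")
    # five components, each mean within ~3σ/√n; total tolerance scaled accordingly
    assert rec.mean == pytest.approx(
        total_from_components(truth), abs=3 * 3.0 * np.sqrt(5) / np.sqrt(10_000)
    )
    same = generate_energy_frames(truth, 3.0, 100, seed=2)
    again = generate_energy_frames(truth, 3.0, 100, seed=2)
    assert same.equals(again)


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(score_sigma=0.0)
    with pytest.raises(ValueError):
        SyntheticSpec(n_compounds=10, n_actives=20)
    spec = SyntheticSpec()
    assert spec.n_compounds == 10_000 and spec.n_actives == 42
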