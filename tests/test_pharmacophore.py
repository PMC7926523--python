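import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vsfunnel.chemio import CompoundLibrary, MoleculeRecord, embed_conformers, standardize
from vsfunnel.datasets import structure_based_model_synthetic
from vsfunnel.pharmacophore import (
    PharmacophoreFeature,
    PharmacophoreModel,
    build_model_from_overlay,
    match_features,
    load_model,
    perceive_features,
    save_model,
    screen_by_model,
    validate_model,
)
from tests.conftest import record_from_smiles


def brute_force_best_match(candidate, model):
    """Exhaustive assignment enumeration: the largest kind-consistent,
    distance-consistent injective mapping of model features onto candidate
    features. Independent of the clique implementation."""
    n_model = len(model.features)
    best = 0
    for size in range(n_model, 0, -1):
        for model_subset in itertools.combinations(range(n_model), size):
            cands_per_feature = [
                [
                    j
                    for j, cf in enumerate(candidate)
                    if cf.kind == model.features[i].kind
                ]
                for i in model_subset
            ]
            for assignment in itertools.product(*cands_per_feature):
                if len(set(assignment)) != size:
                    continue
                ok = True
                for (ai, mi), (aj, mj) in itertools.combinations(
                    zip(assignment, model_subset), 2
                ):
                    dm = np.linalg.norm(
                        np.array(model.features[mi].center)
                        - np.array(model.features[mj].center)
                    )
                    dc = np.linalg.norm(
                        np.array(candidate[ai].center) - np.array(candidate[aj].center)
                    )
                    if abs(dm - dc) > model.features[mi].radius + model.features[mj].radius:
                        ok = False
                        break
                if ok:
                    best = max(best, size)
                    break
            if best >= size:
                return best
    return best


def embedded(smiles, name="mol", n=1, seed=7):
    return embed_conformers(standardize(record_from_smiles(name, smiles)), n=n, seed=seed)


def rigid(features, seed=0):
    rot = Rotation.random(random_state=seed).as_matrix()
    shift = np.array([3.0, -7.0, 11.0])
    return [
        PharmacophoreFeature(f.kind, tuple(rot @ np.array(f.center) + shift), f.radius)
        for f in features
    ]


# --- perception --------------------------------------------------------------

def test_methane_has_no_features():
    rec = embedded("C", "methane")
    assert perceive_features(rec) == []


def test_benzene_aromatic_centroid():
    rec = embedded("c1ccccc1", "benzene")
    feats = perceive_features(rec)
    aro = [f for f in feats if f.kind == "ARO"]
    assert len(aro) == 1
    ring_centroid = rec.conformer(0)[:6].mean(axis=0)  # heavy atoms come first
    assert np.allclose(aro[0].xyz, ring_centroid, atol=1e-8)


def test_protonated_ethylamine_is_cationic_donor():
    rec = embedded("CC[NH3+]", "ethylammonium")
    kinds = {f.kind for f in perceive_features(rec)}
    assert "CAT" in kinds and "HBD" in kinds


def test_carboxylate_perceived_as_anion():
    rec = embedded("CCCC(=O)[O-]", "butanoate")
    assert any(f.kind == "ANI" for f in perceive_features(rec))


def test_perception_requires_conformer(small_molecules):
    with pytest.raises(ValueError, match="conformer"):
        perceive_features(small_molecules["benzene"])


# --- model construction ------------------------------------------------------

def cloud(center, kind="HYD"):
    return PharmacophoreFeature(kind, tuple(center))


def test_overlay_of_identical_copies_reproduces_features():
    feats = [cloud((0, 0, 0), "HYD"), cloud((4, 0, 0), "HBA")]
    model = build_model_from_overlay([feats, list(feats)])
    assert sorted(f.kind for f in model.features) == ["HBA", "HYD"]
    assert all(f.radius == 1.5 for f in model.features)


def test_consensus_cluster_kept_singleton_excluded():
    jitters = [(0.1, 0, 0), (0, 0.2, 0), (-0.1, -0.1, 0.1)]
    overlay = [[cloud(j, "HYD")] for j in jitters]
    overlay[0].append(cloud((8, 8, 8), "HBA"))  # one molecule-unique acceptor
    model = build_model_from_overlay(overlay, consensus_fraction=0.75)
    kinds = [f.kind for f in model.features]
    assert kinds == ["HYD"]
    assert np.allclose(model.features[0].xyz, np.mean(jitters, axis=0), atol=1e-8)


def test_strict_consensus_drops_incomplete_clusters():
    overlay = [
        [cloud((0, 0, 0)), cloud((6, 0, 0))],
        [cloud((0.1, 0, 0)), cloud((6.1, 0, 0))],
        [cloud((0, 0.1, 0))],  # lacks the second cluster
    ]
    model = build_model_from_overlay(overlay, consensus_fraction=1.0)
    assert len(model.features) == 1


def test_overlay_needs_two_molecules():
    with pytest.raises(ValueError):
        build_model_from_overlay([[cloud((0, 0, 0))]])


# --- matching ----------------------------------------------------------------

def test_model_matches_itself_exactly():
    model = structure_based_model_synthetic(min_match=6)
    result = match_features(list(model.features), model)
    assert result.passed and result.matched == 6
    assert result.deviation == pytest.approx(0.0, abs=1e-12)


def test_match_invariant_under_rigid_transform():
    model = structure_based_model_synthetic()
    for seed in range(5):
        result = match_features(rigid(model.features, seed), model)
        assert result.passed and result.matched == 6
        assert result.deviation == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("jitter, should_pass", [(0.4, True), (5.0, False)])
def test_jittered_candidates_verified_against_enumeration(jitter, should_pass):
    model = structure_based_model_synthetic()
    rng = np.random.default_rng(17)
    cand = [
        PharmacophoreFeature(f.kind, tuple(np.array(f.center) + rng.normal(0, jitter, 3)))
        for f in model.features
    ]
    result = match_features(rigid(cand, 3), model)
    assert result.matched == brute_force_best_match(cand, model)
    assert result.passed is should_pass or result.matched >= model.min_match


def test_clique_equals_enumeration_on_random_feature_sets():
    rng = np.random.default_rng(5)
    kinds = ("HYD", "HBA", "HBD", "CAT")
    for trial in range(8):
        model = PharmacophoreModel(
            tuple(
                PharmacophoreFeature(kinds[rng.integers(4)], tuple(rng.uniform(-6, 6, 3)))
                for _ in range(int(rng.integers(3, 7)))
            ),
            min_match=2,
        )
        cand = [
            PharmacophoreFeature(kinds[rng.integers(4)], tuple(rng.uniform(-6, 6, 3)))
            for _ in range(int(rng.integers(2, 8)))
        ]
        assert match_features(cand, model).matched == brute_force_best_match(cand, model)


def test_lowering_min_match_never_fails_a_pass():
    base = structure_based_model_synthetic()
    rng = np.random.default_rng(2)
    cand = [
        PharmacophoreFeature(f.kind, tuple(np.array(f.center) + rng.normal(0, 0.8, 3)))
        for f in base.features
    ]
    passes = []
    for mm in range(len(base.features), 0, -1):
        model = PharmacophoreModel(base.features, min_match=mm)
        passes.append(match_features(cand, model).passed)
    # once it passes at some min_match, it passes at every lower one
    assert passes == sorted(passes)


def test_empty_candidate_fails_gracefully():
    model = structure_based_model_synthetic()
    result = match_features([], model)
    assert not result.passed and result.matched == 0


def test_model_invariants():
    with pytest.raises(ValueError):
        PharmacophoreModel((), min_match=1)
    with pytest.raises(ValueError):
        PharmacophoreModel(
            (PharmacophoreFeature("HYD", (0, 0, 0)),), min_match=2
        )
    with pytest.raises(ValueError):
        PharmacophoreFeature("XYZ", (0, 0, 0))


# --- screening & validation --------------------------------------------------

def _feature_record(rec_id, feats):
    """Wrap a raw feature list so screen_by_model sees one 'conformer'."""

    class _Shim:
        def __init__(self):
            self.id = rec_id
            self.properties = {}
            self.num_conformers = 1

    return _Shim(), feats


def test_screen_retrieves_planted_matchers(monkeypatch):
    from vsfunnel import pharmacophore as ph
    from vsfunnel.synthetic import generate_feature_sets

    model = structure_based_model_synthetic()
    sets = generate_feature_sets(model, jitter=0.2, n=10, seed=3)
    carrier = embedded("C", "carrier").mol  # any molecule with one conformer
    records = [
        MoleculeRecord(f"c{i}", carrier) for i in range(len(sets))
    ]
    feature_map = {f"c{i}": feats for i, (feats, _) in enumerate(sets)}
    labels = {f"c{i}": label for i, (_, label) in enumerate(sets)}
    monkeypatch.setattr(
        ph, "perceive_features", lambda rec, ci=0, radius=1.5: feature_map[rec.id]
    )
    lib = CompoundLibrary(records, provenance="feature clouds")
    retrieved = set(ph.screen_by_model(lib, model).ids)
    positives = {k for k, v in labels.items() if v == 1}
    assert positives <= retrieved
    # kind-scrambled negatives must not satisfy a strict 6-of-6 match
    strict = ph.PharmacophoreModel(model.features, min_match=6)
    assert set(ph.screen_by_model(lib, strict).ids) <= positives


def test_validate_model_arithmetic_and_disjointness(query_records):
    model = structure_based_model_synthetic(min_match=1)
    actives = CompoundLibrary(
        [embedded("c1ccc(CCN)cc1C(C)C", f"act{i}") for i in range(2)][:1]
        + [embedded("CCCCc1ccccc1O", "act1")]
    )
    decoys = CompoundLibrary([embedded("C", "dec0"), embedded("CC", "dec1")])
    report = validate_model(model, actives, decoys)
    assert report.actives_total == 2
    assert report.percent_retrieval == 100.0 * report.actives_retrieved / 2
    overlapping = CompoundLibrary([actives.records[0]])
    with pytest.raises(ValueError, match="overlap"):
        validate_model(model, actives, overlapping)


def test_model_round_trip_serialization(tmp_path):
    model = structure_based_model_synthetic()
    path = tmp_path / "model.txt"
    save_model(model, path)
    back = load_model(path)
    assert back.min_match == model.min_match
    assert len(back) == len(model)
    for a, b in zip(model.features, back.features):
        assert a.kind == b.kind
        assert np.allclose(a.xyz, b.xyz, atol=1e-4)
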