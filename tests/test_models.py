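import numpy as np
import pytest

from clinsts.data_io import SentencePair, SyntheticConfig, generate_pairs
from clinsts.errors import InvalidInputError, StateError
from clinsts.models import (
    EncoderConfig,
    FEATURE_FAMILIES,
    FEATURE_NAMES,
    FeatureContext,
    FeatureVector,
    encoder_inputs,
    extract_features,
    feature_matrix,
    train_encoder,
    train_ensemble,
    train_random_forest,
)


def test_feature_vector_has_frozen_14_slot_order():
    assert len(FEATURE_NAMES) == 14
    assert FEATURE_NAMES == (
        "jaccard", "generalized_jaccard", "dice", "ochiai", "tfidf",
        "qgram3", "qgram4",
        "bag", "levenshtein", "needleman_wunsch", "smith_waterman",
        "embedding_cosine",
        "entity_sim", "number_sim",
    )


def test_feature_families_partition_as_5_2_4_1_2():
    counts = {fam: len(slots) for fam, slots in FEATURE_FAMILIES.items()}
    assert counts == {"token": 5, "character": 2, "sequence": 4, "semantic": 1, "entity": 2}
    flat = [s for slots in FEATURE_FAMILIES.values() for s in slots]
    assert sorted(flat) == sorted(FEATURE_NAMES)


def test_feature_vector_rejects_out_of_range_values():
    kwargs = {n: 0.5 for n in FEATURE_NAMES}
    FeatureVector(**kwargs)
    with pytest.raises(InvalidInputError):
        FeatureVector(**{**kwargs, "jaccard": 1.5})
    with pytest.raises(InvalidInputError):
        FeatureVector(**{**kwargs, "dice": float("nan")})


def test_identical_sentences_maximize_every_feature(small_ctx):
    text = "historian denies abdominal pain and nausea"
    pair = SentencePair("px", text, text)
    fv = extract_features(pair, small_ctx)
    assert np.allclose(fv.to_array(), 1.0)


def test_fully_disjoint_pair_zeroes_surface_features(small_ctx):
    # no shared tokens or concepts, all cross-token Jaro < 0.6, number on one side
    pair = SentencePair(
        "py", "historian denies abdominal pain", "take 2 tablets by mouth"
    )
    fv = extract_features(pair, small_ctx)
    for slot in ("jaccard", "generalized_jaccard", "dice", "ochiai", "tfidf",
                 "qgram3", "qgram4", "entity_sim", "number_sim"):
        assert getattr(fv, slot) == 0.0, slot


def test_features_symmetric_under_sentence_swap(small_ctx, small_pairs):
    for p in small_pairs[:10]:
        fwd = extract_features(p, small_ctx).to_array()
        rev = extract_features(
            SentencePair(p.pair_id, p.text_b, p.text_a, p.gold_score), small_ctx
        ).to_array()
        assert np.allclose(fwd, rev)


def test_extract_features_requires_fitted_context(small_pairs):
    with pytest.raises(StateError):
        extract_features(small_pairs[0], FeatureContext())


def test_random_forest_constant_scores_and_determinism(small_ctx, small_pairs):
    X = feature_matrix(small_pairs[:20], small_ctx)
    const = train_random_forest(X, [3.0] * 20, seed=0, n_estimators=20)
    assert np.allclose(const.predict(X), 3.0)
    y = [p.gold_score for p in small_pairs[:20]]
    b1 = train_random_forest(X, y, seed=7, n_estimators=50)
    b2 = train_random_forest(X, y, seed=7, n_estimators=50)
    assert np.array_equal(b1.predict(X), b2.predict(X))


def test_random_forest_rejects_out_of_range_scores(small_ctx, small_pairs):
    X = feature_matrix(small_pairs[:5], small_ctx)
    with pytest.raises(InvalidInputError):
        train_random_forest(X, [1.0, 2.0, 3.0, 4.0, 6.0])


def test_random_forest_interpolates_training_data():
    pairs = generate_pairs(SyntheticConfig(n_pairs=400, seed=1))
    ctx = FeatureContext().fit_idf(pairs)
    X = feature_matrix(pairs, ctx)
    y = np.array([p.gold_score for p in pairs])
    bundle = train_random_forest(X, y, seed=1, n_estimators=100)
    r = np.corrcoef(bundle.predict(X), y)[0, 1]
    assert r > 0.9


def test_encoder_input_composition(backend):
    pairs = [SentencePair("p1", "patient denies pain", "patient reports pain")]
    X = encoder_inputs(pairs, backend)
    assert X.shape == (1, 4 * backend.dim)
    d = backend.dim
    v1, v2, absdiff, prod = X[0, :d], X[0, d:2*d], X[0, 2*d:3*d], X[0, 3*d:]
    assert np.allclose(absdiff, np.abs(v1 - v2))
    assert np.allclose(prod, v1 * v2)
    Xs = encoder_inputs(pairs, backend, elementwise_product=False)
    assert Xs.shape == (1, 3 * d + 1)
    assert Xs[0, -1] == pytest.approx(float(v1 @ v2))


def test_encoder_config_validation():
    with pytest.raises(InvalidInputError):
        EncoderConfig(hidden_sizes=(10, 10))
    with pytest.raises(InvalidInputError):
        EncoderConfig(learning_rate=0.0)
    with pytest.raises(InvalidInputError):
        EncoderConfig(dropout=1.0)
    assert EncoderConfig().hidden_sizes == (480, 240, 80)


def test_encoder_requires_validation_pairs(backend, small_pairs):
    with pytest.raises(InvalidInputError):
        train_encoder(small_pairs[:5], [], backend)


def test_encoder_predicts_one_bounded_score_per_pair(backend, small_pairs):
    cfg = EncoderConfig(seed=0, max_epochs=5)
    bundle = train_encoder(small_pairs[:20], small_pairs[20:30], backend, cfg)
    X = encoder_inputs(small_pairs[:7], backend)
    pred = bundle.predict(X)
    assert pred.shape == (7,)
    assert np.all((pred >= 0) & (pred <= 5))
    assert bundle.predict(np.zeros((0, X.shape[1]))).shape == (0,)


def test_encoder_seeded_retraining_is_bit_identical(backend, small_pairs):
    cfg = EncoderConfig(seed=3, max_epochs=30)
    b1 = train_encoder(small_pairs[:30], small_pairs[30:40], backend, cfg)
    b2 = train_encoder(small_pairs[:30], small_pairs[30:40], backend, cfg)
    X = encoder_inputs(small_pairs[40:50], backend)
    assert np.array_equal(b1.predict(X), b2.predict(X))


def test_fingerprint_mismatch_refused(small_ctx, small_pairs):
    X = feature_matrix(small_pairs[:10], small_ctx)
    y = [p.gold_score for p in small_pairs[:10]]
    bundle = train_random_forest(X, y, fingerprint="fp-train")
    with pytest.raises(InvalidInputError):
        bundle.predict(X, fingerprint="fp-other")
    bundle.predict(X, fingerprint="fp-train")  # matching fingerprint passes


def test_ensemble_recovers_identity_on_perfect_component(rng):
    gold = rng.uniform(0, 5, size=50)
    bundle = train_ensemble(gold[:, None], gold)
    w, b, _ = bundle.predictor
    assert abs(w[0] - 1) < 1e-8 and abs(b) < 1e-8
    assert np.allclose(bundle.predict(gold[:, None]), gold)


def test_ensemble_downweights_noise_component(rng):
    gold = rng.uniform(0, 5, size=10_000)
    noise = rng.uniform(0, 5, size=10_000)
    bundle = train_ensemble(np.column_stack([gold, noise]), gold)
    w, _, _ = bundle.predictor
    assert abs(w[0] - 1) < 0.01
    assert abs(w[1]) < 0.01


def test_ensemble_drops_duplicate_columns_and_rejects_empty(rng):
    gold = rng.uniform(0, 5, size=30)
    P = np.column_stack([gold, gold])
    bundle = train_ensemble(P, gold)
    assert bundle.predictor[2] == [0]  # second identical column dropped
    assert np.allclose(bundle.predict(P), gold)
    with pytest.raises(InvalidInputError):
        train_ensemble(np.zeros((10, 0)), np.zeros(10))


def test_bundle_serialization_round_trip(tmp_path, backend, small_ctx, small_pairs):
    from clinsts.models import load_bundle, save_bundle

    X = feature_matrix(small_pairs[:20], small_ctx)
    y = [p.gold_score for p in small_pairs[:20]]
    rf = train_random_forest(X, y, seed=1, n_estimators=30, fingerprint="fp")
    enc = train_encoder(
        small_pairs[:20], small_pairs[20:26], backend,
        EncoderConfig(seed=1, max_epochs=10), fingerprint="fp",
    )
    ens = train_ensemble(np.column_stack([y, np.linspace(0, 5, 20)]), y)
    Xe = encoder_inputs(small_pairs[:8], backend)
    P = np.column_stack([rf.predict(X[:8]), enc.predict(Xe)])
    for bundle, inputs in ((rf, X[:8]), (enc, Xe), (ens, P)):
        d = tmp_path / bundle.kind
        save_bundle(bundle, d)
        loaded = load_bundle(d)
        assert loaded.kind == bundle.kind
        assert loaded.fingerprint == bundle.fingerprint
        assert np.allclose(loaded.predict(inputs), bundle.predict(inputs))
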