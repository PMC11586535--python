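import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from caninepcg.features import SpectrogramConfig
from caninepcg.grades import GRADES, grade_index
from caninepcg.model import (Ensemble, GradeDistribution, GRUModel, ModelConfig,
                             aggregate_patient, binary_murmur_probability,
                             build_base_model, finetune_crossval,
                             loud_or_greater_probability, predict_grade,
                             spectrogram_batch, stratified_patient_folds,
                             surrogate_pretrain, train_model,
                             transfer_head_surgery)
from caninepcg.pipeline import make_pretrain_set
from caninepcg.synth import SynthesisConfig, synthesize_pcg

FAST_SPEC = SpectrogramConfig(window_length=400, hop_length=320, fft_size=512)
TINY = ModelConfig(hidden_size=24, max_epochs=30, learning_rate=0.01,
                   early_stopping_patience=8, seed=3)


def _dist(*p):
    return GradeDistribution(np.array(p, dtype=float))


# --------------------------------------------------------------------------
# construction & backprop correctness


def test_seeded_initialization_is_deterministic():
    a = build_base_model(ModelConfig(seed=4), input_dim=10)
    b = build_base_model(ModelConfig(seed=4), input_dim=10)
    c = build_base_model(ModelConfig(seed=5), input_dim=10)
    for k in a.params:
        np.testing.assert_array_equal(a.params[k], b.params[k])
    assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)


def test_forward_shape():
    m = build_base_model(ModelConfig(num_output_classes=2, seed=0), input_dim=7)
    logits = m.predict_logits(np.zeros((3, 20, 7)))
    assert logits.shape == (3, 2)


def test_gradients_match_finite_differences():
    """BPTT gradients agree with central differences on a tiny 2-layer net."""
    cfg = ModelConfig(hidden_size=4, num_layers=2, num_output_classes=3, seed=1)
    m = GRUModel(cfg, input_dim=3)
    rng = np.random.default_rng(0)
    X = rng.standard_normal((2, 5, 3))
    y = np.array([0, 2])
    _, grads = m.loss_and_grads(X, y)
    eps = 1e-6
    for name, arr in m.params.items():
        flat = arr.ravel()
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = m.loss(X, y)
            flat[idx] = orig - eps
            lm = m.loss(X, y)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[name].ravel()[idx]
            assert abs(num - ana) <= 1e-5 + 1e-4 * abs(num), (name, num, ana)


# --------------------------------------------------------------------------
# head surgery


@pytest.fixture(scope="module")
def pretrained_tiny():
    cfg = ModelConfig(hidden_size=24, num_output_classes=2, max_epochs=10,
                      learning_rate=0.01, early_stopping_patience=4, seed=21)
    base = build_base_model(cfg, spectrogram=FAST_SPEC)
    X, y = make_pretrain_set(48, seed=100, features=FAST_SPEC)
    hist = surrogate_pretrain(base, X, y, seed=50)
    return base, X, y, hist


def test_pretrained_base_separates_easy_set(pretrained_tiny):
    base, _, _, _ = pretrained_tiny
    Xh, yh = make_pretrain_set(32, seed=200, features=FAST_SPEC)
    auc = roc_auc_score(yh, base.predict_proba(Xh)[:, 1])
    assert auc >= 0.95


def test_pretraining_is_deterministic():
    cfg = ModelConfig(hidden_size=8, num_output_classes=2, max_epochs=3,
                      seed=77, batch_size=8)
    X, y = make_pretrain_set(12, seed=5, features=FAST_SPEC)
    runs = []
    for _ in range(2):
        m = build_base_model(cfg, spectrogram=FAST_SPEC)
        runs.append(surrogate_pretrain(m, X, y, seed=9).train_loss)
    assert runs[0] == runs[1]


def test_permuted_labels_are_unpredictable_on_heldout_dogs():
    """With shuffled labels there is nothing learnable: held-out AUC against
    the permuted labels sits at chance."""
    aucs = []
    X, y = make_pretrain_set(96, seed=300, features=FAST_SPEC)
    for perm_seed in (1, 2, 3):
        rng = np.random.default_rng(perm_seed)
        y_perm = rng.permutation(y)
        tr, ho = slice(0, 64), slice(64, 96)
        cfg = ModelConfig(hidden_size=16, num_output_classes=2, max_epochs=8,
                          learning_rate=0.01, seed=perm_seed)
        m = build_base_model(cfg, spectrogram=FAST_SPEC)
        surrogate_pretrain(m, X[tr], y_perm[tr], seed=perm_seed)
        aucs.append(roc_auc_score(y_perm[ho], m.predict_proba(X[ho])[:, 1]))
    assert 0.4 <= float(np.mean(aucs)) <= 0.6


def test_surgery_outputs_uniform_distribution(pretrained_tiny):
    base, X, _, _ = pretrained_tiny
    model = transfer_head_surgery(base, 5)
    probs = model.predict_proba(X[:4])
    np.testing.assert_allclose(probs, 0.2, atol=1e-12)


def test_surgery_preserves_nonfinal_parameters_bitwise(pretrained_tiny):
    base, _, _, _ = pretrained_tiny
    model = transfer_head_surgery(base, 5)
    for k in base.params:
        if not k.startswith("head_"):
            assert np.array_equal(base.params[k], model.params[k])
    assert model.params["head_W"].shape[1] == 5
    assert not np.any(model.params["head_W"])


def test_copied_layers_receive_gradient_during_finetuning(pretrained_tiny):
    """No layer is frozen: recurrent weights move once the head is non-zero."""
    base, X, y, _ = pretrained_tiny
    model = transfer_head_surgery(base, 5)
    y5 = np.where(y == 1, 3, 0)          # loud vs none grades
    _, grads0 = model.loss_and_grads(X[:16], y5[:16])
    # with an all-zero head no signal reaches the recurrent stack yet
    assert all(np.allclose(grads0[k], 0) for k in grads0 if k.startswith("gru"))
    train_model(model, X[:16], y5[:16], seed=0)
    _, grads1 = model.loss_and_grads(X[:16], y5[:16])
    gru_norm = sum(np.abs(grads1[k]).sum() for k in grads1 if k.startswith("gru"))
    assert gru_norm > 0
    moved = any(not np.array_equal(base.params[k], model.params[k])
                for k in base.params if k.startswith("gru"))
    assert moved


def test_surgery_rejects_bad_class_count(pretrained_tiny):
    base, _, _, _ = pretrained_tiny
    with pytest.raises(ValueError):
        transfer_head_surgery(base, 1)


# --------------------------------------------------------------------------
# probability reductions and aggregation


@pytest.mark.parametrize("p,expected", [
    ((1, 0, 0, 0, 0), 0.0),
    ((0.3, 0.3, 0.2, 0.1, 0.1), 0.7),
    ((0, 0.25, 0.25, 0.25, 0.25), 1.0),
])
def test_binary_murmur_probability(p, expected):
    assert binary_murmur_probability(_dist(*p)) == pytest.approx(expected)


@pytest.mark.parametrize("p,expected", [
    ((0, 0, 0, 0.6, 0.4), 1.0),
    ((0.2, 0.2, 0.2, 0.2, 0.2), 0.4),
    ((1, 0, 0, 0, 0), 0.0),
])
def test_loud_or_greater_probability(p, expected):
    assert loud_or_greater_probability(_dist(*p)) == pytest.approx(expected)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
       st.integers(0, 3), st.integers(1, 4), st.floats(0.1, 1.0))
def test_mass_shift_toward_higher_grades_is_monotone(weights, lo, step, frac):
    """Moving probability mass upward never decreases either reduction."""
    hi = min(4, lo + step)
    p = np.array(weights) / np.sum(weights)
    q = p.copy()
    moved = frac * q[lo]
    q[lo] -= moved
    q[hi] += moved
    d_p, d_q = _dist(*p), _dist(*(q / q.sum()))
    assert binary_murmur_probability(d_q) >= binary_murmur_probability(d_p) - 1e-12
    assert loud_or_greater_probability(d_q) >= loud_or_greater_probability(d_p) - 1e-12


def test_distribution_validation():
    with pytest.raises(ValueError):
        _dist(0.5, 0.5, 0.5, 0, 0)
    with pytest.raises(ValueError):
        GradeDistribution(np.array([1.0, 0.0]))


def test_aggregate_patient_shared_maxima():
    pred = aggregate_patient({
        "left_apex": _dist(0, 0, 0, 0.9, 0.1),
        "left_base": _dist(0, 0, 0.1, 0.8, 0.1),
        "right_side": _dist(0.1, 0.8, 0.1, 0, 0),
    })
    assert pred.murmur_flag
    assert pred.sites_of_maximal_predicted_grade == {"left_apex", "left_base"}


def test_aggregate_patient_all_none_and_single_site():
    quiet = aggregate_patient({s: _dist(0.9, 0.1, 0, 0, 0)
                               for s in ("left_apex", "left_base")})
    assert not quiet.murmur_flag
    assert quiet.sites_of_maximal_predicted_grade == set()
    single = aggregate_patient({"left_apex": _dist(0.2, 0.7, 0.1, 0, 0)})
    assert single.murmur_flag
    assert single.sites_of_maximal_predicted_grade == {"left_apex"}
    with pytest.raises(ValueError):
        aggregate_patient({})


# --------------------------------------------------------------------------
# folds and ensembles


def test_folds_partition_patients():
    pids = [f"p{i}" for i in range(50)]
    labels = {p: i % 5 for i, p in enumerate(pids)}
    folds = stratified_patient_folds(pids, labels, k=5, seed=0)
    sizes = np.bincount(list(folds.values()), minlength=5)
    assert sizes.tolist() == [10] * 5
    with pytest.raises(ValueError):
        stratified_patient_folds(pids[:3], labels, k=5)


def test_ensemble_of_identical_members_equals_single(pretrained_tiny):
    base, X, _, _ = pretrained_tiny
    ens = Ensemble(members=[base, base.clone(), base.clone()])
    np.testing.assert_allclose(ens.predict_proba(X[:3]),
                               base.predict_proba(X[:3]), atol=1e-12)


def test_ensemble_prediction_order_invariant(pretrained_tiny):
    base, X, _, _ = pretrained_tiny
    other = build_base_model(ModelConfig(hidden_size=24, num_output_classes=2,
                                         seed=99), spectrogram=FAST_SPEC)
    a = Ensemble(members=[base, other]).predict_proba(X[:3])
    b = Ensemble(members=[other, base]).predict_proba(X[:3])
    np.testing.assert_allclose(a, b, atol=1e-12)
    with pytest.raises(ValueError):
        Ensemble(members=[]).predict_proba(X[:1])


# --------------------------------------------------------------------------
# fine-tuning on separable synthetic data


@pytest.fixture(scope="module")
def finetuned(small_cohort, pretrained_tiny):
    from caninepcg.evaluate import recordings_to_arrays
    base, _, _, _ = pretrained_tiny
    records, recordings = small_cohort
    X, y, pids, sites = recordings_to_arrays(records, recordings, FAST_SPEC)
    model = transfer_head_surgery(base, 5)
    model.config = TINY
    ens = finetune_crossval(model, X, y, pids, k=5, seed=13)
    return ens, X, y, pids


def test_finetune_folds_partition_and_descend(finetuned):
    ens, _, _, pids = finetuned
    assert set(ens.fold_assignment.values()) == set(range(5))
    assert set(ens.fold_assignment) == set(pids)
    for hist in ens.histories:
        assert hist.train_loss[0] > hist.train_loss[-1]


def test_heldout_fold_accuracy_on_separable_cohort(finetuned):
    ens, X, y, pids = finetuned
    fold_of = np.array([ens.fold_assignment[p] for p in pids])
    accs = []
    for fold, member in enumerate(ens.members):
        mask = fold_of == fold
        pred = member.predict_proba(X[mask]).argmax(axis=1)
        accs.append(float(np.mean(pred == y[mask])))
    assert float(np.mean(accs)) >= 0.8


def test_predict_grade_identifies_loud_recordings(finetuned):
    ens, _, _, _ = finetuned
    hits = 0
    for seed in range(10):
        rec = synthesize_pcg(SynthesisConfig(murmur_grade="loud", seed=seed,
                                             heart_rate=100 + 5 * seed))
        dist = predict_grade(ens, rec, FAST_SPEC)
        assert abs(dist.probabilities.sum() - 1) < 1e-6
        if dist.argmax_grade in ("loud", "thrilling"):
            hits += 1
    assert hits >= 8


def test_surrogate_pretrain_rejects_nonbinary_labels(pretrained_tiny):
    base, X, _, _ = pretrained_tiny
    with pytest.raises(ValueError):
        surrogate_pretrain(base.clone(), X, np.full(len(X), 3))
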