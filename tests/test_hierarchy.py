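"""Hierarchical model bank: training structure, Bayes inversion, posterior
fusion, conventional baseline, timelines, serialization."""

import copy

import numpy as np
import pytest

from emgintent import SimConfig, simulate_dataset
from emgintent.gmm_hmm import FitOptions, HmmModel, StateEmission
from emgintent.hierarchy import (
    ConventionalModel, HierarchicalModel, PipelineSettings, decode_timeline,
    fuse_posteriors, idle_posterior, load_model, motion_posterior_given_idle,
    predict_conventional, predict_intention, predict_trial,
    predict_with_known_idle, save_model, train_conventional,
    train_hierarchical,
)
from emgintent.preprocess import (
    extract_idle_sequence, extract_initiation_sequence,
)


def _stub_hmm(mean, dim=2, var=1.0):
    e = StateEmission([1.0], [np.full(dim, float(mean))], [np.eye(dim) * var])
    return HmmModel(1, [1.0], [[1.0]], [e])


def _stub_hierarchical(ism_means=(0.0, 0.0), mim_means=None, dim=2):
    """Tiny hand-built hierarchy over 1-state HMMs for arithmetic checks."""
    from emgintent.preprocess import PcaModel
    idle_classes, motion_classes = ("prepared", "relaxed"), ("pull", "push")
    if mim_means is None:
        mim_means = {(c, m): 0.0 for c in idle_classes for m in motion_classes}
    pca = PcaModel(center=np.zeros(dim), scale=np.ones(dim),
                   eigenvalues=np.ones(dim), eigenvectors=np.eye(dim),
                   p=dim, kept=np.ones(dim, dtype=bool))
    return HierarchicalModel(
        isms={c: _stub_hmm(m, dim) for c, m in zip(idle_classes, ism_means)},
        mims={k: _stub_hmm(v, dim) for k, v in mim_means.items()},
        pca_idle=pca, pca_init=copy.deepcopy(pca),
        idle_prior={c: 0.5 for c in idle_classes},
        motion_prior={c: {m: 0.5 for m in motion_classes}
                      for c in idle_classes},
        settings=PipelineSettings(n_states=1, n_components=1),
        idle_classes=idle_classes, motion_classes=motion_classes)


def _seq(vals, origin="idle"):
    from emgintent.preprocess import FeatureSequence
    return FeatureSequence(vectors=np.atleast_2d(vals), step=0.02,
                           origin=origin)


# ---------------------------------------------------------------------------
# Training structure
# ---------------------------------------------------------------------------

def test_trained_bank_structure(trained_hierarchical):
    m = trained_hierarchical
    assert set(m.isms) == {"relaxed", "prepared"}
    assert set(m.mims) == {(c, mm) for c in ("relaxed", "prepared")
                           for mm in ("push", "pull")}
    for hmm in list(m.isms.values()) + list(m.mims.values()):
        assert hmm.n_states == 3
        assert all(e.n_components == 4 for e in hmm.emissions)
        assert hmm.topology == "left-to-right"


def test_balanced_training_gives_uniform_priors(trained_hierarchical):
    for p in trained_hierarchical.idle_prior.values():
        assert p == pytest.approx(0.5)
    for cond in trained_hierarchical.motion_prior.values():
        for p in cond.values():
            assert p == pytest.approx(0.5)


def test_training_is_deterministic(small_dataset, light_opts, tmp_path):
    a = train_hierarchical(small_dataset, light_opts)
    b = train_hierarchical(small_dataset, light_opts)
    save_model(a, tmp_path / "a.json")
    save_model(b, tmp_path / "b.json")
    assert (tmp_path / "a.json").read_text() == (tmp_path / "b.json").read_text()


def test_missing_condition_rejected(small_dataset, light_opts):
    partial = [t for t in small_dataset
               if not (t.idle_label == "prepared" and t.motion_label == "pull")]
    with pytest.raises(ValueError, match="prepared"):
        train_hierarchical(partial, light_opts)


def test_conventional_pools_over_idle_states(trained_conventional):
    assert set(trained_conventional.models) == {"push", "pull"}
    for hmm in trained_conventional.models.values():
        assert hmm.n_states == 3


# ---------------------------------------------------------------------------
# Posterior arithmetic (stub models)
# ---------------------------------------------------------------------------

def test_identical_isms_give_uniform_idle_posterior():
    model = _stub_hierarchical()
    post = idle_posterior(_seq([0.3, -0.2]), model)
    assert post["prepared"] == pytest.approx(0.5, abs=1e-12)
    assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)


def test_idle_posterior_log_odds_match_bayes_rule():
    model = _stub_hierarchical(ism_means=(0.0, 1.0))
    model.idle_prior = {"prepared": 0.7, "relaxed": 0.3}
    from emgintent.gmm_hmm import forward_loglik
    x = _seq([0.4, 0.1])
    post = idle_posterior(x, model)
    ll_p = forward_loglik(x.vectors, model.isms["prepared"])
    ll_r = forward_loglik(x.vectors, model.isms["relaxed"])
    expect = (ll_p - ll_r) + np.log(0.7 / 0.3)
    got = np.log(post["prepared"] / post["relaxed"])
    assert got == pytest.approx(expect, abs=1e-10)


def test_identical_mims_give_uniform_motion_posterior():
    model = _stub_hierarchical()
    post = motion_posterior_given_idle(_seq([0.1, 0.1], "initiation"),
                                       model, "prepared")
    assert post["push"] == pytest.approx(0.5, abs=1e-12)


def test_motion_posterior_matches_softmax_oracle():
    model = _stub_hierarchical(mim_means={
        ("prepared", "push"): 0.5, ("prepared", "pull"): -0.5,
        ("relaxed", "push"): 0.0, ("relaxed", "pull"): 0.0})
    model.motion_prior["prepared"] = {"push": 0.6, "pull": 0.4}
    from emgintent.gmm_hmm import forward_loglik
    x = _seq([0.2, 0.8], "initiation")
    post = motion_posterior_given_idle(x, model, "prepared")
    logits = {m: forward_loglik(x.vectors, model.mims[("prepared", m)])
              + np.log(model.motion_prior["prepared"][m])
              for m in ("push", "pull")}
    z = np.exp(logits["push"]) + np.exp(logits["pull"])
    assert post["push"] == pytest.approx(np.exp(logits["push"]) / z,
                                         abs=1e-10)


def test_unknown_idle_class_rejected():
    model = _stub_hierarchical()
    with pytest.raises(ValueError, match="unknown idle class"):
        motion_posterior_given_idle(_seq([0.0, 0.0]), model, "startled")


def test_fusion_is_the_stated_convex_combination():
    """P(push) = 0.9 * 0.8 + 0.6 * 0.2 = 0.84, exactly."""
    fused = fuse_posteriors(
        {"prepared": 0.8, "relaxed": 0.2},
        {"prepared": {"push": 0.9, "pull": 0.1},
         "relaxed": {"push": 0.6, "pull": 0.4}})
    assert fused["push"] == pytest.approx(0.9 * 0.8 + 0.6 * 0.2, abs=1e-10)
    assert sum(fused.values()) == pytest.approx(1.0, abs=1e-10)


def test_agreeing_conditionals_make_idle_posterior_irrelevant():
    cond = {"prepared": {"push": 0.7, "pull": 0.3},
            "relaxed": {"push": 0.7, "pull": 0.3}}
    for w in (0.1, 0.5, 0.95):
        fused = fuse_posteriors({"prepared": w, "relaxed": 1 - w}, cond)
        assert fused["push"] == pytest.approx(0.7, abs=1e-12)


def test_known_idle_equals_conditional_posterior():
    model = _stub_hierarchical(mim_means={
        ("prepared", "push"): 1.0, ("prepared", "pull"): -1.0,
        ("relaxed", "push"): 0.0, ("relaxed", "pull"): 0.0})
    x = _seq([0.9, 0.9], "initiation")
    known = predict_with_known_idle(x, model, "prepared")
    cond = motion_posterior_given_idle(x, model, "prepared")
    for m in cond:
        assert known.motion_post[m] == pytest.approx(cond[m], abs=1e-12)
    assert known.idle_post == {"prepared": 1.0, "relaxed": 0.0}


def test_point_mass_idle_reduces_fusion_to_known_idle():
    model = _stub_hierarchical(mim_means={
        ("prepared", "push"): 1.0, ("prepared", "pull"): -1.0,
        ("relaxed", "push"): 2.0, ("relaxed", "pull"): -2.0})
    x_mi = _seq([0.9, 0.9], "initiation")
    cond = motion_posterior_given_idle(x_mi, model, "prepared")
    fused = fuse_posteriors({"prepared": 1.0, "relaxed": 0.0},
                            {"prepared": cond,
                             "relaxed": motion_posterior_given_idle(
                                 x_mi, model, "relaxed")})
    known = predict_with_known_idle(x_mi, model, "prepared")
    for m in cond:
        assert fused[m] == pytest.approx(known.motion_post[m], abs=1e-12)


def test_identical_pooled_models_give_uniform_conventional_posterior():
    from emgintent.preprocess import PcaModel
    pca = PcaModel(center=np.zeros(2), scale=np.ones(2),
                   eigenvalues=np.ones(2), eigenvectors=np.eye(2), p=2,
                   kept=np.ones(2, dtype=bool))
    conv = ConventionalModel(
        models={"push": _stub_hmm(0.0), "pull": _stub_hmm(0.0)},
        pca_init=pca, motion_prior={"push": 0.5, "pull": 0.5},
        settings=PipelineSettings(), motion_classes=("pull", "push"))
    post = predict_conventional(_seq([1.0, -1.0], "initiation"), conv)
    assert post["push"] == pytest.approx(0.5, abs=1e-12)


# ---------------------------------------------------------------------------
# End-to-end prediction on trained models
# ---------------------------------------------------------------------------

def test_posteriors_normalize_on_real_trials(small_dataset,
                                             trained_hierarchical):
    for trial in small_dataset[:6]:
        post = predict_trial(trial, trained_hierarchical)
        assert sum(post.motion_post.values()) == pytest.approx(1.0,
                                                               abs=1e-10)
        assert sum(post.idle_post.values()) == pytest.approx(1.0, abs=1e-10)
        assert post.decision in ("push", "pull")


def test_known_idle_beats_or_ties_inferred_idle_on_average(
        small_dataset, trained_hierarchical):
    """Information ordering: conditioning on the true idle state cannot be
    worse in expectation than inferring it."""
    hier = known = 0
    for trial in small_dataset:
        x_mi = extract_initiation_sequence(trial)
        hier += predict_trial(trial, trained_hierarchical).decision \
            == trial.motion_label
        known += predict_with_known_idle(
            x_mi, trained_hierarchical, trial.idle_label).decision \
            == trial.motion_label
    assert known >= hier - 1  # allow one-trial noise at this sample size


def test_serialization_round_trip_preserves_posteriors(
        small_dataset, trained_hierarchical, trained_conventional, tmp_path):
    save_model(trained_hierarchical, tmp_path / "h.json")
    save_model(trained_conventional, tmp_path / "c.json")
    h2 = load_model(tmp_path / "h.json")
    c2 = load_model(tmp_path / "c.json")
    for trial in small_dataset[:4]:
        a = predict_trial(trial, trained_hierarchical)
        b = predict_trial(trial, h2)
        assert a.motion_post == b.motion_post  # bit-identical
        x_mi = extract_initiation_sequence(trial)
        assert predict_conventional(x_mi, trained_conventional) \
            == predict_conventional(x_mi, c2)


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------

def test_timeline_occupancy_sums_to_one(small_dataset, trained_hierarchical):
    frame = decode_timeline(small_dataset, trained_hierarchical,
                            t_grid=[0.3, 0.15, 0.0])
    for t, grp in frame.groupby("t_before_onset"):
        assert grp["occupancy"].sum() == pytest.approx(1.0, abs=1e-10)
        assert grp["accuracy"].nunique() == 1


def test_timeline_at_onset_matches_full_sequence_accuracy(
        small_dataset, trained_hierarchical):
    frame = decode_timeline(small_dataset, trained_hierarchical, t_grid=[0.0])
    acc_timeline = frame["accuracy"].iloc[0]
    correct = sum(predict_trial(t, trained_hierarchical).decision
                  == t.motion_label for t in small_dataset)
    assert acc_timeline == pytest.approx(correct / len(small_dataset),
                                         abs=1e-12)


def test_timeline_posterior_mode_also_normalizes(small_dataset,
                                                 trained_hierarchical):
    frame = decode_timeline(small_dataset[:8], trained_hierarchical,
                            t_grid=[0.2, 0.0], state_mode="posterior")
    for _, grp in frame.groupby("t_before_onset"):
        assert grp["occupancy"].sum() == pytest.approx(1.0, abs=1e-10)


def test_timeline_rejects_empty_grid(small_dataset, trained_hierarchical):
    with pytest.raises(ValueError):
        decode_timeline(small_dataset, trained_hierarchical, t_grid=[])


def test_zero_ramp_amplitude_removes_class_signal(light_opts):
    """With all initiation ramps at zero there is no class information; a
    trained predictor must hover at chance on held-out-style evaluation."""
    flat = {k: tuple(0.0 for _ in range(6))
            for k in (("relaxed", "push"), ("relaxed", "pull"),
                      ("prepared", "push"), ("prepared", "pull"))}
    cfg = SimConfig(trials_per_condition=10, seed=31,
                    initiation_ramp_profiles=flat, envelope_floor=0.05)
    trials = simulate_dataset(cfg, 1)
    train, test = trials[:20], trials[20:]
    # ensure all four conditions present in the training half
    if len({(t.idle_label, t.motion_label) for t in train}) < 4:
        train, test = trials[:28], trials[28:]
    model = train_hierarchical(train, light_opts)
    correct = sum(predict_trial(t, model).decision == t.motion_label
                  for t in test)
    assert 0.2 <= correct / len(test) <= 0.8
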