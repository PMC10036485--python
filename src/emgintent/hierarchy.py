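"""Hierarchical dynamic Bayesian network for pre-onset intention prediction.

Two banks of GMM-HMMs: per idle class an *idle-state model* (ISM) trained on
the 600 ms pre-cue segment, and per (idle, motion) pair a *motion-initiation
model* (MIM) trained on the cue-to-onset segment conditioned on that idle
state.  Prediction fuses the banks by marginalizing over the idle state:

    P(c_mot | X_idle, X_MI) = sum_{c_idle} P(c_mot | X_MI, c_idle)
                                           P(c_idle | X_idle)

where each conditional is a Bayes inversion of the corresponding model
likelihoods with training-frequency priors.  A conventional (idle-pooled)
GMM-HMM baseline, oracle-idle prediction, time-resolved partial-sequence
prediction, and decoded-state occupancy timelines complete the module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import preprocess as pp
from .gmm_hmm import FitOptions, HmmModel, em_fit, forward_loglik, viterbi_decode
from .preprocess import FeatureSequence, FilterSpec, PcaModel, fit_pca, project
from .synth import TrialRecording

__all__ = [
    "PipelineSettings", "HierarchicalModel", "ConventionalModel",
    "IntentionPosterior", "train_hierarchical", "train_conventional",
    "idle_posterior", "motion_posterior_given_idle", "fuse_posteriors",
    "predict_intention", "predict_with_known_idle", "predict_conventional",
    "predict_trial", "decode_timeline", "save_model", "load_model",
]


@dataclass
class PipelineSettings:
    """Feature-pipeline and model-architecture configuration."""

    n_states: int = 3
    n_components: int = 4
    topology: str = "left-to-right"
    window: float = pp.FEATURE_WINDOW
    smoothing: float = pp.FEATURE_WINDOW
    var_frac: float = 0.95
    filter_spec: FilterSpec = field(default_factory=FilterSpec)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineSettings":
        d = dict(d)
        if "filter_spec" in d and isinstance(d["filter_spec"], dict):
            d["filter_spec"] = FilterSpec(**d["filter_spec"])
        return cls(**d)


@dataclass
class IntentionPosterior:
    """Posterior over motion (and idle) classes for one trial at one time."""

    motion_post: dict[str, float]
    idle_post: dict[str, float]
    loglik: dict[str, float]          # per-model log-likelihoods
    evaluation_time: float | None = None  # s relative to onset (<= 0: early)

    @property
    def decision(self) -> str:
        # argmax; ties resolved by fixed class order (dict insertion order)
        return max(self.motion_post, key=lambda c: (self.motion_post[c],))


@dataclass
class HierarchicalModel:
    isms: dict[str, HmmModel]
    mims: dict[tuple[str, str], HmmModel]
    pca_idle: PcaModel
    pca_init: PcaModel
    idle_prior: dict[str, float]
    motion_prior: dict[str, dict[str, float]]   # per idle class
    settings: PipelineSettings
    idle_classes: tuple[str, ...]
    motion_classes: tuple[str, ...]


@dataclass
class ConventionalModel:
    """Idle-pooled baseline: one GMM-HMM per motion class."""

    models: dict[str, HmmModel]
    pca_init: PcaModel
    motion_prior: dict[str, float]
    settings: PipelineSettings
    motion_classes: tuple[str, ...]


def _group_trials(trials: Sequence[TrialRecording]
                  ) -> tuple[tuple[str, ...], tuple[str, ...],
                             dict[tuple[str, str], list[TrialRecording]]]:
    idle_classes = tuple(sorted({t.idle_label for t in trials}))
    motion_classes = tuple(sorted({t.motion_label for t in trials}))
    groups: dict[tuple[str, str], list[TrialRecording]] = {}
    for t in trials:
        groups.setdefault((t.idle_label, t.motion_label), []).append(t)
    missing = [(i, m) for i in idle_classes for m in motion_classes
               if (i, m) not in groups]
    if missing:
        raise ValueError(f"missing (idle, motion) conditions: {missing}")
    return idle_classes, motion_classes, groups


def _extract_features(trials: Sequence[TrialRecording],
                      settings: PipelineSettings
                      ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    idle_feats, init_feats = [], []
    for t in trials:
        idle_feats.append(pp.extract_idle_sequence(
            t, settings.filter_spec, settings.window,
            settings.smoothing).vectors)
        init_feats.append(pp.extract_initiation_sequence(
            t, None, settings.filter_spec, settings.window,
            settings.smoothing).vectors)
    return idle_feats, init_feats


def _seed_for(base: int, tag: str) -> int:
    # stable per-model child seed, independent of dict ordering
    h = 2166136261
    for ch in tag.encode():
        h = ((h ^ ch) * 16777619) % (2 ** 32)
    return (base ^ h) % (2 ** 31)


def train_hierarchical(trials: Sequence[TrialRecording],
                       fit_options: FitOptions | None = None,
                       settings: PipelineSettings | None = None
                       ) -> HierarchicalModel:
    """Fit one ISM per idle class and one MIM per (idle, motion) pair.

    One PCA (95% total-variance rule) is fitted on the pooled idle-segment
    features and shared by all ISMs, another on the pooled initiation
    features shared by all MIMs, so sibling model likelihoods live in a
    common feature space.  Class priors are training frequencies.
    """
    settings = settings or PipelineSettings()
    fit_options = fit_options or FitOptions()
    idle_classes, motion_classes, groups = _group_trials(trials)
    for key, group in groups.items():
        if len(group) < 2:
            raise ValueError(f"need >= 2 trials per condition; {key} has "
                             f"{len(group)}")
    idle_feats, init_feats = _extract_features(trials, settings)
    pca_idle = fit_pca(np.vstack(idle_feats), settings.var_frac)
    pca_init = fit_pca(np.vstack(init_feats), settings.var_frac)

    idle_by_class: dict[str, list[np.ndarray]] = {c: [] for c in idle_classes}
    init_by_pair: dict[tuple[str, str], list[np.ndarray]] = {
        (i, m): [] for i in idle_classes for m in motion_classes}
    for t, fi, fm in zip(trials, idle_feats, init_feats):
        idle_by_class[t.idle_label].append(project(fi, pca_idle))
        init_by_pair[(t.idle_label, t.motion_label)].append(
            project(fm, pca_init))

    isms = {}
    for c in idle_classes:
        opts = dataclasses.replace(fit_options,
                                   seed=_seed_for(fit_options.seed, f"ism:{c}"))
        isms[c], _ = em_fit(idle_by_class[c], settings.n_states,
                            settings.n_components, opts, settings.topology)
    mims = {}
    for pair in init_by_pair:
        opts = dataclasses.replace(
            fit_options,
            seed=_seed_for(fit_options.seed, f"mim:{pair[0]}:{pair[1]}"))
        mims[pair], _ = em_fit(init_by_pair[pair], settings.n_states,
                               settings.n_components, opts, settings.topology)

    n = len(trials)
    idle_prior = {c: sum(t.idle_label == c for t in trials) / n
                  for c in idle_classes}
    motion_prior = {}
    for c in idle_classes:
        n_c = sum(t.idle_label == c for t in trials)
        motion_prior[c] = {
            m: len(groups[(c, m)]) / n_c for m in motion_classes}
    return HierarchicalModel(
        isms=isms, mims=mims, pca_idle=pca_idle, pca_init=pca_init,
        idle_prior=idle_prior, motion_prior=motion_prior, settings=settings,
        idle_classes=idle_classes, motion_classes=motion_classes)


def train_conventional(trials: Sequence[TrialRecording],
                       fit_options: FitOptions | None = None,
                       settings: PipelineSettings | None = None
                       ) -> ConventionalModel:
    """Idle-pooled baseline: one GMM-HMM per motion class trained on the
    union of initiation sequences across idle states."""
    settings = settings or PipelineSettings()
    fit_options = fit_options or FitOptions()
    _, motion_classes, _ = _group_trials(trials)
    _, init_feats = _extract_features(trials, settings)
    pca_init = fit_pca(np.vstack(init_feats), settings.var_frac)
    by_motion: dict[str, list[np.ndarray]] = {m: [] for m in motion_classes}
    for t, fm in zip(trials, init_feats):
        by_motion[t.motion_label].append(project(fm, pca_init))
    models = {}
    for m in motion_classes:
        opts = dataclasses.replace(fit_options,
                                   seed=_seed_for(fit_options.seed, f"conv:{m}"))
        models[m], _ = em_fit(by_motion[m], settings.n_states,
                              settings.n_components, opts, settings.topology)
    prior = {m: sum(t.motion_label == m for t in trials) / len(trials)
             for m in motion_classes}
    return ConventionalModel(models=models, pca_init=pca_init,
                             motion_prior=prior, settings=settings,
                             motion_classes=motion_classes)


# ---------------------------------------------------------------------------
# Posterior computation
# ---------------------------------------------------------------------------

def _log_normalize(logp: Mapping[str, float]) -> dict[str, float]:
    keys = list(logp)
    arr = np.array([logp[k] for k in keys], dtype=float)
    arr -= logsumexp(arr)
    return {k: float(np.exp(v)) for k, v in zip(keys, arr)}


def _project_seq(seq: FeatureSequence, pca: PcaModel) -> np.ndarray:
    if seq.vectors.shape[1] == pca.p:        # already projected
        return seq.vectors
    return project(seq.vectors, pca)


def idle_posterior(X_idle: FeatureSequence,
                   model: HierarchicalModel) -> dict[str, float]:
    """P(c_idle | X_idle) from ISM likelihoods and the idle prior."""
    obs = _project_seq(X_idle, model.pca_idle)
    logp = {c: forward_loglik(obs, model.isms[c])
            + float(np.log(model.idle_prior[c]))
            for c in model.idle_classes}
    return _log_normalize(logp)


def motion_posterior_given_idle(X_MI: FeatureSequence,
                                model: HierarchicalModel,
                                c_idle: str) -> dict[str, float]:
    """P(c_mot | X_MI, c_idle) from the MIMs of one idle class."""
    if c_idle not in model.idle_classes:
        raise ValueError(f"unknown idle class {c_idle!r}; "
                         f"valid: {list(model.idle_classes)}")
    obs = _project_seq(X_MI, model.pca_init)
    logp = {m: forward_loglik(obs, model.mims[(c_idle, m)])
            + float(np.log(model.motion_prior[c_idle][m]))
            for m in model.motion_classes}
    return _log_normalize(logp)


def fuse_posteriors(idle_post: Mapping[str, float],
                    conditionals: Mapping[str, Mapping[str, float]]
                    ) -> dict[str, float]:
    """Marginalize the idle state:
    P(c_mot) = sum_idle P(c_mot | idle) P(idle)."""
    motions = list(next(iter(conditionals.values())))
    fused = {m: float(sum(conditionals[c][m] * idle_post[c]
                          for c in idle_post))
             for m in motions}
    total = sum(fused.values())
    return {m: v / total for m, v in fused.items()}


def predict_intention(X_idle: FeatureSequence, X_MI: FeatureSequence,
                      model: HierarchicalModel,
                      evaluation_time: float | None = None
                      ) -> IntentionPosterior:
    """Fused posterior over motion classes for one trial."""
    ip = idle_posterior(X_idle, model)
    conditionals = {c: motion_posterior_given_idle(X_MI, model, c)
                    for c in model.idle_classes}
    fused = fuse_posteriors(ip, conditionals)
    obs = _project_seq(X_MI, model.pca_init)
    obs_idle = _project_seq(X_idle, model.pca_idle)
    loglik = {f"ism:{c}": forward_loglik(obs_idle, model.isms[c])
              for c in model.idle_classes}
    loglik.update({f"mim:{c}:{m}": forward_loglik(obs, model.mims[(c, m)])
                   for c in model.idle_classes for m in model.motion_classes})
    return IntentionPosterior(motion_post=fused, idle_post=ip, loglik=loglik,
                              evaluation_time=evaluation_time)


def predict_with_known_idle(X_MI: FeatureSequence, model: HierarchicalModel,
                            true_idle: str,
                            evaluation_time: float | None = None
                            ) -> IntentionPosterior:
    """Fusion with the idle posterior replaced by a point mass."""
    if true_idle not in model.idle_classes:
        raise ValueError(f"unknown idle class {true_idle!r}")
    cond = motion_posterior_given_idle(X_MI, model, true_idle)
    ip = {c: 1.0 if c == true_idle else 0.0 for c in model.idle_classes}
    obs = _project_seq(X_MI, model.pca_init)
    loglik = {f"mim:{true_idle}:{m}":
              forward_loglik(obs, model.mims[(true_idle, m)])
              for m in model.motion_classes}
    return IntentionPosterior(motion_post=dict(cond), idle_post=ip,
                              loglik=loglik, evaluation_time=evaluation_time)


def predict_conventional(X_MI: FeatureSequence,
                         model: ConventionalModel) -> dict[str, float]:
    """Normalized likelihood x prior under the idle-pooled models."""
    obs = _project_seq(X_MI, model.pca_init)
    logp = {m: forward_loglik(obs, model.models[m])
            + float(np.log(model.motion_prior[m]))
            for m in model.motion_classes}
    return _log_normalize(logp)


def predict_trial(trial: TrialRecording, model: HierarchicalModel,
                  end_time: float | None = None) -> IntentionPosterior:
    """Extract both segments from a raw trial and fuse.  ``end_time``
    truncates the initiation segment for time-resolved prediction."""
    s = model.settings
    X_idle = pp.extract_idle_sequence(trial, s.filter_spec, s.window,
                                      s.smoothing)
    X_MI = pp.extract_initiation_sequence(trial, end_time, s.filter_spec,
                                          s.window, s.smoothing)
    eval_time = None
    if trial.onset_time is not None:
        eval_time = (end_time if end_time is not None
                     else trial.onset_time) - trial.onset_time
    return predict_intention(X_idle, X_MI, model, evaluation_time=eval_time)


# ---------------------------------------------------------------------------
# Time-resolved decoding
# ---------------------------------------------------------------------------

def decode_timeline(trials: Sequence[TrialRecording],
                    model: HierarchicalModel,
                    t_grid: Sequence[float],
                    state_mode: str = "viterbi") -> pd.DataFrame:
    """State occupancy and prediction accuracy as functions of time-to-onset.

    For each grid value t (seconds before onset), initiation sequences are
    truncated at onset - t and (a) the trial's true-condition MIM decodes
    the terminal hidden state (``state_mode='viterbi'``) or its smoothed
    marginal (``'posterior'``); (b) the fused posterior predicts the motion
    class.  Occupancy is the distribution of the decoded terminal state
    across trials (sums to 1 at every t).  Decoding under the true-condition
    MIM is an explanatory analysis of the learned state progression, not a
    deployable decoder; the accuracy column uses only the fused posterior.

    Returns a tidy frame with columns
    (t_before_onset, state, occupancy, accuracy, n_trials).
    """
    t_grid = list(t_grid)
    if not t_grid:
        raise ValueError("t_grid must be non-empty")
    if state_mode not in ("viterbi", "posterior"):
        raise ValueError("state_mode must be 'viterbi' or 'posterior'")
    s = model.settings
    N = s.n_states
    # the idle segment (and hence the idle posterior) is fixed per trial
    idle_posts = {}
    for trial in trials:
        if trial.onset_time is None:
            continue
        X_idle = pp.extract_idle_sequence(trial, s.filter_spec, s.window,
                                          s.smoothing)
        idle_posts[id(trial)] = idle_posterior(X_idle, model)
    rows = []
    for t_ahead in t_grid:
        occ = np.zeros(N)
        correct = 0
        n = 0
        for trial in trials:
            if trial.onset_time is None:
                continue
            end = trial.onset_time - t_ahead
            try:
                X_MI = pp.extract_initiation_sequence(
                    trial, end, s.filter_spec, s.window, s.smoothing)
            except ValueError:
                continue  # trial too short for this grid point
            obs = project(X_MI.vectors, model.pca_init)
            mim = model.mims[(trial.idle_label, trial.motion_label)]
            if state_mode == "viterbi":
                path, _ = viterbi_decode(obs, mim)
                occ[path[-1]] += 1.0
            else:
                occ += _terminal_state_posterior(obs, mim)
            conditionals = {
                c: motion_posterior_given_idle(X_MI, model, c)
                for c in model.idle_classes}
            fused = fuse_posteriors(idle_posts[id(trial)], conditionals)
            decision = max(fused, key=lambda c: (fused[c],))
            correct += decision == trial.motion_label
            n += 1
        if n == 0:
            continue
        occ = occ / occ.sum()
        acc = correct / n
        for j in range(N):
            rows.append({"t_before_onset": t_ahead, "state": j,
                         "occupancy": occ[j], "accuracy": acc,
                         "n_trials": n})
    return pd.DataFrame(rows)


def _terminal_state_posterior(obs: np.ndarray, model: HmmModel) -> np.ndarray:
    """Filtered state distribution at the final step (scaled forward)."""
    logB = model.log_emission_matrix(obs)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = model.startprob * B[0]
    alpha /= alpha.sum()
    for t in range(1, obs.shape[0]):
        alpha = (alpha @ model.transmat) * B[t]
        alpha /= alpha.sum()
    return alpha


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: HierarchicalModel | ConventionalModel, path) -> None:
    """Write a model bundle as JSON (full float precision)."""
    path = Path(path)
    if isinstance(model, HierarchicalModel):
        d = {
            "kind": "hierarchical",
            "idle_classes": list(model.idle_classes),
            "motion_classes": list(model.motion_classes),
            "isms": {c: m.to_dict() for c, m in model.isms.items()},
            "mims": {f"{c}:{m}": hmm.to_dict()
                     for (c, m), hmm in model.mims.items()},
            "pca_idle": model.pca_idle.to_dict(),
            "pca_init": model.pca_init.to_dict(),
            "idle_prior": model.idle_prior,
            "motion_prior": model.motion_prior,
            "settings": model.settings.to_dict(),
        }
    else:
        d = {
            "kind": "conventional",
            "motion_classes": list(model.motion_classes),
            "models": {m: hmm.to_dict() for m, hmm in model.models.items()},
            "pca_init": model.pca_init.to_dict(),
            "motion_prior": model.motion_prior,
            "settings": model.settings.to_dict(),
        }
    path.write_text(json.dumps(d, indent=1))


def load_model(path) -> HierarchicalModel | ConventionalModel:
    d = json.loads(Path(path).read_text())
    settings = PipelineSettings.from_dict(d["settings"])
    if d["kind"] == "hierarchical":
        return HierarchicalModel(
            isms={c: HmmModel.from_dict(m) for c, m in d["isms"].items()},
            mims={tuple(k.split(":")): HmmModel.from_dict(m)
                  for k, m in d["mims"].items()},
            pca_idle=PcaModel.from_dict(d["pca_idle"]),
            pca_init=PcaModel.from_dict(d["pca_init"]),
            idle_prior=d["idle_prior"],
            motion_prior=d["motion_prior"],
            settings=settings,
            idle_classes=tuple(d["idle_classes"]),
            motion_classes=tuple(d["motion_classes"]),
        )
    if d["kind"] == "conventional":
        return ConventionalModel(
            models={m: HmmModel.from_dict(h) for m, h in d["models"].items()},
            pca_init=PcaModel.from_dict(d["pca_init"]),
            motion_prior=d["motion_prior"],
            settings=settings,
            motion_classes=tuple(d["motion_classes"]),
        )
    raise ValueError(f"unknown model kind {d['kind']!r}")
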