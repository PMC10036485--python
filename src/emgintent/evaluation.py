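"""Experimental harness: stratified k-fold cross-validation, accuracy
summaries (mean +- sd in percent), Wilcoxon signed-rank and Lilliefors
tests, a static band-power LDA comparator for idle-state recognition, and
multi-method comparisons on paired folds.

Folds are stratified by the (idle, motion) condition and determined solely
by the trial ordering and the seed, so every method in a comparison is
evaluated on identical train/test splits (the paired design behind the
signed-rank tests).  All model fitting — including PCA — happens inside the
training folds only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from . import hierarchy as hr
from . import preprocess as pp
from .gmm_hmm import FitOptions
from .hierarchy import PipelineSettings
from .synth import TrialRecording

__all__ = [
    "FoldResult", "AccuracySummary", "make_folds", "kfold_cv",
    "wilcoxon_signed_rank", "lilliefors_test", "lda_idle_baseline",
    "compare_methods",
]

TASKS = ("idle", "motion", "hierarchy", "conventional", "known_idle")


@dataclass
class FoldResult:
    fold: int
    true_labels: list[str]
    predicted_labels: list[str]

    @property
    def accuracy(self) -> float:
        t, p = self.true_labels, self.predicted_labels
        return float(np.mean([a == b for a, b in zip(t, p)]))


@dataclass
class AccuracySummary:
    """Per-fold accuracies with mean and sd reported in percent."""

    fold_accuracies: list[float]
    fold_results: list[FoldResult] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracies)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies) * 100.0)

    @property
    def sd(self) -> float:
        if self.n_folds < 2:
            return 0.0
        return float(np.std(self.fold_accuracies, ddof=1) * 100.0)

    @property
    def n_trials(self) -> int:
        return sum(len(f.true_labels) for f in self.fold_results)

    @property
    def overall_accuracy(self) -> float:
        """Trial-weighted accuracy across folds, as a fraction."""
        total = self.n_trials
        correct = sum(
            sum(a == b for a, b in zip(f.true_labels, f.predicted_labels))
            for f in self.fold_results)
        return correct / total if total else float("nan")

    def __str__(self) -> str:
        return f"{self.mean:.2f} +- {self.sd:.2f} % ({self.n_folds} folds)"


def _sorted_trials(trials: Sequence[TrialRecording]) -> list[TrialRecording]:
    return sorted(trials, key=lambda t: (t.subject_id, t.trial_id))


def make_folds(trials: Sequence[TrialRecording], k: int = 5, seed: int = 0
               ) -> list[tuple[list[int], list[int]]]:
    """Stratified fold indices over the (idle, motion) conditions.

    Depends only on the trial ids and the seed; reused across methods so
    comparisons are paired fold-by-fold.
    """
    conditions = [f"{t.idle_label}:{t.motion_label}" for t in trials]
    counts = pd.Series(conditions).value_counts()
    if counts.min() < k:
        short = counts[counts < k].index.tolist()
        raise ValueError(
            f"conditions {short} have fewer than k={k} trials")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train.tolist(), test.tolist())
            for train, test in skf.split(np.zeros(len(trials)), conditions)]


def _default_predictor_factory(task: str, fit_options: FitOptions,
                               settings: PipelineSettings,
                               predict_end_before_onset: float | None):
    """Returns train(trials) -> predict(trial) -> label for one CV task."""

    def _end_time(trial: TrialRecording) -> float | None:
        if predict_end_before_onset is None:
            return None
        return trial.onset_time - predict_end_before_onset

    def factory(train_trials: Sequence[TrialRecording]):
        if task == "conventional":
            model = hr.train_conventional(train_trials, fit_options, settings)

            def predict(trial: TrialRecording) -> str:
                X_MI = pp.extract_initiation_sequence(
                    trial, _end_time(trial), settings.filter_spec,
                    settings.window, settings.smoothing)
                post = hr.predict_conventional(X_MI, model)
                return max(post, key=post.get)
            return predict

        model = hr.train_hierarchical(train_trials, fit_options, settings)

        def predict(trial: TrialRecording) -> str:
            if task == "idle":
                X_idle = pp.extract_idle_sequence(
                    trial, settings.filter_spec, settings.window,
                    settings.smoothing)
                post = hr.idle_posterior(X_idle, model)
                return max(post, key=post.get)
            if task == "known_idle":
                X_MI = pp.extract_initiation_sequence(
                    trial, _end_time(trial), settings.filter_spec,
                    settings.window, settings.smoothing)
                return hr.predict_with_known_idle(
                    X_MI, model, trial.idle_label).decision
            # "hierarchy" / "motion"
            return hr.predict_trial(trial, model, _end_time(trial)).decision
        return predict

    return factory


def _true_label(trial: TrialRecording, task: str) -> str:
    return trial.idle_label if task == "idle" else trial.motion_label


def kfold_cv(trials: Sequence[TrialRecording], k: int = 5,
             task: str = "hierarchy", seed: int = 0,
             fit_options: FitOptions | None = None,
             settings: PipelineSettings | None = None,
             predict_end_before_onset: float | None = None,
             predictor_factory: Callable | None = None) -> AccuracySummary:
    """Stratified k-fold cross-validation of one task.

    Per fold, every model stage (PCA included) is fitted on the k-1
    training folds only; the held-out fold is scored.  Trials too short
    for ``predict_end_before_onset`` truncation are skipped with a warning.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    fit_options = fit_options or FitOptions()
    settings = settings or PipelineSettings()
    trials = _sorted_trials(trials)
    folds = make_folds(trials, k, seed)
    factory = predictor_factory or _default_predictor_factory(
        task, fit_options, settings, predict_end_before_onset)
    results = []
    for fold_idx, (train_idx, test_idx) in enumerate(folds):
        predict = factory([trials[i] for i in train_idx])
        truths, preds = [], []
        for i in test_idx:
            try:
                pred = predict(trials[i])
            except ValueError as err:
                warnings.warn(
                    f"skipping trial {trials[i].trial_id!r} in fold "
                    f"{fold_idx}: {err}", stacklevel=2)
                continue
            truths.append(_true_label(trials[i], task))
            preds.append(pred)
        results.append(FoldResult(fold_idx, truths, preds))
    return AccuracySummary([r.accuracy for r in results], results)


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    return w_pos, ranks


def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float],
                         alternative: str = "two-sided",
                         exact_threshold: int = 12) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples (a - b).

    Zero differences are dropped.  For n <= ``exact_threshold`` the null
    distribution of W+ (sum of positive ranks) is enumerated exactly over
    all 2^n sign assignments (valid with tied magnitudes); otherwise a
    normal approximation with tie correction is used.  ``alternative`` is
    'two-sided', 'greater' (a > b) or 'less'.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided/greater/less")
    d = a - b
    n_zero = int(np.sum(d == 0))
    if n_zero:
        warnings.warn(f"dropping {n_zero} zero difference(s)", stacklevel=2)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate: all paired differences are zero")
    if n < 5:
        warnings.warn("fewer than 5 nonzero differences; test has little "
                      "power", stacklevel=2)
    w_pos, ranks = _signed_rank_statistic(d)

    if n <= exact_threshold:
        # exact null: each |d| contributes its rank with probability 1/2
        w_values = np.zeros(1)
        for r in ranks:
            w_values = np.concatenate([w_values, w_values + r])
        ge = float(np.mean(w_values >= w_pos - 1e-9))
        le = float(np.mean(w_values <= w_pos + 1e-9))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = float(np.sum(counts ** 3 - counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
        z = (w_pos - mean) / np.sqrt(var)
        ge = float(stats.norm.sf(z))
        le = float(stats.norm.cdf(z))
    if alternative == "greater":
        p = ge
    elif alternative == "less":
        p = le
    else:
        p = min(1.0, 2.0 * min(ge, le))
    return w_pos, p


_LILLIEFORS_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_statistic(x: np.ndarray) -> float:
    n = x.size
    z = (np.sort(x) - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def lilliefors_test(values: Sequence[float], n_mc: int = 10000,
                    seed: int = 0) -> tuple[float, float]:
    """Lilliefors normality test (KS distance to a normal with estimated
    mean and sd), with a seeded Monte-Carlo null distribution.

    The null table is simulated once per (n, n_mc, seed) and cached, so
    repeated tests at the same sample size are cheap.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if x.std(ddof=1) <= 0:
        raise ValueError("zero-variance sample")
    d = _lilliefors_statistic(x)
    key = (x.size, n_mc, seed)
    if key not in _LILLIEFORS_NULL_CACHE:
        rng = np.random.default_rng(seed)
        n = x.size
        sims = rng.standard_normal((n_mc, n))
        sims.sort(axis=1)
        means = sims.mean(axis=1, keepdims=True)
        sds = sims.std(axis=1, ddof=1, keepdims=True)
        cdf = stats.norm.cdf((sims - means) / sds)
        grid = np.arange(1, n + 1) / n
        upper = (grid[None, :] - cdf).max(axis=1)
        lower = (cdf - (grid[None, :] - 1.0 / n)).max(axis=1)
        _LILLIEFORS_NULL_CACHE[key] = np.maximum(upper, lower)
    null = _LILLIEFORS_NULL_CACHE[key]
    p = (1.0 + np.sum(null >= d)) / (null.size + 1.0)
    return d, float(p)


# ---------------------------------------------------------------------------
# Static LDA comparator for idle-state recognition
# ---------------------------------------------------------------------------

def _band_power_features(trial: TrialRecording,
                         filter_spec: pp.FilterSpec | None,
                         band: tuple[float, float] = (30.0, 80.0),
                         window: float = pp.IDLE_SEGMENT) -> np.ndarray:
    """Per-channel log band power over the pre-cue idle window.

    The 30-80 Hz band tracks muscle-force level, making this a natural
    static (non-temporal) comparator for idle-state recognition.
    """
    fs = trial.sampling_rate
    i1 = int(round(trial.cue_time * fs))
    i0 = i1 - int(round(window * fs))
    seg = pp.apply_filters(trial.emg[i0:i1], fs, filter_spec)
    nperseg = min(128, seg.shape[0])
    freqs, psd = sps.welch(seg, fs=fs, nperseg=nperseg, axis=0)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    power = np.trapezoid(psd[sel], freqs[sel], axis=0)
    return np.log(np.maximum(power, 1e-300))


def lda_idle_baseline(trials: Sequence[TrialRecording], k: int = 5,
                      seed: int = 0,
                      settings: PipelineSettings | None = None,
                      band: tuple[float, float] = (30.0, 80.0)
                      ) -> AccuracySummary:
    """Regularized LDA on pre-cue log band power (static idle comparator).

    Uses exactly the same stratified folds as ``kfold_cv`` under the same
    seed, so the comparison with the ISM is paired.
    """
    settings = settings or PipelineSettings()

    def factory(train_trials: Sequence[TrialRecording]):
        X = np.array([_band_power_features(t, settings.filter_spec, band)
                      for t in train_trials])
        y = [t.idle_label for t in train_trials]
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)

        def predict(trial: TrialRecording) -> str:
            f = _band_power_features(trial, settings.filter_spec, band)
            return str(lda.predict(f[None, :])[0])
        return predict

    return kfold_cv(trials, k=k, task="idle", seed=seed,
                    settings=settings, predictor_factory=factory)


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------

METHODS = ("hierarchy", "known_idle", "conventional", "idle", "lda_idle")


def compare_methods(trials: Sequence[TrialRecording],
                    seeds: Sequence[int] = (0, 1),
                    k: int = 5,
                    fit_options: FitOptions | None = None,
                    settings: PipelineSettings | None = None,
                    methods: Sequence[str] = METHODS,
                    alternative: str = "greater") -> dict:
    """Run all methods per subject on common folds and compare pairwise.

    Returns a dict with ``accuracies`` (tidy frame: subject, seed, fold,
    method, accuracy), ``summary`` (method, mean %, sd % over subjects x
    seeds x folds), and ``tests`` (pairwise Wilcoxon signed-rank on the
    paired per-fold accuracies).
    """
    seeds = list(seeds)
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    fit_options = fit_options or FitOptions()
    settings = settings or PipelineSettings()
    subjects = sorted({t.subject_id for t in trials})
    records = []
    for subject in subjects:
        subj_trials = [t for t in trials if t.subject_id == subject]
        for seed in seeds:
            for method in methods:
                if method == "lda_idle":
                    summary = lda_idle_baseline(subj_trials, k=k, seed=seed,
                                                settings=settings)
                else:
                    summary = kfold_cv(subj_trials, k=k, task=method,
                                       seed=seed, fit_options=fit_options,
                                       settings=settings)
                for fold, acc in enumerate(summary.fold_accuracies):
                    records.append({"subject": subject, "seed": seed,
                                    "fold": fold, "method": method,
                                    "accuracy": acc})
    acc = pd.DataFrame(records)
    summary = (acc.groupby("method")["accuracy"]
               .agg(["mean", "std"]).mul(100.0)
               .rename(columns={"mean": "mean_pct", "std": "sd_pct"})
               .reset_index())
    tests = []
    wide = acc.pivot_table(index=["subject", "seed", "fold"],
                           columns="method", values="accuracy")
    for m1, m2 in itertools.combinations(methods, 2):
        a, b = wide[m1].to_numpy(), wide[m2].to_numpy()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w, p = wilcoxon_signed_rank(a, b, alternative=alternative)
        except ValueError:
            w, p = float("nan"), float("nan")  # degenerate: identical
        tests.append({"method_a": m1, "method_b": m2, "statistic": w,
                      "p_value": p, "alternative": alternative})
    return {"accuracies": acc, "summary": summary,
            "tests": pd.DataFrame(tests)}
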