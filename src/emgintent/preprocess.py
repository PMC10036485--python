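"""Raw trials -> HMM-ready feature sequences.

Pipeline: Butterworth high-pass (15 Hz, order 3) and notch (50 Hz, order 3)
filtering; instantaneous power (squared amplitude) smoothed by a moving
average; non-overlapping 20 ms windows each summarized by the least-squares
quadratic fit x^(tau) = a0 + a1*tau + a2*tau^2 with tau = 0 at the window's
end, so a0 is the current envelope level and a1, a2 its local dynamics;
optional PCA (95% total-variance rule) on the concatenated per-channel
coefficient triples.

Two segments feed the models: the *idle* segment, the 600 ms immediately
before the cue (30 windows at 500 Hz), and the *initiation* segment, from
100 ms before the cue to the motion onset (variable length).  Segment
extraction is strictly causal: the raw recording is sliced to the segment
before filtering, the filters run forward-only within the slice, and the
envelope uses a trailing moving average, so a window's features depend only
on samples up to that window's end.  Truncating a sequence at an earlier
end time therefore yields an exact prefix — essential for honest
time-resolved (pre-onset) prediction.  Whole-recording filtering through
:func:`apply_filters` stays zero-phase by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .synth import TrialRecording

__all__ = [
    "FilterSpec", "PowerEnvelope", "QuadFeature", "FeatureSequence",
    "PcaModel", "apply_filters", "power_envelope", "quad_features",
    "extract_idle_sequence", "extract_initiation_sequence",
    "detect_motion_onset", "fit_pca", "project", "choose_rank",
    "IDLE_SEGMENT", "PRE_CUE_MARGIN", "FEATURE_WINDOW",
]

IDLE_SEGMENT = 0.600       # s of pre-cue signal used by the idle-state models
PRE_CUE_MARGIN = 0.100     # initiation segment starts this long before the cue
FEATURE_WINDOW = 0.020     # s, sliding-window length (= step; non-overlapping)


@dataclass
class FilterSpec:
    """Butterworth high-pass + notch filter parameters (zero-phase)."""

    highpass_cutoff: float = 15.0
    highpass_order: int = 3
    notch_freq: float = 50.0
    notch_order: int = 3
    notch_bandwidth: float = 4.0  # full stop-band width, Hz

    def validate(self, fs: float) -> None:
        if not 0 < self.highpass_cutoff < fs / 2:
            raise ValueError("highpass_cutoff must lie in (0, fs/2)")
        if not 0 < self.notch_freq < fs / 2:
            raise ValueError("notch_freq must lie in (0, fs/2)")
        if self.highpass_order < 1 or self.notch_order < 1:
            raise ValueError("filter orders must be >= 1")


@dataclass
class PowerEnvelope:
    """Smoothed instantaneous power, (samples, channels), units amplitude^2."""

    values: np.ndarray
    sampling_rate: float
    smoothing_window: float


@dataclass
class QuadFeature:
    """Per-channel quadratic coefficients (a0, a1, a2) of one 20 ms window."""

    a0: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    window_end_time: float


@dataclass
class FeatureSequence:
    """Time-ordered feature vectors feeding an HMM.

    ``vectors`` is (T, d): concatenated per-channel coefficient triples
    (ch0 a0,a1,a2, ch1 a0,a1,a2, ...) or their PCA projection.  ``times``
    are window-end times in seconds relative to the cue.
    """

    vectors: np.ndarray
    step: float
    origin: str                      # "idle" | "initiation"
    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.shape[0] == 0:
            raise ValueError("FeatureSequence must be non-empty")

    def __len__(self) -> int:
        return self.vectors.shape[0]


def apply_filters(emg: np.ndarray, fs: float,
                  spec: FilterSpec | None = None,
                  zero_phase: bool = True) -> np.ndarray:
    """High-pass + band-stop filtering, per channel.

    Zero-phase (forward-backward) by default, for whole-recording use;
    ``zero_phase=False`` applies the filters forward-only (causal), which
    segment extraction uses so that features at time t depend on samples up
    to t only.  Output shape equals input shape; DC is removed and the
    notch band attenuated.  Non-finite samples are rejected naming the
    channel.
    """
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.asarray(emg, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    for ch in range(x.shape[1]):
        if not np.all(np.isfinite(x[:, ch])):
            raise ValueError(f"non-finite samples in channel {ch}")
    hp = signal.butter(spec.highpass_order, spec.highpass_cutoff,
                       btype="highpass", fs=fs, output="sos")
    half = spec.notch_bandwidth / 2.0
    notch = signal.butter(spec.notch_order,
                          [spec.notch_freq - half, spec.notch_freq + half],
                          btype="bandstop", fs=fs, output="sos")
    if zero_phase:
        y = _sosfiltfilt(hp, x)
        y = _sosfiltfilt(notch, y)
    else:
        y = signal.sosfilt(notch, signal.sosfilt(hp, x, axis=0), axis=0)
    return y[:, 0] if squeeze else y


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Zero-phase filtering with a reduced pad on very short segments."""
    try:
        return signal.sosfiltfilt(sos, x, axis=0)
    except ValueError:
        return signal.sosfiltfilt(sos, x, axis=0, padlen=x.shape[0] - 1)


def power_envelope(filtered: np.ndarray, fs: float,
                   smoothing_window: float = FEATURE_WINDOW,
                   causal: bool = False) -> PowerEnvelope:
    """Elementwise square followed by a moving average.

    Centered by default; ``causal=True`` uses a trailing window (mean over
    the ``smoothing_window`` ending at each sample, shorter at the start),
    which segment extraction uses to keep the pipeline causal.
    """
    x = np.atleast_2d(np.asarray(filtered, dtype=float).T).T
    w = max(int(round(smoothing_window * fs)), 1)
    if w > x.shape[0]:
        raise ValueError(
            f"smoothing window of {w} samples exceeds signal length {x.shape[0]}"
        )
    power = x ** 2
    if causal:
        c = np.cumsum(power, axis=0)
        smooth = np.empty_like(power)
        smooth[:w] = c[:w] / np.arange(1, w + 1)[:, None]
        smooth[w:] = (c[w:] - c[:-w]) / w
    else:
        smooth = uniform_filter1d(power, size=w, axis=0, mode="nearest")
    # a moving average of non-negative values is non-negative up to rounding
    np.maximum(smooth, 0.0, out=smooth)
    return PowerEnvelope(values=smooth, sampling_rate=fs,
                         smoothing_window=w / fs)


def _window_design(w: int, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic design for one window: tau = 0 at the window's last sample."""
    tau = (np.arange(w) - (w - 1)) / fs
    design = np.column_stack([np.ones(w), tau, tau ** 2])
    return tau, np.linalg.pinv(design)


def quad_features(envelope: PowerEnvelope,
                  window: float = FEATURE_WINDOW) -> list[QuadFeature]:
    """Least-squares quadratic coefficients per non-overlapping window.

    Windows tile the segment from its start; a trailing remainder shorter
    than one window is dropped.
    """
    values = envelope.values
    fs = envelope.sampling_rate
    w = int(round(window * fs))
    if w < 3:
        raise ValueError("window must span at least 3 samples (3 unknowns)")
    n_win = values.shape[0] // w
    if n_win == 0:
        raise ValueError("segment shorter than one window")
    _, pinv = _window_design(w, fs)
    out = []
    for k in range(n_win):
        seg = values[k * w:(k + 1) * w]
        coefs = pinv @ seg                      # (3, channels)
        out.append(QuadFeature(a0=coefs[0], a1=coefs[1], a2=coefs[2],
                               window_end_time=((k + 1) * w - 1) / fs))
    return out


def _features_to_matrix(feats: Sequence[QuadFeature]) -> np.ndarray:
    """Stack windows into (T, 3*channels): per-channel (a0, a1, a2) triples."""
    rows = [np.column_stack([f.a0, f.a1, f.a2]).ravel() for f in feats]
    return np.asarray(rows)


def _segment_features(trial: TrialRecording, start: float, end: float,
                      spec: FilterSpec | None, window: float,
                      smoothing: float) -> tuple[np.ndarray, np.ndarray]:
    """Slice [start, end) of the raw recording, filter causally within the
    slice, and return (feature matrix, window-end times relative to the
    cue).  Fully causal: the k-th window's features depend only on samples
    in [start, start + (k+1)*window), so a truncated extraction is an exact
    prefix of a longer one."""
    fs = trial.sampling_rate
    i0, i1 = int(round(start * fs)), int(round(end * fs))
    raw = trial.emg[i0:i1]
    filtered = apply_filters(raw, fs, spec, zero_phase=False)
    env = power_envelope(filtered, fs, smoothing, causal=True)
    feats = quad_features(env, window)
    times = start - trial.cue_time + np.array(
        [f.window_end_time for f in feats])
    return _features_to_matrix(feats), times


def extract_idle_sequence(trial: TrialRecording,
                          spec: FilterSpec | None = None,
                          window: float = FEATURE_WINDOW,
                          smoothing: float = FEATURE_WINDOW) -> FeatureSequence:
    """Features of the 600 ms immediately preceding the cue (T = 30 at 500 Hz)."""
    required = IDLE_SEGMENT + 0.1  # transient margin
    if trial.cue_time < required:
        raise ValueError(
            f"insufficient pre-cue data: cue_time={trial.cue_time:.3f}s, "
            f"need >= {required:.3f}s"
        )
    vectors, times = _segment_features(
        trial, trial.cue_time - IDLE_SEGMENT, trial.cue_time,
        spec, window, smoothing)
    return FeatureSequence(vectors=vectors, step=window, origin="idle",
                           times=times)


def extract_initiation_sequence(trial: TrialRecording,
                                end_time: float | None = None,
                                spec: FilterSpec | None = None,
                                window: float = FEATURE_WINDOW,
                                smoothing: float = FEATURE_WINDOW,
                                ) -> FeatureSequence:
    """Features on [cue - 100 ms, end_time).

    ``end_time`` defaults to the motion onset; an earlier value yields the
    partial sequence used for time-resolved (pre-onset) prediction, computed
    from pre-``end_time`` samples only.
    """
    if end_time is None:
        if trial.onset_time is None:
            raise ValueError("trial has no onset_time; pass end_time explicitly")
        end_time = trial.onset_time
    start = trial.cue_time - PRE_CUE_MARGIN
    if end_time < start + window:
        raise ValueError(
            f"end_time={end_time:.3f}s leaves no full window after "
            f"{start:.3f}s (cue - {PRE_CUE_MARGIN * 1e3:.0f} ms)"
        )
    vectors, times = _segment_features(trial, start, end_time,
                                       spec, window, smoothing)
    return FeatureSequence(vectors=vectors, step=window, origin="initiation",
                           times=times)


def detect_motion_onset(joystick_x: np.ndarray, cue_time: float, fs: float,
                        k_sigma: float = 5.0, hold: int = 5,
                        baseline_window: float = 2.0) -> float | None:
    """First post-cue time at which |x - baseline median| exceeds
    ``k_sigma`` robust baseline SDs for ``hold`` consecutive samples.

    The baseline is the idle period preceding the cue (up to
    ``baseline_window`` seconds).  Returns ``None`` when no crossing occurs
    (trial to be flagged invalid).
    """
    x = np.asarray(joystick_x, dtype=float)
    cue_idx = int(round(cue_time * fs))
    b0 = max(0, cue_idx - int(round(baseline_window * fs)))
    baseline = x[b0:cue_idx]
    if baseline.size < int(0.5 * fs):
        raise ValueError("need >= 500 ms of pre-cue baseline")
    med = np.median(baseline)
    sd = 1.4826 * np.median(np.abs(baseline - med))
    if sd <= 0:
        sd = baseline.std()
    if sd <= 0:
        raise ValueError("degenerate (constant) joystick baseline")
    dev = np.abs(x[cue_idx:] - med) > k_sigma * sd
    if dev.size < hold:
        return None
    runs = np.lib.stride_tricks.sliding_window_view(dev, hold).all(axis=1)
    hits = np.flatnonzero(runs)
    if hits.size == 0:
        return None
    return (cue_idx + hits[0]) / fs


# ---------------------------------------------------------------------------
# PCA with the 95% total-variance rule
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    center: np.ndarray        # per-dimension mean (original space)
    scale: np.ndarray         # per-dimension sd
    eigenvalues: np.ndarray   # descending, >= 0
    eigenvectors: np.ndarray  # orthonormal columns (kept dims, all ranks)
    p: int                    # retained dimension
    kept: np.ndarray          # boolean mask of non-constant dimensions
    var_frac: float = 0.95

    @property
    def w_p(self) -> np.ndarray:
        return self.eigenvectors[:, :self.p]

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(), "scale": self.scale.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(), "p": int(self.p),
            "kept": self.kept.astype(int).tolist(),
            "var_frac": float(self.var_frac),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        return cls(center=np.array(d["center"]), scale=np.array(d["scale"]),
                   eigenvalues=np.array(d["eigenvalues"]),
                   eigenvectors=np.array(d["eigenvectors"]), p=int(d["p"]),
                   kept=np.array(d["kept"], dtype=bool),
                   var_frac=float(d["var_frac"]))


def choose_rank(eigenvalues: np.ndarray, var_frac: float = 0.95) -> int:
    """Smallest p whose leading eigenvalues reach ``var_frac`` of the total."""
    lam = np.asarray(eigenvalues, dtype=float)
    frac = np.cumsum(lam) / lam.sum()
    return int(np.searchsorted(frac, var_frac - 1e-12) + 1)


def fit_pca(features: np.ndarray, var_frac: float = 0.95) -> PcaModel:
    """Standardize, eigendecompose the correlation matrix, keep the smallest
    p reaching ``var_frac`` cumulative variance.

    Constant dimensions are dropped with a warning.  Eigenvector signs are
    fixed so each column's largest-magnitude entry is positive.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with n >= 2 rows")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    kept = scale > 1e-12
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} constant feature dimension(s)",
            stacklevel=2)
    if not kept.any():
        raise ValueError("all feature dimensions are constant")
    B = (X[:, kept] - center[kept]) / scale[kept]
    cov = (B.T @ B) / (B.shape[0] - 1)
    lam, W = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.maximum(lam[order], 0.0)
    W = W[:, order]
    flip = W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])] < 0
    W[:, flip] *= -1
    p = choose_rank(lam, var_frac)
    return PcaModel(center=center, scale=scale, eigenvalues=lam,
                    eigenvectors=W, p=p, kept=kept, var_frac=var_frac)


def project(features: np.ndarray, model: PcaModel) -> np.ndarray:
    """Center, scale and project onto the retained eigenvectors."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.center.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match PCA model "
            f"dimension {model.center.shape[0]}"
        )
    B = (X[:, model.kept] - model.center[model.kept]) / model.scale[model.kept]
    return B @ model.w_p
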