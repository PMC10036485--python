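# emgintent

Early (pre-onset) prediction of hand-motion intention from multichannel
surface EMG (sEMG), using a hierarchical bank of Gaussian-mixture hidden
Markov models (GMM-HMMs) that models the *idle* state explicitly.

## The problem

In a cued joystick task a subject rests in one of two designated idle
regimes — **relaxed** (minimal muscle tone) or **prepared** (isometric
hold) — then, after a visual cue, pushes or pulls as the cue demands.  The
goal is to decode *push* vs *pull* from the 6-channel sEMG **before** the
joystick moves, i.e. during motion initiation.  The idle regime shapes how
the muscles transition into motion, so a single pooled model of initiation
confuses dynamics that are cleanly separable once the idle state is known.

## The model

Per subject, two banks of GMM-HMMs (N = 3 left-to-right states, M = 4
Gaussian components) are trained on 20 ms-windowed quadratic-coefficient
features of the sEMG power envelope, PCA-reduced by the 95% total-variance
rule:

- an **idle-state model** (ISM) per idle class, on the 600 ms before the
  cue (T = 30 windows at 500 Hz);
- a **motion-initiation model** (MIM) per (idle, motion) pair, on the
  segment from 100 ms before the cue to the motion onset.

The fused intention posterior marginalizes over the unknown idle state,

    P(c_mot | X_idle, X_MI) = Σ_{c_idle} P(c_mot | X_MI, c_idle) · P(c_idle | X_idle),

with each conditional a Bayes inversion of forward log-likelihoods.
Because feature extraction is strictly causal, the posterior can be
evaluated at any time before motion onset by truncating the initiation
sequence — this yields time-resolved accuracy curves and decoded
hidden-state occupancy timelines.

Since suitable human recordings are private, the package ships a
protocol-faithful synthetic trial simulator (`emgintent.synth`) with known
ground truth: uniform(3–10 s) idle intervals, two idle envelope regimes,
class- and idle-state-specific activation ramps, truncated-normal reaction
times, and an abrupt joystick deflection at onset.  Every downstream stage
is validated against it.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from emgintent import SimConfig, simulate_dataset
from emgintent.evaluation import compare_methods
from emgintent.gmm_hmm import FitOptions

config = SimConfig(trials_per_condition=10, seed=42)
trials = simulate_dataset(config, n_subjects=2)
report = compare_methods(
    trials, seeds=[0], k=5,
    fit_options=FitOptions(max_iter=20, n_init=1, rel_tol=1e-3, seed=0),
)
print(report["summary"].to_string(index=False))
```

prints

```
      method  mean_pct    sd_pct
conventional     76.25 12.430362
   hierarchy     92.50 10.540926
        idle     96.25  6.038074
  known_idle     96.25  6.038074
    lda_idle     97.50  5.270463
```

Reading the table: `hierarchy` is the fused posterior (92.5% motion
accuracy over 5-fold CV of two 40-trial subjects); `conventional` is the
idle-pooled GMM-HMM baseline (76.2% — pooling mixes dissimilar initiation
dynamics); `known_idle` conditions on the true idle state (the ceiling the
hierarchy approaches); `idle` and `lda_idle` are idle-state recognition by
the ISMs and by static band-power LDA.  The accompanying pairwise Wilcoxon
signed-rank table shows hierarchy > conventional with one-sided
p = 0.0156 on the paired fold accuracies.

The same pipeline is scriptable from the shell:

```bash
emgintent simulate --out data/ --subjects 2 --seed 42
emgintent train    --data data/ --out models/
emgintent predict  --data data/ --model models/ --out posteriors.csv
emgintent evaluate --data data/ --out report/
emgintent timeline --data data/ --model models/ --out timeline.csv
```

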