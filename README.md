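# fingerbmi

Detection and correction of *execution errors* in an intracortical
brain–machine interface (BMI) controlling virtual fingers — as a fully
simulated, tested pipeline.

In a finger BMI, binned spiking-band power (SBP) from motor cortex is decoded
into finger-group velocities by a Kalman filter. Decoding is imperfect: the
virtual fingers sometimes move *away* from their targets during a trial.
This package implements, end to end, the idea that the same neural activity
used for decoding also carries information about such erroneous movements —
because motor cortex encodes not only position `P` and velocity `V` but also
the signed distance to the target `D = T − P` (with a lag of ~200 ms), and
possibly a direct error signal — and that detecting and stopping erroneous
movements online improves task performance.

It is written for computational-neuroscience and neural-engineering work:
prototyping error detectors, studying correction policies, and teaching the
closed-loop BMI stack, with every stage replaceable and unit-tested.

## The pipeline

1. **Task simulator** — the two-finger-group target-acquisition task
   (index + middle-ring-small (MRS) groups on arcs in [0, 1], 50 ms bins,
   500 ms hold). The simulated subject is a proportional feedback controller
   with AR(1) motor noise; channels are generated by a lagged linear tuning
   model

   `SBP_c(k) = ω₀ + Σ_g [ω_P P_g(k−6) + ω_V V_g(k) + ω_D D_g(k−4)] + error drive + noise`

2. **Velocity Kalman filter** — state `[P, V, 1]`, observation SBP;
   position rows fixed to exact integration of velocity; trained by least
   squares on a manual-control session (phase I).
3. **Encoding analysis** — single-lag and multi-lag linear models of SBP on
   any subset of {P, V, D}; percent-variance-explained curves with peak
   lags; nested comparison of VPD vs VP (one-sided Wilcoxon across
   channels); per-channel maxima.
4. **Error detection** — overlapping N-bin segments (N = 4, 200 ms) of the
   decoded movement labeled *toward*/*away* per bin by the sign of `V·D`;
   one classifier per (finger group × movement type), trained on balanced
   sets; SWLDA (stepwise feature selection + linear discriminant), QDA and
   linear SVM; thresholds chosen from a validation ROC to keep the false
   positive rate below 5%.
5. **Closed loop** — brain-control phases with detectors monitoring every
   bin and a two-step stopping correction (stop the offending group for
   N bins, pause its detector for 2N bins); orbiting time (OT), time to
   first acquire (TFA) and total time to target (TTT) per trial; ABA
   phase comparison with one-sided Wilcoxon rank-sum tests.

## Worked example

```python
from fingerbmi import (make_fixtures, label_segments, train_detector_bank,
                       run_closed_loop, compute_trial_metrics, compare_aba,
                       CorrectionPolicy, TaskConfig)
from fingerbmi.encoding import variance_curve, compare_nested

# phases I + II: manual training session, Kalman filter, brain control
fx = make_fixtures("error-gain", rng_seed=1, n_trials_train=120, n_trials_brain=300)

# where does the neural activity sit relative to the kinematics?
for reg in ("V", "D"):
    c = variance_curve(fx["manual"], (reg,))
    print(reg, "peak lag", c.attrs["peak_lag"], "bins, max", round(c["mean_pct"].max(), 1), "%")
print("VPD vs VP p =", compare_nested(fx["manual"], L=4)["p_value"])

# train the four error detectors on phase-II segments
segs = label_segments(fx["brain"], n_window=4, channels=fx["kf"].channels_)
bank = train_detector_bank(segs, kind="swlda", rng_seed=11)

# ABA: monitoring / correction / monitoring, 400 trials each
cfg = TaskConfig(hold_time_ms=500.0, n_trials=400)
metrics = {}
for name, on, seed in (("A1", False, 201), ("B", True, 202), ("A2", False, 203)):
    sess, _ = run_closed_loop(fx["kf"], cfg, fx["tuning"], bank=bank,
                              policy=CorrectionPolicy(enabled=on), rng_seed=seed)
    metrics[name] = compute_trial_metrics(sess)
print(compare_aba(metrics["A1"], metrics["B"], metrics["A2"]))
```

Output (abridged):

```
V: peak lag 0 bins (0 ms), max 26.0%
D: peak lag -4 bins (-200 ms), max 18.3%
VPD vs VP (one-sided Wilcoxon): p = 1.53e-05
index extension  FPR  4.9%  TPR 88.9%  AUC 0.98
index flexion    FPR  4.4%  TPR 87.3%  AUC 0.98
MRS   extension  FPR  4.9%  TPR 78.1%  AUC 0.96
MRS   flexion    FPR  4.8%  TPR 87.1%  AUC 0.98
         p_value    mean_a   mean_b  mean_delta
ttt_ms     0.226  1419.875  1318.50    -101.375
ot_ms_0    0.002   807.188   593.00    -214.188
ot_ms_1    0.003   778.750   593.25    -185.500
```

Reading this: velocity explains the most neural variance at zero lag while
the distance-to-target curve peaks when the neural activity lags the
distance by 4 bins (200 ms), and adding D to a velocity+position model
explains significantly more variance. Detector thresholds hold the FPR just
under the 5% design bound. Turning correction on (phase B) cuts mean
orbiting time by roughly 200 ms for both finger groups (significant at
p < 0.01) while the TTT reduction is not significant — the stopping policy
mainly helps fingers *stay* in the target.

## Command line

Every stage is also a subcommand of the `fingerbmi` CLI:

```bash
fingerbmi simulate --trials 500 --seed 1 --out run/manual
fingerbmi train-decoder --session run/manual --out run/kf.json
fingerbmi run-loop --kf run/kf.json --trials 500 --seed 2 --out run/phase2
fingerbmi train-detectors --session run/phase2 --kf run/kf.json --out run/bank.json
fingerbmi run-loop --kf run/kf.json --bank run/bank.json --mode correct \
    --trials 400 --seed 3 --out run/b
fingerbmi report --aba run/a1 run/b run/a2 --out run/report.json
fingerbmi analyze-encoding --session run/manual --regressors VPD --out run/enc.json
fingerbmi make-fixtures --scenario error-gain --seed 1 --out run/fx
```

Sessions are stored as plain CSV tables with a JSON sidecar and round-trip
bit-exactly.

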