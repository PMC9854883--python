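# fusemble

Classifier fusion, ensemble pruning, and one-vs-rest evaluation for
single-label multiclass prediction sets.

## The problem

A common pattern in applied image classification — medical imaging in
particular — is to fine-tune a bank of m convolutional networks on the same
C-class task and then combine their outputs on a shared test set.  `fusemble`
starts exactly where the networks end: its input is, per classifier, an N×C
row-stochastic matrix of class probabilities (or an N-vector of hard labels)
plus the N ground-truth labels, all as delimited text.  From there it
provides:

- **Fusion.** Soft voting (SV), `ŷ = argmax_i Σ_j w_j p_ij` with uniform
  weights; weighted average voting (WAV), the same rule with optimized
  weights; weighted hard voting / weighted majority voting (WHV),
  `ŷ = argmax_i Σ_j w_j 1[C_j(x) = i]`; and stacking (ST), a meta-learner
  (LightGBM or multinomial logistic regression) trained on the concatenated
  member probabilities via stratified k-fold out-of-fold cross-validation.
  WAV/WHV weights are tuned by a seeded Gaussian-process Bayesian search over
  [0,1]^m that always evaluates the uniform vector first, so tuned weights
  never score below uniform on their objective set.
- **Pruning.** The ranking method: members are ordered by standalone overall
  accuracy and every fusion method is swept over the top-k prefixes
  (k = 2..m), re-fitting weights and stacks at each k, to find the best
  ensemble size.
- **Evaluation.** One-vs-rest TP/FP/FN/TN per class; precision, sensitivity,
  specificity, F1 and accuracy with macro averages; Wilson and Wald binomial
  confidence intervals; one-vs-rest ROC AUC with macro average; McNemar's
  paired test `χ² = (n01 − n10)² / (n01 + n10)`; and a Pearson
  diversity matrix of predicted labels with a 0.95 redundancy threshold.
- **Simulation.** A seeded generator of correlated prediction banks with
  independent dials for per-classifier accuracy and inter-classifier
  correlation, plus packaged count-table fixtures from a published 16-CNN
  liver-ultrasound study (classes BLT/LCY/MLC/PLC) used as ground truth for
  the metric suite.

## Worked example

Metrics from the packaged 16-classifier count table:

```python
>>> import fusemble as fm
>>> rep = fm.fixture_report("counts16", "ResNeXt101", ci="wilson")
>>> print(rep.summary())
   class  precision  sensitivity  specificity     f1  class_accuracy  auc
0    BLT      0.745        0.688        0.921  0.715           0.863  NaN
1    LCY      0.991        0.904        0.997  0.946           0.974  NaN
2    MLC      0.567        0.664        0.831  0.611           0.789  NaN
3    PLC      0.625        0.620        0.876  0.622           0.812  NaN
4  macro      0.732        0.719        0.906  0.724           0.719  NaN
```

Each row is one class treated one-vs-rest (the `macro` row's
`class_accuracy` column holds the overall accuracy Σtp/N = 0.719: 719 of the
1000 test items correct).  Fit a weighted-average-voting ensemble on a
synthetic 16-member bank:

```python
>>> ps = fm.generate(fm.GeneratorConfig(seed=7))
>>> res = fm.FusionModel(ps, "wav").fit(seed=7, budget=50)
>>> print(res.summary())
Fusion method: WAV  (k=16 members, N=1000)
Members: m01, m02, m03, m04, m05, m06, m07, m08, m09, m10, m11, m12, m13, m14, m15, m16
Overall accuracy: 0.852
Macro precision/sensitivity/specificity/F1: 0.852 / 0.852 / 0.951 / 0.852
Weights: m01=0.097, m02=0.041, m03=0.083, m04=0.076, m05=0.096, m06=0.098, m07=0.020, m08=0.064, m09=0.035, m10=0.043, m11=0.070, m12=0.051, m13=0.083, m14=0.035, m15=0.091, m16=0.017
```

The fused ensemble reaches 0.852 accuracy while its best single member sits
at 0.719 — fusing many moderately correlated classifiers recovers much of the
idiosyncratic error.  `fm.sweep(ps, ...)` runs the full prune-and-fuse grid
and reports the best ensemble size per method.

The same operations are available from the shell:

```bash
fusemble simulate --n 1000 --members 16 --seed 7 --out sim/
fusemble fuse  --pred sim/predictions.csv --truth sim/truth.csv --method wav --seed 7
fusemble sweep --pred sim/predictions.csv --truth sim/truth.csv \
               --methods sv,wav,whv,stack --meta-learner logistic \
               --seed 7 --out grid.csv
fusemble diversity --pred sim/predictions.csv --truth sim/truth.csv --out corr.csv
```

## Layout

- `src/fusemble/data.py` — prediction-set container, validation, text I/O,
  confusion matrices and one-vs-rest counts
- `src/fusemble/metrics.py` — per-class and macro metrics, Wilson/Wald CIs,
  one-vs-rest ROC AUC
- `src/fusemble/fusion.py` — SV/WAV/WHV/stacking, weight optimization, the
  `FusionModel`/`FusionResults` front door
- `src/fusemble/pruning.py` — accuracy ranking and the top-k sweep
- `src/fusemble/stats.py` — McNemar test, diversity diagnostics
- `src/fusemble/synthetic.py` — the generator and packaged fixtures
- `docs/methods.md` — the model, its assumptions, parameter choices and
  known limitations
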