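# dosim — few-time-point renal dosimetry with mixed-effects kinetics

Internal dosimetry for 177Lu radiopharmaceutical therapy (e.g.
[177Lu]Lu-PSMA-617 in metastatic prostate cancer) needs each organ's
**time-integrated activity** (TIA): the integral of the activity–time
curve from injection to infinity.  Measuring that curve well takes about
five SPECT/CT sessions spread over a week — a heavy burden for patients
and clinics.  `dosim` is a library + pipeline for asking, quantitatively:
*how much accuracy and precision do you lose when you image at fewer time
points, and which time points should you keep?*

It is aimed at medical physicists and pharmacometricians.  The package
implements, from the likelihood up:

* the six-parameter sum-of-exponentials kidney model

  `f(t) = A1 e^{-(λ1+λph)t} + A2 e^{-(λ2+λph)t} − A3 e^{-(λ3+λph)t} − (A1+A2−A3) e^{-(λbc+λph)t}`

  with analytic TIA `Σ ±Ai/(λi+λph)` and delta-method TIA uncertainty
  (λph: 177Lu decay, half-life 6.6443 d; λbc: blood-circulation uptake,
  half-life 1 min; both fixed);
* nonlinear mixed-effects estimation: log-normal inter-individual
  variability (`p = θ e^η`, `η ~ N(0, diag Ω)`), proportional residual
  error, Laplacian conditional approximation of each subject's marginal
  likelihood, and seeded multi-start optimisation of the 13 population
  parameters (6 fixed effects + 6 IIV variances + 1 residual SD);
* empirical-Bayes individual estimation from any subset of a subject's
  imaging sessions — well-posed even from a single scan thanks to the
  population prior;
* the evaluation protocol: all-session reference TIAs (rTIA),
  leave-one-out few-time-point estimates (eTIA) for all 30 subsets of the
  five sessions, no-imaging mean/median surrogates, and accuracy
  (RD/RMSE/MAPE with propagated SDs, RD>10%/20% counts, eTIA–rTIA
  regression) plus precision (CV) summaries;
* a virtual-patient generator reproducing the clinical sampling schedule
  and noise structure, with ground truth for recovery checks.

See `docs/methods.md` for the model, estimation details and limitations.

## Worked example

The `analysis/` scripts run the whole study on simulated cohorts and
write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py    # 63- and 20-subject cohorts
python analysis/02_fit_reference.py      # all-session population fit
python analysis/03_jackknife_ftp.py      # 30 subsets, leave-one-out
python analysis/04_accuracy_report.py    # accuracy/precision tables
```

`02_fit_reference.py` fits the 63-subject cohort (315 observations) and
prints:

```
OFV -2924.26, converged=True
theta_hat: [0.02049 0.01006 0.00958 0.00498 0.04622 2.68448]
sigma_hat: 0.1016
rTIA vs truth: rank correlation 0.948
rTIA CV: mean 5.4%, max 7.0%
```

The generating values were `θ = (0.02, 0.01, 0.025, 0.005, 0.05, 2.0)`
and `σ = 0.10`: the identifiable components (A1, A2, λ1, λ2) and the
residual SD come back within a few percent, while A3/λ3 — the fast
secretion phase, already over before the first scan at ~2 h — are only
weakly constrained, as expected.  Reference TIAs rank-track the true TIAs
(ρ = 0.948) with ~5% precision.

`03_jackknife_ftp.py` then evaluates every reduced schedule on the
20-subject cohort (one training fit per left-out subject, cached across
subsets):

```
best 1-session subset: TP5 — RMSE 11.2%, MAPE 9.4%
best 2-session subset: TP25 — RMSE 4.8%, MAPE 3.5%
best 3-session subset: TP345 — RMSE 2.5%, MAPE 2.1%
best 4-session subset: TP1345 — RMSE 1.9%, MAPE 1.5%
```

with the all-session jackknife at RMSE 1.3% and the no-imaging
surrogates at 26–29%: each added session buys accuracy, a single
well-placed late scan already recovers individual kinetics to ~11%, and
ignoring individual kinetics altogether is an order of magnitude worse.
The same monotone trend holds for precision (mean CV ~11.5% for the best
single session down to ~5.2% for all sessions).

The same pipeline runs from the shell, on simulated or real cohort CSVs
(`subject_id, time_h, activity_fraction[, sd, tp_label]`):

```bash
dosim simulate -o cohort.csv --seed 42
dosim fit-atp cohort.csv -o ref.csv
dosim fit-ftp cohort.csv --subsets TP3,TP25 -o ftp.csv
dosim evaluate ref.csv ftp.csv -o report.csv
dosim all -o results/        # the full protocol in one command
```

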