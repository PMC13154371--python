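# ema-rt — EMA response-time dynamics as a marker of depressive-symptom change

Older adults at risk of depression can answer four brief daily mood items
("feeling", "appetite", "sleep_quality", "general_evaluation") on a phone
for a month.  Beyond *what* they answer, the latency of each answer is a
free behavioural signal.  This package implements a complete analysis of
those response times (RTs) as a proxy for symptom change: people who
benefit from EMA-adjunctive care appear to *habituate* to repeated
self-report much faster — their RT decay rate is several-fold higher —
than people who do not.

It is aimed at researchers in digital phenotyping / intensive
longitudinal data who want a tested, reproducible reference
implementation of this analysis, exercised end-to-end on a synthetic
cohort generator with known ground truth (raw cohorts of this kind are
not publicly deposited).

## The model at the core

Each trial's RT follows a log-normal distribution whose location decays
exponentially over normalized time t ∈ [0, 1]:

    RT_n ~ LogNormal(η_n, σ_log)
    η_n  = θa(i)·exp(−θb(i)·t_n) + θc(i, r_n)

    log θa(i) = β0a + β1a·g(i) + σa·z_a(i)        (amplitude)
    log θb(i) = β0b + β1b·g(i) + σb·z_b(i)        (decay rate)
    θc(i,r)   = β0c + β1c·g(i) + u_c(i) + α_c(r) + ε_c(i,r)   (asymptote)

where g(i) ∈ {0,1} marks responders — subjects whose GDS-15 change meets
the minimal-detectable-change criterion Δ ≤ −3.81 — and α_c(r) are
response-option offsets constrained to sum to zero.  Group effects are
reported as responder/nonresponder ratios exp(β1) with 95% credible
intervals and P(ratio > 1).  Around the model sit the supporting stages:
asymmetric-IQR RT cleaning, within-person × option standardization
(Z-RT), per-subject nonlinear-least-squares decay features, paired
pre/post tests with a Shapiro–Wilk gate, and a Spearman screen of
features against change scores.  Inference uses the package's own NUTS
sampler with analytic gradients; PSIS-LOO (via ArviZ) selects the
random-effects structure.  See `docs/methods.md` for the full account.

## Worked example

Run the numbered analysis scripts in order (all accept `--seed` and
`--outdir`; defaults write under `results/pipeline/`):

```bash
python analysis/01_simulate.py      # synthetic cohort + scale batteries
python analysis/02_preprocess.py    # IQR cleaning + Z-RT
python analysis/03_features.py      # descriptives + decay fits
python analysis/04_outcomes.py      # change scores, responders, paired tests
python analysis/05_associate.py     # Spearman screen
python analysis/06_model.py         # hierarchical model (adds --sensitivity)
```

With the default seed the run prints, among other things:

```
simulated 5164 records, 49 subjects
removed 373/5164 trials (7.2%) as RT outliers; 158 cells too small and 0
zero-SD cells dropped from Z-RT

15/49 subjects classified as responders (GDS-15 change <= -3.81)
gds15: wilcoxon statistic=781.50 p(one-tailed)=2.4e-06 rank_biserial=0.82
cesdr: t statistic=-4.22 p(one-tailed)=5.3e-05 cohen_d=0.60

feeling Z-RT decay rate vs d_gds15: rho=-0.297
(negative rho = faster adaptation, larger improvement)

PSIS-LOO variant comparison (moderation omitted):
variant     elpd_loo        se      p_loo  frac_pareto_k_le_0_7
b_and_c -1887.470653 31.938809 127.571282              0.999174
   none -2274.011660 25.343242   9.571582              1.000000

responder/nonresponder ratio summaries (ratio 1 = no group difference):
   item   parameter  ratio_median  cri_low  cri_high  p_increase
feeling     theta_b      4.468143 1.733829 11.263479     0.99925
feeling exp_theta_c      1.417414 1.144837  1.849448     1.00000
feeling     theta_a      0.853317 0.600747  1.148160     0.15850

diagnostics: max R-hat 1.015, min ESS 300, divergences 0.0%, PPC bin
coverage 100%
```

Reading this: the cleaning stage removed ~7% of trials as latency
outliers (2% were injected; the asymmetric rule also clips honest
right-tail mass of the log-normal).  Faster Z-RT adaptation on the
feeling item goes with larger GDS-15 improvement (negative Spearman ρ).
PSIS-LOO prefers subject-level random effects on the decay rate and
asymptote over a fully pooled model by ~387 ELPD units, and the
moderated fit estimates responders adapting ~4.5× faster (true
generative ratio: 5; the 95% CrI covers it and excludes 1), an
asymptote RT ratio ~1.4 (true: 1.25) and no amplitude difference (true
ratio: 1) — the contrast the analysis is designed to detect: a sharp,
certain decay-rate separation alongside a modest asymptote difference.

The same stages are scriptable through one CLI (`ema-rt all --seed 1
--outdir results/run`) or the `ema_rt.pipeline` API, which adds a run
manifest with per-stage seeds and artifact paths.

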