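# Methods

`sepsopt` couples two pieces of machinery: an observational estimator of the
payer cost attributable to a secondary severe-sepsis/septic-shock diagnosis,
and a decision-theoretic optimizer that converts those costs into alert
sensitivity thresholds per Major Diagnostic Category (MDC). This note
records the models, the defaults and why they were chosen, and what the
synthetic data can and cannot demonstrate.

## Excess-cost estimation by matched controls

Under the Medicare prospective payment system, encounters in the same DRG
with the same DRG weight are reimbursed from the same base rate; payment
differences inside a (DRG code, DRG weight) stratum come from outlier
payments for unusually costly stays. The excess cost of a secondary sepsis
diagnosis is therefore estimated pairwise: each sepsis-flagged encounter is
compared with the control in its stratum whose Charlson comorbidity index is
closest, and the excess is the payment difference (possibly negative).
Encounters in the sepsis-specific DRGs 870–872 are excluded by construction —
the target is the *excess* cost of sepsis on top of another primary
diagnosis, not the cost of sepsis admissions.

Matching choices, all deterministic:

- **With replacement.** Each sepsis case searches the full control pool of
  its stratum, so matches are independent across sepsis cases and invariant
  to row order.
- **Tie-break.** Ties in |ΔCharlson| resolve to the lexicographically
  smallest control encounter id. Identifiers are assigned independently of
  payments, so this rule is outcome-blind: among tied controls it selects one
  whose payment is an unbiased draw. Any payment-based tie-break (cheapest
  control, or payment closest to the case's) selects on the outcome and
  biases the estimator — with ~10 tied controls per stratum and a log-normal
  payment spread the bias reaches tens of percent of the true excess.
- **Unmatched cases.** A sepsis row whose stratum has no control is logged
  and excluded, never fatal.
- **Aggregation.** DRG-level mean excesses are averaged into MDC-level
  `cost_fn` values. The default is the unweighted mean of DRG means
  (`mdc_weighting="drg_mean"`); `"pair_weighted"` averages over pairs
  instead. The unweighted mean treats each DRG as one draw from the MDC's
  cost distribution; the pair-weighted mean tilts toward high-incidence DRGs.

Site-level tables scale to the national population by multiplying costs by a
national-to-site payment ratio (per DRG, averaged unweighted to the MDC, or
directly per MDC) and dividing counts by the site's share of national
Medicare patients. Ratios and share are user inputs; the package ships no
national payment file.

No causal claim is made: nearest-comorbidity matching within DRG adjusts for
the primary diagnosis and baseline severity but cannot rule out residual
confounding.

## ROC model

The alert system is abstracted by its ROC curve. The default family is the
equal-variance binormal ROC: septic and non-septic risk scores are
unit-variance Gaussians separated by `d`, giving

    AUC  = Φ(d/√2)        ⇔   d = √2 · Φ⁻¹(AUC)
    f(s) = Φ(Φ⁻¹(s) − d)

where `f` maps a chosen sensitivity `s` to the false-positive rate. This
family has exactly one free parameter, so it is fully identified by the AUC —
the only performance statistic assumed available for the predictive model.
`f` is shared across MDCs by default; an empirical (sens, fpr) CSV can be
substituted (validated monotone, spanning (0,0)–(1,1), interpolated
piecewise-linearly). Constructor round-trip is verified by quadrature:
`∫₀¹ TPR(u) du` recovers the input AUC to 1e−6.

The diagnostic odds ratio is `[s/(1−s)]/[f/(1−f)]`; pooled across MDCs it is
computed from summed confusion counts `TP = Σ sᵢ·N_septic_i` etc. Boundary
operating points make the DOR undefined; the functions return NaN with a
`RuntimeWarning` rather than ±inf or an exception, so sweeps degrade
gracefully.

## Cost objective and optimizer

Per MDC `i` with missed-case cost `Cost_FN_i`, septic count `N_septic_i` and
control count `N_controls_i`, operating the alert at sensitivity `sens_i`
costs

    FN_i = Cost_FN_i · N_septic_i · (1 − γ·sens_i)
    FP_i = (Cost_FN_i / α) · N_controls_i · γ · f(sens_i)

- **α** (default sweeps 17–27): one false alarm costs `Cost_FN_i/α`. Higher
  α means cheaper overtreatment. α=20 is the headline value, matching the
  maximum false-alarm penalty of the PhysioNet sepsis challenge scoring.
- **γ** ∈ (0,1] (sweeps 0.5–1.0): physician adherence. An ignored alarm
  yields no treatment, so the effective detection rate is `γ·sens_i`; by the
  same logic an ignored alarm causes no overtreatment, so γ scales the FP
  term too (`gamma_scales_fp=True`, the default). Under this convention γ
  multiplies the whole net benefit: optimal thresholds are γ-invariant and
  savings scale linearly in γ. Setting `gamma_scales_fp=False` keeps the
  full FP cost regardless of adherence; optima then shift downward with γ.
  Both conventions are tested.
- Costs of the early treatment itself (broad-spectrum antibiotics) are taken
  as negligible; the modeled FP cost is the downstream cost of overtreatment
  expressed through α.

The objective is a sum of per-MDC terms, so each `sens_i` minimizes its own
term. The optimizer is a deterministic grid search over
`{0, step, …, 1}` (default step 0.001), ties to the lower sensitivity
(fewer alarms at equal cost). Grid search was chosen over continuous
optimization because the problem is one-dimensional per category, exactly
reproducible, and directly checkable against exhaustive enumeration — which
the test suite does, jointly (without assuming separability) on random 2–3
category tables.

Three deployment regimes: `fixed_080` evaluates a uniform 80% sensitivity (a
common clinical target) without optimizing; `uniform_optimized` picks one
shared threshold; `heterogeneous` picks one per MDC. Savings are measured
against the no-model baseline `Σᵢ Cost_FN_i·N_septic_i` (every sepsis case
incurs its excess, no alarms). Constraint-set nesting guarantees
savings(heterogeneous) ≥ savings(uniform) ≥ savings(fixed, up to the grid
resolution at 0.8), and savings are non-decreasing in α, γ and AUC — the
sweep tests assert these at every grid point, not on samples.

Negative `cost_fn` categories are handled by the same formula: where sepsis
is *cheaper* than matched controls, detection has no value and the optimum
sits at sensitivity 0 (or, when the category's false-"alarm" term dominates,
at 1 — the grid handles both). One consequence worth knowing: the pooled
DOR of the heterogeneous optimum can fall below the uniform optimum's,
because a sens=0 category contributes all its cases as misses to the pooled
2×2 table. Cost, not DOR, is the objective; DOR is reported, and it is
non-decreasing in AUC at the optimum.

## Synthetic-data generator

The generator emulates the study conditions end to end so each stage has a
recoverable ground truth: 131 non-sepsis DRGs partitioned round-robin over
16 MDC labels, 149 controls per DRG (19,519 total), an MDC-dependent sepsis
incidence of 1–10 flagged encounters per DRG (673 total), Charlson indices
0–15, DRG weights uniform on 0.7–5.5.

    payment = (6000·weight + 800·charlson) · L + excess(mdc)·sepsis_flag

with `L` a unit-mean log-normal factor, log-scale `outlier_tail` (default
0.5, i.e. ~50% payment coefficient of variation — the right-skewed outlier
payments of real claims; 0 disables noise). Injected per-MDC excesses span
−$3,000 (infectious-disease, mirroring the observed left tail where
sepsis-flagged stays can be cheaper) to $85,000 (pre-MDC transplant/ECMO
stays), mean ≈ $24,000. Incidence varies by MDC because that variation —
some departments see ten times the sepsis rate of others — is what makes
category-specific thresholds worth choosing; with uniform incidence the
per-MDC optima nearly coincide and the regimes collapse.

Sepsis cases draw their Charlson index by resampling the control indices
already present in their stratum, so an exact-comorbidity match always
exists: with zero noise the matching estimator recovers every injected
excess exactly (to float rounding), and with noise it is unbiased — verified
over 100 seeded replicates per MDC (one-sample t-tests, familywise 1% level).

What the generator does **not** emulate: empirical payment distributions
beyond a right-skewed two-moment stand-in, correlation between comorbidity
and sepsis risk, time trends in DRG weights, readmissions and
skilled-nursing costs, and real MDC composition. Passing tests therefore
demonstrate correctness of the estimator and optimizer under known ground
truth — not fidelity of any particular dollar figure to real claims.

## Numerical choices and degenerate inputs

- Grid step 0.001 (1001 points) for production runs; unit tests use 0.01
  where they compare against exhaustive enumeration.
- AUC quadrature via adaptive Gauss–Kronrod (`scipy.integrate.quad`,
  epsabs 1e−10); the binormal endpoints are removable and cause no trouble.
- `auc=1` is admitted as the perfect-classifier limit (`f(s)=0` for `s<1`);
  `auc≤0.5` is a domain error — a no-skill or inverted model has no
  meaningful threshold trade-off.
- Zero-count MDCs contribute nothing to either cost term; a zero-cost MDC
  optimizes to sensitivity 0 by the tie-break.
- Scaled national counts are kept as floats (counts divided by a site share
  are expectations, not integers).
- All pipeline randomness flows from one integer seed through one
  `numpy.random.default_rng` stream; everything downstream of the generator
  is deterministic, and two runs of the same config are byte-identical.

## Problem sizes

Default analyses run the full synthetic cohort (~20,200 encounters, 673
sepsis cases). The repeated-seed bias study uses a reduced cohort (32 DRGs,
4 septic / 40 controls per DRG, 100 seeds) — ample for a standard error of a
few hundred dollars per MDC on injected excesses of thousands to tens of
thousands. The default sweep grid is 11 α × 6 γ × 3 AUC × 3 regimes = 594
optimizations; a full sweep takes a few seconds.
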