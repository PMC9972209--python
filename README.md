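# sepsopt

Excess sepsis costs from claims data, and cost-minimizing alert-threshold
policies across hospital diagnostic categories.

Machine-learning sepsis alerts are usually deployed with one classification
threshold for the whole hospital. But both the cost of a missed sepsis case
and the rate of sepsis vary enormously across Major Diagnostic Categories
(MDCs) — the 16-odd broad diagnosis areas that partition DRG-coded inpatient
stays and roughly correspond to departments. `sepsopt` is a pipeline for
payers and implementers who want thresholds that reflect those differences:

1. **Excess-cost estimation.** From claims-style data (one row per
   encounter: DRG code and weight, MDC, Charlson comorbidity index, payment,
   secondary-sepsis flag), each sepsis-flagged encounter is matched — with
   replacement, within its (DRG code, DRG weight) stratum — to the control
   with the nearest Charlson index. The payment difference is that case's
   excess cost `Cost_FN`; DRG-level means are averaged per MDC. Site-level
   estimates can be scaled to the national Medicare population.
2. **Threshold optimization.** Given per-MDC costs and counts, an
   AUC-constrained ROC model, a false-alarm cost ratio α (one false alarm
   costs `Cost_FN/α`) and a physician adherence rate γ, choose sensitivities
   `sens_i` to minimize

   ```
   Σ_i  Cost_FN_i · N_septic_i · (1 − γ·sens_i)                 (missed cases)
      + (Cost_FN_i / α) · N_controls_i · γ · f(sens_i)          (false alarms)
   ```

   where `f(s) = Φ(Φ⁻¹(s) − √2·Φ⁻¹(AUC))` maps sensitivity to false-alarm
   rate on the equal-variance binormal ROC curve. Three regimes are
   compared: a fixed 80% sensitivity everywhere, one cost-optimized uniform
   threshold, and per-MDC heterogeneous thresholds.
3. **Simulation sweeps.** Savings (vs. the no-model baseline
   `Σ Cost_FN_i·N_septic_i`) and pooled diagnostic odds ratios over
   α ∈ 17–27, γ ∈ 0.5–1.0, AUC ∈ {0.82, 0.87, 0.9}, per regime.

A seeded synthetic-claims generator with known injected excess costs makes
the whole pipeline testable without access to protected claims data.

## Worked example

```python
from sepsopt import (GeneratorConfig, generate_claims, match_controls,
                     aggregate_mdc, make_roc, optimize_heterogeneous,
                     optimize_uniform, evaluate_fixed)

claims = generate_claims(GeneratorConfig(seed=42))      # synthetic cohort
pairs  = match_controls(claims).pairs                   # matched comparisons
table  = aggregate_mdc(pairs, claims)                   # per-MDC Cost_FN, counts
roc    = make_roc(0.9)

fix = evaluate_fixed(table, roc, alpha=20, gamma=1.0)
uni = optimize_uniform(table, roc, alpha=20, gamma=1.0)
het = optimize_heterogeneous(table, roc, alpha=20, gamma=1.0)

print(f"encounters: {len(claims):,}  matched pairs: {len(pairs):,}")
print(f"baseline excess cost: ${het.baseline_cost:,.0f}")
for r in (fix, uni, het):
    print(f"{r.regime:18s} savings ${r.savings:,.0f}   pooled DOR {r.pooled_dor:5.1f}")
```

prints

```
encounters: 20,192  matched pairs: 673
baseline excess cost: $16,060,485
fixed_080          savings $8,974,011   pooled DOR  20.1
uniform_optimized  savings $9,067,456   pooled DOR  20.4
heterogeneous      savings $9,526,640   pooled DOR  10.6
```

Reading: with no alert model, the 673 secondary-sepsis cases in this
synthetic cohort cost the payer $16.1M beyond their matched controls. An
AUC-0.9 alert at the standard 80% sensitivity recovers $9.0M of that;
letting the optimizer choose one hospital-wide threshold adds ~$93k; letting
it choose per-category thresholds adds another ~$459k (e.g. 0.857 in
high-incidence respiratory DRGs but 0.42 in mental-health DRGs, and 0 in the
infectious-disease category, where sepsis-flagged stays are on average
*cheaper* than controls — which is also why the heterogeneous pooled DOR
drops: those cases count as misses in the pooled table while costing
nothing). Savings rise with α (cheaper false alarms), γ (better adherence)
and AUC.

The same pipeline runs from the shell:

```bash
sepsopt generate --seed 42 --out claims.csv
sepsopt excess-cost --claims claims.csv --out costs.csv
sepsopt optimize --costs costs.csv --alpha 20 --gamma 1.0 --auc 0.9 --out opt.json
sepsopt sweep --costs costs.csv --outdir report/        # CSV + JSON + heat maps
sepsopt run --config pipeline.yaml --outdir out/        # all stages, provenance.json
```

To run the optimizer on published per-MDC aggregates instead of
patient-level data, write them as a CSV `mdc,cost_fn,n_septic,n_controls`
and pass it via `--costs` (or the `costs:` key of the pipeline config).

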