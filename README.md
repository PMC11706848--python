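# trimeth

Quantification and prognosis pipeline for methylation-based ctDNA
monitoring of resectable gastric and gastroesophageal-junction cancer.

Circulating tumor DNA (ctDNA) in plasma can be detected tumor-agnostically
by methylation-specific droplet digital PCR over the gastrointestinal
cancer markers *C9orf50*, *KCNQ5* and *CLIP4* (the TriMeth test).  This
package implements the full analysis chain a perioperative ctDNA study
needs, for lab analysts and biostatisticians working with droplet-level
ddPCR exports and serial plasma collections:

1. **ddPCR quantification** — per-plate amplitude thresholds derived from
   positive/negative control wells, Poisson occupancy correction
   λ = −ln(1 − k/n), and scaling to methylated copies per mL plasma from
   the sample's extraction geometry;
2. **sample QC** — CPP1 spike-in purification efficiency, PBC
   (leucocyte contamination) screening, CF-assay bisulfite recovery, and
   the exclusion gate (contamination, <10,000 droplets, no CF signal);
3. **TriMeth calling** — a marker is positive with >1 positive droplet; a
   sample is ctDNA positive with ≥2 of 3 positive markers; detection
   rates per timepoint and status-transition (dynamics) groups;
4. **survival analytics** — recurrence-free and overall survival
   endpoints, Kaplan–Meier curves with Greenwood intervals and 24-month
   landmarks, log-rank tests, univariable → multivariable Cox models with
   a p < 0.05 entry screen, ROC analysis of marker concentrations;
5. **study design** — Schoenfeld's event formula
   d = (z₁₋α/₂ + z_pow)² / (p(1−p)(ln HR)²) converted to a patient count
   via exponential event probabilities, plus a Monte-Carlo power check;
6. **synthetic data** — a seeded generator of droplet plates (two-cluster
   amplitudes with rain, ~21,000 droplets/well) and clinical cohorts
   (copula-correlated serial ctDNA statuses, status-dependent recurrence
   hazards) so every stage is testable without patient data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a 12-patient study and push it through the whole pipeline:

```bash
trimeth simulate study --seed 11 --n-patients 12 --out sim
trimeth run --droplets sim/droplets.csv --sample-sheet sim/sample_sheet.csv \
            --clinical sim/clinical.csv --out results
```

prints

```
samples collected: 30; QC-passed: 27; excluded: 3
evaluable samples: 27; positive: 9
baseline: ctDNA detected in 50% (5 of 10)
after_1_cycle: ctDNA detected in 33% (3 of 9)
after_preop_ct: ctDNA detected in 33% (1 of 3)
post_surgery: ctDNA detected in 0% (0 of 5)
```

Thirty plasma samples were simulated; three failed QC (one low-droplet
well, contamination or missing CF signal each — see
`results/qc_report.csv` for the reasons) and are *not evaluable* rather
than negative.  The remaining 27 were scored with the 2-of-3 rule; the
per-timepoint lines give positives / evaluable patients.  `results/`
also contains the per-well measurements, per-sample calls,
RFS/OS endpoints, Kaplan–Meier tables, a hazard-ratio table
(`hazard_ratios.csv`: log-rank χ², Cox HR with 95% CI, 24-month landmark
survival per ctDNA group), dynamics groups and ROC AUCs, plus
`run_metadata.json` with droplet counts, thresholds and exclusions.

The design calculator reproduces a two-arm log-rank design from its
assumptions (here: two-sided α = 0.05, power 0.80, HR 5.4, 15%
postoperative positivity, 30-month median RFS, 18-month follow-up):

```bash
$ trimeth design n
{
  "events": 22,
  "event_probability": 0.42333266331472247,
  "n": 52
}
```

— 22 required events at an overall event probability of 0.423 give a
cohort of 52 patients with complete postoperative samples.

Library use mirrors the CLI: `trimeth.quantify_stage`, `qc_stage`,
`call_stage`, `survival_stage` operate on DataFrames, and
`trimeth.design` / `trimeth.simulate` expose the calculators and
generators directly.

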