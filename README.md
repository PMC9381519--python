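# slaml

Stage-of-leukemia-arrest (SLA) immunophenotyping toolkit for AML:
rule-based classification of specimens into six differentiation-arrest
stages (HSC-L, MPP-L, CMP-L, GMP-L, GP-L, MP-L) from flow-cytometry marker
profiles, plus the downstream analyses that hang off that label —
genotype association screens, secondary-AML labelling, and per-stage
survival/competing-risks statistics. A synthetic-cohort simulator makes
the whole pipeline testable without any patient data.

## What's inside

| module | purpose |
|---|---|
| `slaml.synthetic` | event-level specimen and full-cohort simulation (archetypes, published prevalence defaults, exponential competing-risks outcomes) |
| `slaml.gating` | CD45-dim blast gate, percent-positive per marker, CD34+CD38−CD123+ LSC fraction; CSV event files (FCS via the optional `fcsparser` extra) |
| `slaml.classifier` | the six-stage decision tree (CD34 / CD13 / CD33 / MPO tiers / HLA-DR), atypical flagging, cohort frequency tables, PCA projection |
| `slaml.genotype` | one-vs-rest 2×2 relative risks, Fisher exact tests, secondary-AML labels, functional mutation modules |
| `slaml.outcomes` | Kaplan–Meier with Greenwood variance, k-group log-rank, Aalen–Johansen cumulative incidence, permutation-calibrated Gray-type CIF comparison |
| `slaml.pipeline` / `slaml.cli` | end-to-end orchestration, manifests, the `sla` command |

## CLI

```bash
# simulate a cohort and write profiles/genotypes/outcomes CSVs
sla simulate --n-patients 2087 --seed 1 --out cohort/

# classify marker profiles (CSV: patient_id + percent-positive columns)
sla classify --profiles cohort/profiles.csv --out labels.csv

# one-vs-rest association screen (volcano table)
sla assoc --labels labels.csv --genotypes cohort/genotypes.csv --out volcano.csv

# secondary-AML labels
sla saml --clinical clinical.csv --genotypes cohort/genotypes.csv --out saml.csv

# survival/CIR step tables
sla survival --outcomes cohort/outcomes.csv --labels labels.csv --out surv/

# full pipeline from a YAML config
sla run --config run.yaml --out out/
```

A `run.yaml` names either `inputs:` (paths to `profiles`, and optionally
`genotypes`, `outcomes`, `clinical` CSVs) or a `simulate:` block (fields of
`slaml.synthetic.CohortConfig`), plus `classifier:` thresholds and
`analyses:` toggles (`pca`, `association`, `survival`, `saml`):

```yaml
seed: 1
simulate:
  n_patients: 2087
  jitter: 0.0
analyses:
  association: true
  survival: true
```

## Classification rules

Positivity is percent-of-blasts ≥ 20% (configurable). CD34+ specimens
split on cytoplasmic MPO: < 10% → MPP-L (or HSC-L when CD13 and CD33 are
both negative), 10–70% → CMP-L, > 70% → GMP-L. CD34− specimens split on
HLA-DR: ≥ 20% → MP-L, < 20% → GP-L. Boundary ties resolve toward CMP-L;
violations of secondary expectations (CD117− in a committed CD34+ stage,
MPO expression without CD13/CD33) set an `atypical` flag without changing
the label.

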