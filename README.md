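# diabsub

Clinical-variable subtyping of recent-onset type 2 diabetes, built as a
tested, reusable pipeline: de novo k-means subgrouping on five routine
clinical classifiers, polygenic-score and lipidomic characterisation of the
subgroups, and cardio-renal outcome analysis — exercised end-to-end on
synthetic cohorts whose statistical structure is calibrated to published
per-subgroup baseline summaries from a South East Asian study population.

## Who this is for

Diabetes epidemiologists and biostatisticians who want to run (or stress-test)
the clinical-variable subtyping workflow without access to patient-level data:
every stage consumes plain delimited-text tables, and a calibrated synthetic
generator stands in for the cohort so the whole analysis is reproducible from
a seed.

## The method

**Subtyping.** Participants with recent-onset type 2 diabetes are clustered on
five classifiers — age at diabetes onset, BMI, HbA1c, HOMA2-B and HOMA2-IR
(the HOMA indices log-transformed) — each standardised to mean 0, SD 1.
k-means (Lloyd iterations, k-means++ seeding, best of ≥25 restarts by
within-cluster sum of squares) partitions the cohort; the number of clusters
is chosen by majority voting over twelve internal validity indices
(Calinski–Harabasz, silhouette, Davies–Bouldin, Dunn, C-index, Ball–Hall,
Hartigan, Krzanowski–Lai, McClain–Rao, point-biserial, Ratkowsky–Lance,
Xie–Beni); stability is quantified by the bootstrap Jaccard index
(resample rows, refit, match clusters by maximal |A∩C|/|A∪C|). The k=3
clusters map to phenotypes from their centroid profile: **SIRD-RII** (severe
insulin-resistant with relative insulin insufficiency — highest HbA1c),
**MARD-II** (mild age-related with insulin insufficiency — older onset, low
HOMA2-B), and **MOD** (mild obesity-related — high BMI, preserved HOMA2-B).

**Characterisation.** Polygenic risk scores are weighted risk-allele dosage
sums, `PRS_i = Σ_v w_v d_iv`, compared across subgroups by OLS with sex and
genotype principal components as covariates (MOD reference). The lipidomic
screen is two-stage: species with signal-to-noise < 3 are dropped, batch
effects removed by per-batch log-median centring, each of the 315 remaining
species tested by Kruskal–Wallis across subgroups at the Bonferroni threshold
0.05/315 = 1.59×10⁻⁴, and discovery hits re-tested in an independent
validation cohort at nominal p < 0.05 (the validation cohort is assigned to
subgroups by minimal Euclidean distance to the discovery centroids over BMI,
onset age, HbA1c and the triacylglycerol/HDL ratio).

**Outcomes.** Progressive chronic kidney disease is derived from longitudinal
eGFR series as a confirmed decline of ≥40% from baseline (repeat measurement
≥3 months later). Crude incidence is reported per 1000 person-years with
exact Poisson (Garwood) intervals; cumulative risk uses Kaplan–Meier and the
logrank test; adjusted subgroup hazard ratios come from Cox proportional
hazards regression (Efron ties) with Schoenfeld-residual diagnostics.

## Worked example

```python
from diabsub.synth import simulate_table1_cohort
from diabsub import SubtypeModel

cohort = simulate_table1_cohort(seed=1)          # 687 participants
res = SubtypeModel(cohort).fit(k=3, stability_bootstraps=200, seed=1)
print(res.summary())
```

```
Subtype model fit
============================================================
n = 687, k = 3, classifiers = ['onset_age', 'bmi', 'hba1c', 'homa2b', 'homa2ir']
total within-cluster SS = 2054.99

cluster sizes:
     MARD-II:   285  (41.5%)
         MOD:   280  (40.8%)
    SIRD-RII:   122  (17.8%)

centroids (original scale):
          onset_age    bmi  hba1c  homa2b  homa2ir
MARD-II       56.45  24.91   7.13   54.47     1.35
MOD           50.01  30.34   6.90  103.65     2.40
SIRD-RII      38.18  31.91   9.36   40.37     2.66
```

The centroids read directly as the three phenotypes: SIRD-RII combines the
worst glycaemia (HbA1c 9.4%), the highest insulin resistance (HOMA2-IR 2.7)
and low beta-cell function; MOD is obese (BMI 30) with preserved HOMA2-B
(~104%); MARD-II is older at onset, lean, and insulin-insufficient (HOMA2-B
~54%). The bootstrap Jaccard means (0.94 per cluster here) indicate a stable
partition. `res.labels` attaches a phenotype to every row, and
`res.assigned_cohort()` returns the cohort with assignments appended.

The full pipeline — cohort, clustering with optimal-k voting, PRS
association, discovery–validation lipid screen, and Cox models for the four
cardio-renal outcomes — runs from one config:

```bash
diabsub all --seed 17 --out results/
# or: diabsub simulate / diabsub cluster for individual stages
```

## Documentation

`docs/methods.md` describes the generative model behind the synthetic
cohorts, the numerical conventions of each stage (standardisation, index
decision rules, tie handling, censoring), and the known limitations of
testing against synthetic data.
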