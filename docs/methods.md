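# Methods

This note documents the models and procedures implemented in `stshypoxia`,
the parameter defaults and why they were chosen, the numerical decisions
made where the design was genuinely open, and the limits of what the
synthetic experiments demonstrate.

## 1. Classification model

The hypoxia call is a nearest-centroid rule on the 24 signature genes.
Centroids are per-class, per-gene means of log2 expression (an unshrunken
PAM centroid); prediction median-centres the sample across the panel and
assigns the class with the shorter Spearman distance 1 − ρ.

Numerical decisions:

* **Median-centring is inert.** Spearman correlation depends only on
  within-sample ranks, so subtracting the sample median cannot change a
  call. It is retained for fidelity to the deployed assay's description and
  asserted inert by a property test, not relied upon.
* **Ties.** Ranks within a profile are averaged (standard mid-rank
  handling). An exact distance tie (d_low = d_high) is called **low** — the
  conservative call for a poor-prognosis marker — and is deterministic.
* **Scale tags.** A model file records the normalization scale it was
  trained on and `classify_matrix` refuses input carrying a different tag.
  Whether the training matrix was median-centred before computing centroids
  is irrelevant to Spearman prediction (a per-sample shift does not change
  ranks) but is recorded in the model metadata.
* **Default model.** The shipped model is fit on a seeded *synthetic*
  training cohort (120 patients, balanced classes) because the original
  training matrix is not redistributable. The CSV model format is the
  interface for installing real centroids.

A consequence worth stating explicitly: a rank-based classifier cannot
distinguish two centroids that differ by a *uniform* shift, because their
rank orders coincide. Class separation therefore requires per-gene
heterogeneity in the hypoxia effect — which is also what real signatures
exhibit. This drives a generator design choice (§4).

## 2. QC and normalization

Lane QC flags follow published vendor guidance, all configurable because
deployments differ: imaging FOV ≥ 75%; binding density within
0.05–2.25 spots/µm²; R² of log2(count+1) against log2(concentration) over
the positive titration ≥ 0.95; the 0.5 fM positive probe above
mean + 2·SD of the negative probes. Scaling-factor acceptance windows are
0.3–3 (positive) and 0.1–10 (content).

Normalization pipeline, in order:

1. per-lane positive factor = (geometric mean across lanes of the lane
   positive-control geometric means) ÷ (this lane's geometric mean), applied
   multiplicatively;
2. background threshold = mean + 2·SD of the lane's negative probes (on the
   same scale): counts below it are **raised to** the threshold, not
   subtracted, so positivity is preserved for the log step — a documented
   divergence risk versus tools that optionally subtract;
3. content factor computed identically from the endogenous control genes;
4. log2(x + 1).

Geometric means are computed on count + 1 to tolerate zeros (zero counts do
occur in degraded FFPE material). The across-lane average of lane geometric
means is itself geometric, which gives two clean invariants asserted by
tests: the per-lane factors multiply to exactly 1, and the product over
lanes of (factor × lane geomean) equals (average geomean)^n.

Because both scaling steps anchor to the across-lane average, rescaling a
single lane by a constant moves the entire normalized cohort by one global
log2 constant; each sample's *centred* log2 profile is invariant (up to the
background step and the +1 guards). Every rank-based downstream step —
classification above all — is fully invariant to these per-sample scalar
factors.

## 3. Endogenous control selection

Candidates are shortlisted by coefficient of variation (SD/mean per gene;
with several cohorts, per-cohort ranks are combined by mean rank). The
geNorm stage then computes, for each candidate j,
M_j = mean over other candidates k of SD over samples of log2(x_j/x_k),
iteratively excludes the highest-M gene, and selects the smallest panel size
n whose pairwise variation V(n, n+1) — the SD over samples of
log2(NF_n/NF_{n+1}), NF_n being the geometric mean of the n most stable
genes — falls below 0.15 (the conventional threshold, configurable).

Decisions: log ratios are base 2; an M tie at exclusion drops the
lexicographically last gene; the final two genes cannot be ranked by the
algorithm and share the 2-gene-step M, ordered lexicographically; if no step
satisfies the threshold, all candidates are selected. geNorm runs on
positive-control-normalized counts — content normalization before control
selection would be circular.

One property often quoted for geNorm is that excluding the worst gene
improves every remaining gene's M. That is false in general for the
mean-pairwise definition (a gene whose ratio to the excluded gene happened
to be stable can get worse); what holds, and what the tests assert, is that
the *panel average* M never increases under exclusion.

## 4. Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes;
every stage of the pipeline runs against it.

**Expression.** Per-sample class ~ Bernoulli(π), default π = 53/126 ≈ 0.42
(the Manchester hypoxia-high fraction). Signature gene g in sample s:
log2 expression = mu_low[g] + class_s·Δ[g] + N(0, σ_gene[g]), plus a
per-lane library-size shift N(0, 0.15 log2); counts are the rounded powers
of two (log-normal-then-round, matching the log2-scale analyses; a negative
binomial option would be a config extension). Baselines mu_low span 6–12
log2 units; controls sit higher (10–13), as housekeeping genes do.

**Effect sizes.** No per-gene effect sizes are published for the panel, so
they are config, not inference. A scalar Δ is an overall effect *scale*
multiplying a fixed per-gene profile with mean 1 (spread 0.25–1.75 log2,
fixed permutation); an explicit 24-vector is taken literally. The profile is
heterogeneous by design: §1 explains why a uniform shift would make the
rank-based classifier degenerate. Δ = 0 still produces an exact null.
Defaults Δ-scale 1, σ_gene 0.3 give a well-separated cohort (≥ 95% label
recovery), the regime in which assay prevalence is meaningful.

**Controls.** The five deployed controls default to σ 0.2 (visibly more
stable than signature genes, as observed in real cohorts); the two extra
candidates are noisier (0.45, 0.6) so that control selection has something
to reject. With five equally stable controls, iid noise makes V(2,3)
already small, so the default panel selects two genes; the deployed-assay
situation — pairwise variation first dipping below 0.15 at five genes —
arises when the stable core carries moderate correlated-free noise
(σ ≈ 0.7), and is exercised by a dedicated tuned-panel test.

**Clinical covariates.** Size is log-normal (median 8 cm low / 10.2 cm
high); grade III probability is 0.55 (low) vs 0.77 (high) — the directions
and rough magnitudes of the published cohort tables; age, sex, WHO PS,
depth, margin and histology follow fixed cohort-like distributions, with
myxoid liposarcoma enriched in hypoxia-low and UPS/myxofibrosarcoma in
hypoxia-high. The nomogram pOS is a logistic function of grade, size and
class plus noise, clipped to (0, 1) — enough structure for the
stratification and C-index machinery, with no claim to emulate the actual
nomogram. IHC marker positivity (CAIX, HIF-1α) is class-dependent Bernoulli.

**Survival.** Each endpoint is exponential with rate
baseline·HR^class (proportional hazards; the Cox analyses are
semi-parametric, so any PH-compatible baseline is valid for recovery
experiments). Default HRs are the combined-cohort univariable estimates
(LRFS 2.17, MFS 1.92, DFS 2.00, OS 2.38); default baselines (0.015, 0.07,
0.08, 0.08 events/year) give a Manchester-like ~40% OS event fraction and a
rare (~10%) local-recurrence endpoint over five years. Censoring is uniform
loss to follow-up on (0.5, 15) years truncated by administrative censoring
at 5 years. Two covariate-model switches (`grade3_hr`,
`size_loghr_per_cm`, both off by default) let grade and size act on the
hazard: off, the configured class HR is *marginal* (what a univariable fit
recovers); on, grade and size become genuine confounders and the configured
class HR is the *conditional* one (what the adjusted fit recovers).

**Determinism.** Each component (class draw, expression, clinical, lanes)
uses its own child of a single seed sequence, so one seed gives
bit-identical cohorts and skipping lane generation does not perturb the
rest.

Not modelled: probe chemistry and hybridisation, batch/lot effects, RNA
degradation (RIN/DV200) effects on counts, platform pass/fail rates, and
competing risks. Passing recovery tests therefore demonstrates the
*statistical machinery* — not assay robustness to those real-world factors.

## 5. Statistical battery

* **Per-gene comparisons**: two-sided unpaired t (pooled variance) or
  Mann–Whitney per gene, with the two-stage linear step-up FDR procedure at
  Q = 1%: stage 1 at q′ = q/(1+q) estimates m0 = m − r1; stage 2 steps up at
  q′·m/m0 (everything rejected if m0 = 0). Genes with zero within-group
  variance are flagged p = NA and excluded from the family.
* **Cohort tables**: chi-square without continuity correction;
  Mann–Whitney with normal approximation and tie correction.
* **Survival**: Kaplan–Meier product-limit estimates; any follow-up beyond
  5 years becomes (5, censored), events at exactly 5 years are kept;
  K-group log-rank with K−1 df. Cox models use the partial likelihood with
  Efron tie handling and report Wald CIs and p per term (lifelines is the
  fitting engine; convergence precision is tightened to 1e-9 so estimates
  match an independently maximised partial likelihood to 1e-4).
* **Covariate encodings**: hypoxia high vs low; sex male vs female; WHO PS
  1/2 vs 0; grade I/II vs III (grade III is the reference); depth deep vs
  superficial; margin marginal/R1 vs wide/R0; histology dummy-coded against
  LMS; age and size continuous. Unknown strata are dropped from models
  containing that covariate. The multivariable inclusion rule screens each
  baseline feature univariably (likelihood-ratio p, so multi-column
  features are one block) at α = 0.05; the published wording of the rule
  reads "significant at >0.05", which is implemented as < 0.05 — the only
  reading under which the rule selects prognostic covariates.
* **C-index**: Harrell's C over usable pairs (shorter time is an event, or
  tied times with exactly one event; risk ties count ½), with the pairwise
  U-statistic standard error of Somers' D (SE(C) = SE(D)/2), hand-
  implemented and cross-checked against lifelines' C on tie-free data.
* **Nested LRT**: Δdeviance = 2·(ll_full − ll_reduced), chi-square with df
  equal to the parameter difference; requires same endpoint and data.
* **Stratification**: hypoxia call × (pOS ≥ 0.60); the boundary value 0.60
  is low-risk; patients without pOS are excluded and counted; 4-group
  log-rank and per-group 5-year KM survival.

## 6. Replication experiments and problem sizes

`experiments.py` drives the study-scale runs. Hazard-ratio recovery
simulates cohorts at the validation-study sizes (126 / 154 / 280 patients,
prevalences 53/126, 70/154, 123/280) with the corresponding published
estimate as the generating truth, and summarises the **geometric** mean
fitted HR across replicates with its Monte-Carlo SE. The geometric mean
(the average on the log-hazard scale, where the estimator is asymptotically
symmetric) is the right summary here: an arithmetic mean of HRs carries a
pure Jensen inflation of exp(SE(β̂)²/2) — about +8% for the rare-event LRFS
endpoint — that reflects the averaging scale, not the estimator. The small
upward bias that remains (≈ +2–4% of the Cox MLE at 25–60 events per
cohort) is genuine small-sample behaviour and sits well within the
Monte-Carlo bands.

The acceptance script uses 200 replicates per target (500 for LRFS, whose
~26 events per cohort make the estimate noisiest) and 15 replicates through
the full RCC → QC → normalize → classify pipeline for prevalence recovery;
the test suite runs the same experiments at 60–100 replicates with the
3-MC-SE acceptance band widening accordingly. FDR control under the global
null uses 250 replicate 60-patient cohorts; the concordance experiment uses
the published heterogeneity design (10 tumours, 45 biopsies, 3–8 each).

## 7. Known limitations

* The default centroid model is synthetic; real deployments must install
  trained centroids.
* Exponential baselines and independent censoring are simplifications;
  parameter-recovery results do not probe misspecified-hazard behaviour.
* The generator samples QC metrics independently of expression, so QC
  failure modes correlated with biology are out of scope.
* No PlexSet/multiplexed RCC layouts, no NormFinder/BestKeeper
  alternatives, no competing-risk or calibration analyses.
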