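# Methods

This note documents the statistical models and procedural choices behind
`nmdscreen`: what is computed, under which assumptions, with which
defaults, and what the synthetic-data results do and do not show.

## Severity stages and comparison tasks

Subjects carry one of four CDR-anchored diagnostic classes with a total
severity order: NC (CDR 0) < MCI (CDR 0.5, non-demented) < VMD (CDR
0.5, demented) < dementia (CDR ≥ 1). Five binary discriminations are
evaluated for every screening score: NC vs CI (all three impaired
classes pooled as positive), NC vs MCI, MCI vs VMD, MCI vs dementia,
and VMD vs dementia. The positive class is always the more impaired
side. Instruments whose scores fall with impairment (MMSE, MoCA, CASI,
IADL) are handled by internal score negation; AD8, NPI and the package's
own sum scores rise with impairment.

## Information-gain ranking

Items are binary (impairment endorsed / not endorsed). For the ranking
label, VMD is folded into dementia by default (`label_mode="3class"`),
since instrument derivation targets the NC / MCI / dementia
distinction; the 4-class labelling is available as an option. Entropy
uses base-2 logarithms with the convention 0·log 0 = 0, so every IG
value lies in [0, log2 m] bits. Ranking ties break by ascending item
id — deterministic and audit-friendly.

**Informative-item filter.** Empirical IG of a class-independent item
is almost surely positive on a finite sample, so "IG > 0" cannot
separate signal from noise literally. The default filter builds a
permutation null: labels are shuffled `n_perm = 200` times, per-item IG
values under shuffling are pooled, and the (1 − alpha) quantile
(alpha = 0.05) is the threshold. Under pure noise the expected number
of flagged items is therefore about alpha × 45 ≈ 2. An `epsilon` mode
(`ig > 1e-12`) is retained for emulating toolkits whose printed zeros
come from rounding.

## ROC analysis

The threshold grid is the sorted unique scores plus a sentinel above
the maximum, so the curve always reaches both trivial operating points.
Sensitivity at t is P(score ≥ t | positive), specificity P(score < t |
negative). The AUC is the trapezoidal area of the (1 − spec, sens)
polyline; on this grid it equals the tie-corrected rank statistic
P(pos > neg) + ½P(pos = neg) exactly, and the test suite pins that
identity to 1e-12 against a pair-counting oracle.

**Cutoffs.** The operating point minimises the Euclidean distance from
(sens, spec) = (1, 1) — the upper-left ROC corner. Exact ties go to the
lower threshold, i.e. the higher-sensitivity point, the conservative
choice for a screening test. Integer cutoffs are rendered "a/b"
(score ≤ a negative, ≥ b positive), the conventional rendering for
screening boundaries.

**AUC confidence intervals.** Default is the Hanley–McNeil standard
error with a normal interval clipped to [0, 1] — the classical
distribution-based approach of standard statistical packages. A seeded
stratified percentile bootstrap is available as an alternative
(`method="bootstrap"`); the suite checks the two substantially overlap
on simulated cohorts.

## Pipeline conventions

* **Split.** Train/test splitting is stratified by class with
  largest-remainder apportionment of per-class counts, seeded. A
  1354-subject cohort at fraction 716/1354 splits exactly 716/638.
* **Candidates.** The grid {8, 9, 10, 12, 14, 16} is ranked once on the
  training group; candidates are nested by construction.
* **Selection.** "Accuracy and practicality" is operationalised as
  parsimony-within-delta: the smallest candidate whose mean AUC across
  the five tasks is within delta = 0.01 of the best. This is an explicit
  stand-in for a human judgment and is fully overridable.
* **Staging.** The adjacent cutoffs (NC|MCI, MCI|VMD, VMD|dementia)
  compose into one staging rule over half-open intervals (a boundary
  score goes to the more impaired side). Staging refuses non-monotone
  cutoffs; loading such an instrument only warns, because independently
  estimated pairwise cutoffs can legitimately cross on small samples.
* A shipped 12-item reference instrument carries the reported
  test-group boundaries 2 / 5 / 6 / 9 for NC|MCI, MCI|VMD,
  MCI|dementia, VMD|dementia. Its default item ids 1..12 are nominal
  placeholders (the actual item identities of the derived instrument
  are not public); callers supply real ids to score data.

## The synthetic cohort generator

The generator exists because no patient-level data are available; it is
calibrated so that the *distributional structure the analysis relies
on* is present, not so that any particular result is forced.

Per class c, a subject draws latent severity p ~ Beta(a_c, b_c) with
mean π_c and concentration (1 − ρ_c)/ρ_c; ρ_c = 0 degenerates to
p = π_c. Item j is endorsed with probability λ_j·p + (1 − λ_j)·b_j,
independently given p. The sum over the k = 12 core items (λ = 1) is
then exactly beta-binomial: mean kπ, variance kπ(1 − π)[1 + (k − 1)ρ].
Independent Bernoulli items cannot reproduce the published
dementia-group SD (1.3 at mean 11.2/12 exceeds the binomial cap ≈
0.86), which is what forces the latent-severity form.

**Calibration.** (π, ρ) per class are the method-of-moments solution of
the two identities at the published score moments (0.6 ± 0.7,
3.1 ± 1.7, 6.4 ± 2.1, 11.2 ± 1.3 for NC/MCI/VMD/dementia):
π = mean/12, ρ = (sd²/(12π(1−π)) − 1)/11. ρ is clamped to [0, 0.35];
the NC class's slightly negative raw ρ (underdispersion, SD 0.7 vs the
binomial 0.755) becomes 0, a discrepancy the beta-binomial cannot
represent and which the moment-recovery test tolerances absorb.

**Panel composition.** 12 core items, 12 weak items (λ uniform in
[0.25, 0.6]) and 21 distractors (base rates uniform in [0.02, 0.15]),
roles assigned to seed-shuffled item ids. This emulates a panel in
which roughly 24 of 45 items carry class information while about half
of those dominate. Weak-item loadings and distractor base rates are
plausibility choices for informant symptom endorsement, not published
quantities.

**Class sizes.** The test configuration is the published composition
53/91/108/386 (total 638). The training group's class breakdown is not
published; `default_paper_spec("train", seed)` reuses the test
proportions via largest-remainder apportionment (60/102/121/433 = 716)
as the least-assumption default, overridable in the spec.

**Comparators and demographics.** AD8, MMSE, MoCA, CASI, IADL and NPI
scores, plus age, education and sex, are drawn per class from
independent truncated normals (rounded, range-clipped) at the published
per-class moments. Correlations *between* instruments are not
modelled, so comparator-vs-instrument orderings on synthetic data are
qualitative only.

**Randomness.** Everything flows from one integer seed through a
`SeedSequence`; each diagnostic class uses its own child stream, so
resizing one class leaves the other classes' subjects unchanged.
Published realized ranges (e.g. MCI score range 0–10) are sample
artefacts, not distribution bounds; the generator does not enforce
them and tests do not assert them.

## What the synthetic results show — and don't

The simulator is moment-matched, not shape-matched: it reproduces the
per-class score means/SDs and the induced item correlation, but not
item-level heterogeneity in difficulty, informant response styles,
education/age effects on endorsement, or missing data. Passing the
stochastic checks (mean AUCs within ±0.05 of the published
0.99/0.94/0.88/0.97/0.96 across 50 replicates; modal NC-vs-MCI boundary
"1/2"; ≥ 11 of 12 core items in the IG top 12 at n = 2000) demonstrates
that the *pipeline* recovers the right instrument and operating points
when the data have the assumed structure — it is not a clinical
validation of any instrument on real patients.

Problem sizes in the test suite were chosen so the full run stays
small: 50 replicates of 638 subjects for the operating-characteristic
sweep, 5000 subjects per class for moment recovery, 20 seeds at 2000
subjects for ranking recovery. The whole suite runs in well under a
minute.

## Supporting statistics

One-way ANOVA (between/within mean-square F on k − 1, N − k df) and
Pearson chi-square without continuity correction back the
group-comparison table; the no-correction choice matches the default of
the major commercial packages at these cell sizes. Inter-rater
reliability uses ICC(2,1): two-way random effects, absolute agreement,
single rating — the standard form when both raters are interchangeable —
computed from the two-way mean squares and cross-checked in the suite
against an independent variance-components oracle and against
pingouin's ICC(A,1). Post-hoc pairwise contrasts are reported only as
descriptive orderings of group means; no multiplicity correction
machinery is included.

## Known limitations

* Items are strictly binary; ordinal response levels are out of scope.
* Missing item responses survive I/O but are rejected by analysis
  operations rather than imputed.
* No longitudinal structure, no differential item functioning, no
  missing-data mechanism in the generator.
* The AUC CI does not include DeLong paired-curve comparisons, and no
  partial/smoothed AUC variants are provided.
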