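# Methods

This note records the statistical model implemented by `ttdrank`, the
conventions chosen where several were defensible, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Evidence model

A curated record table holds one study conclusion per row. Studies are not
exchangeable: the experimental system that produced a finding determines
how much it should count. The seven model tiers are ordered by distance
from the human in-vivo condition and weighted on a doubling ladder,

    model_score(tier) = base_score · 2^tier,   tier = 0 … 6,

with `base_score = 6` for the animal-in-vitro tier. The doubling ratio and
the base are design constants of the scoring scheme, not fitted values; the
base is configurable (`SummaryConfig.base_score`).

When a study's sample size `n` is recorded (curated tables carry it for
clinical tiers only), a size score `n/10` adjusts the weight. Two
combination rules are implemented:

* **multiplicative** (default): `ES = model_score · (1 + n/10)`. The factor
  reduces to 1 for unknown `n`, so preclinical records keep their exact
  ladder value, and tier ordering is preserved for any fixed `n`.
* **additive**: `ES = model_score + n/10`, selectable via
  `size_combination="additive"` for users who want the size adjustment to
  be tier-independent.

The multiplicative rule is the package's convention; the size score is
applied whenever `n` is present, regardless of tier (a case count on a
preclinical record is flagged as a validation warning, not ignored).

## Prevalent-hypothesis decision rule

Within one evidence group (molecule, state, drug, relationship class, plus
the modifier for synergism), the per-direction score percentage is
`SP_i = ES_i / ΣES`. Evidence scores are treated as binomial pseudo-counts
(successes `ES_i` out of `ΣES` trials, both possibly non-integer) and the
Agresti–Coull correction is applied:

    ñ   = ΣES + z²
    SPc = (ES_i + z²/2) / ñ
    SE  = √(SPc (1 − SPc) / ñ)
    CI  = SPc ± z·SE, clipped to [0, 1]

with `z = Φ⁻¹(0.975) = 1.959964` at the default 95% level (never rounded to
2). Direction `i` is declared prevalent under the default criterion when

    SP_i > θ   and   SPc − z·SE > θ,      θ = 0.5,

with strict inequalities — a tie at exactly θ fails. The alternative
`z_test` criterion requires `SP_i > θ` and a significant positive
`Z = (SPc − θ)/SE` at level `1 − confidence_level`. The two criteria are
not forced to agree. With θ ≥ 0.5 at most one direction can qualify because
the score percentages sum to one.

`minimal_base_score` audits the choice of the base constant: it scans for
the smallest integer `b` such that a single lowest-tier study (all `b`
score units on one direction) is already prevalent. Under this
implementation the scan yields **5** for the CI-lower-bound rule (and for
the Z-test with the estimated SE) and **7** for a Z-test evaluated with the
null-hypothesis standard error `√(θ(1−θ)/ñ)`. Neither convention yields 6;
the default `base_score = 6` is kept as the scheme's published constant and
the scan is exposed so users can see the discrepancy.

Groups whose prevalent verdict is null or undetermined are eliminated from
prediction; prevalent positive/negative groups form the drug's informative
molecules.

## Profile matching and drug ranking

Each informative molecule's SP receives a sign: `+` when the prevalent
evidence is favourable (sensitivity, synergism, decreased toxicity), `−`
when unfavourable. Concordance with the patient flips the sign: a
state-pair lexicon declares each literature state's opposite (e.g.
`mut V600E ↔ wt`), and a patient carrying the opposite state contributes
with inverted sign. A patient state that is neither the literature state
nor its declared opposite is *unresolvable* and the molecule is excluded
with a recorded reason — never imputed. Untested molecules are likewise
excluded and reported.

The per-drug overall score is the inverse-variance weighted mean

    OS = Σ W_i · SP_i± / Σ W_i,   W_i = 1/V_i,   V_i = SPc(1 − SPc),

with `OV = 1/ΣW_i`, `SE = √OV` and CI `OS ± z·SE` clipped to [−1, 1].
`V_i` is deliberately **not** divided by the group's evidence total: the
weight depends only on the magnitude of the corrected proportion, so a
molecule whose literature is one-sided (SPc near 0 or 1) counts more than a
contested one, independent of corpus size. The threshold test runs on |OS|
(`Z = (|OS| − θ)/SE`, two-tailed p) because the decision rule is symmetric
for sensitivity and resistance; classification additionally requires the CI
bound nearer zero to stay beyond `sign(OS)·θ`. Two drugs are compared with
`Z = (OS_a − OS_b)/√(OV_a + OV_b)`.

Synergism evidence is summarized like any other class but excluded from
patient-level ranking by default: it describes drug-pair interactions, not
patient states.

## Synthetic corpora and what they show

The generator emulates the *record-level structure* of a curated table:
per-group ground truth (`true_direction`, `support_prob`), tier mix, case
counts on clinical tiers only, and schema-valid rows. Defaults, chosen to
resemble a curated oncology literature:

| parameter | default | rationale |
|---|---|---|
| tier mix | (0.10, 0.08, 0.40, 0.12, 0.22, 0.06, 0.02) | preclinical-heavy; human-in-vitro dominates; meta-analyses rare |
| studies per group | 10 | typical depth for a well-studied pair |
| cases (clinical tiers) | DiscreteUniform(50, 500) | phase-II to randomized-trial enrolments |
| disagreement split | 50/50 | disagreeing studies split evenly between the two non-true directions |

One integer seed feeds named substreams (corpus / profiles / responses), so
each stage reruns independently and reproducibly. Responder outcomes are
Bernoulli with `P(response) = logistic(intercept + slope·OS)`.

What the generator does **not** emulate: real literature text, citation
structure, correlated study designs, publication bias, or molecule-state
vocabularies beyond the paired mutant/wild-type convention. Passing tests
therefore demonstrate the algorithms' internal operating characteristics,
not performance on real curated corpora.

### Operating characteristics worth knowing

Because evidence scores enter the binomial formulas as pseudo-counts, a
single case-weighted clinical record can contribute thousands of
pseudo-trials (an RCT with n = 500 carries 192 · 51 = 9792 units). Two
consequences, both measured by the test suite and the acceptance script:

* **Recovery improves with corpus depth.** At support probability 0.8 the
  prevalent verdict recovers the true direction in ≈97% of replicates with
  50 studies per group, but only ≈83–85% with 10, because a single large
  trial drawn on the wrong direction can dominate its group. The
  parameter-recovery checks run at 50 studies per group; the acceptance
  script reports both depths.
* **Pseudo-count inflation tightens intervals.** Under uninformative truth
  (support 1/3) a lone heavyweight record can make a random direction look
  prevalent; with 50 studies per group the undetermined rate is ≈58%
  (majority), with 10 it drops to ≈17%. Users summarizing shallow groups
  that contain large trials should read prevalent verdicts accordingly.

The end-to-end discrimination study feeds the *computed* OS into the
logistic outcome link (one OS per profile, matching the simulator's
contract), so the AUC-versus-support comparison measures how much sharper
and more spread the evidence-driven scores become as the literature grows
more consistent; the three support levels share common random numbers so
the comparison is paired.

## Validation metrics

The Brier score is the mean squared forecast error; OS is mapped to the
probability scale by `(OS + 1)/2` (an explicit, configurable convention —
no calibration claim is implied). The Murphy decomposition uses 10
equal-width bins by default, empty bins contributing zero; reliability is
computed from each bin's mean forecast, so
`reliability − resolution + uncertainty` recovers the Brier score of the
*binned* forecasts exactly (to 1e−12), differing from the raw Brier score
by the within-bin forecast variance. Both quantities are reported. AUC is
the normalized Mann–Whitney statistic (average ranks, ties half-credit);
the ROC sweep reports (threshold, sensitivity, specificity) at every
distinct score plus the operating point at the 0.5 decision threshold.

## Numerical conventions and degenerate inputs

* Text grouping keys are trimmed, whitespace-collapsed and casefolded;
  original casing is preserved on output.
* Zero-total groups produce an `undetermined` summary with a flag rather
  than an error; empty record groups and empty metric inputs raise.
* CI bounds are clipped to their natural ranges after the ± step.
* Ranking breaks OS ties alphabetically by drug name for determinism.
* The pairwise drug matrix has diagonal (z, p) = (0, 1) and is exactly
  antisymmetric in z.

## Problem sizes

The simulation studies in the test suite and acceptance script use 200
replicates of three 50-study groups for parameter recovery, 200 one-group
replicates for the uninformative condition, and 50 paired replicates per
support level (four molecules, 60 profiles each) for the AUC study. These
sizes give Monte Carlo standard errors comfortably below the margins of the
properties they check.

## Limitations

* The scoring ladder, the n/10 size score and the 0.5 decision rule are
  design constants of the summarized scheme, not estimated quantities; no
  uncertainty attaches to them.
* `V_i = SPc(1−SPc)` ignores the evidence total, so OS confidence intervals
  do not narrow as a molecule's literature grows; only SPc moves.
* The concordance model is binary (state vs declared opposite); graded or
  multi-state genotypes are out of scope.
* No covariate-adjusted outcome modelling is included; the metrics module
  evaluates OS-based forecasts only.
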