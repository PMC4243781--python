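# Methods

## The score and its rules

The Diabetes Remission Score dichotomizes seven preoperative variables
(see README for the table) and sums them to 7–14. The numeric cut-offs
are applied to the raw real values with no rounding; the favourable age
band 30–60 is inclusive at both ends (the unfavourable band is strictly
"<30 or >60"), BMI 27 and C-peptide 4 are favourable boundaries
(`≥`), duration 10 is unfavourable (`≥ 10` scores 2). Missing or
non-finite scoring inputs are a hard error: on a 7-point-wide integer
scale a silently imputed component would shift a patient by a full
band, so nothing is imputed, ever.

The complication flags are pre-adjudicated booleans. The conventional
readings — microvascular: retinopathy, nephropathy, neuropathy;
macrovascular: coronary, cerebrovascular, peripheral arterial disease —
are documented but not enforced, and the stimulated C-peptide value is
accepted as reported without assuming a specific stimulation protocol,
because neither was operationalized in the derivation study.

Eligibility: age 25–70 (inclusive), diabetes duration strictly > 1 year
(> 5 for IIDSG), HbA1c strictly > 7 %, BMI ≥ 20 kg/m² (strictly > 18.5
for IIDSG), stimulated C-peptide strictly > 1.5 ng/mL; exclusion
diagnoses and "stable weight" enter as optional boolean flags since no
operational definitions exist. Remission: HbA1c < 6.5 % (strict) off
all glucose-lowering medication — comparable to ADA partial remission.

## Outcome bands

Remission probabilities are per-score empirical step functions of the
derivation cohort, stored in `src/drscore/data/outcome_bands.json` and
overridable by the user: IISG 1.00 / 0.35 / 0.00 over 7–8 / 9 / ≥ 10,
IIDSG 1.00 / 0.55 / 0.00 over 8–10 / 11 / ≥ 12. No logistic or isotonic
smoothing is applied; the bands are the claim being packaged, not a
fitted model. Two edge choices: the abstract's "more than 12" for the
IIDSG no-remission cut-off is superseded by the results section's
"≥ 12", which is what the band table encodes; and scores outside a
procedure's observed range (7 under IIDSG, 14 under IISG) return the
adjacent band's value with an `OutsideObservedRangeWarning` rather than
silently extrapolating. The recommendation map (7–8 → IISG, 9–11 →
IIDSG, 12–14 → neither) coincides with the severity grades and, by
construction, never selects the procedure with the lower band
probability.

## Statistics

Group comparisons are unpaired two-sided t-tests computed from
(n, mean, SD) triples, so printed summaries are as usable as raw data.
Both the pooled and the Welch variant are implemented from the textbook
formulas with the t distribution from scipy; Welch is the default, and
every report labels the variant. The derivation study did not state
which variant it used; from its printed summaries both round to its
p = 0.0004 for the between-procedure comparison. Degenerate inputs
follow explicit conventions (both SDs zero: p = 1 for equal means, p = 0
otherwise). Percentages are rounded half-up to whole percent (45.65 % →
46 %), matching the derivation study's presentation. No
multiple-testing correction is applied (none was used there); reports
carry the number of tests performed.

Three printed values are documented as irreproducible and excluded
from every quantitative check (`drscore.published.IRREPRODUCIBLE`):
the p = 0.1468 for IISG non-remitters vs IIDSG remitters (both variants
give ≈ 0.05 from the printed summaries), the BMI ≥ 35 subgroup p = 0.07
(subgroup n never printed), and the obese/non-obese DRS rows that
duplicate the remission-split values verbatim (probable typesetting
error).

## Reconstruction from printed aggregates

`reconstruct_score_distribution` enumerates, by depth-first search with
score-sum pruning, every integer count vector over the observed score
range that satisfies a constraint set: cohort n, mean and SD within
±0.05 (the tolerance implied by one-decimal rounding), occupied range
endpoints, the band rules (all-remit scores, no-remit scores, and the
requirement that the partial band's remission fraction rounds half-up
to the printed 35 % / 55 %), the exact remitter total, and optionally
the remitter/non-remitter summaries. Because the printed SDs'
denominator is unknowable, a solution is accepted if either the n−1 or
the n convention matches, and records which. Solutions are returned in
lexicographic order and re-validated by an independent evaluator
(`check_solution`) that expands the counts into an explicit multiset —
double-entry bookkeeping against search bugs. Search is refused up
front beyond n = 200 or a range wider than 8 scores.

**Finding: the full printed aggregate set is self-contradictory for
both procedures.** For IISG, a remission fraction at DRS 9 that rounds
to 35 % forces (remitters, total) at DRS 9 into {(6,17), (7,20),
(8,23)}, hence ≥ 11 non-remitting DRS-9 patients; the 25-patient
non-remitter group then cannot reach mean 10.2 with SD 0.9 (the
minimum achievable SD given the mean window is ≈ 1.27). For IIDSG the
contradiction is one line of arithmetic: the observed maximum score 14
belongs to a non-remitter 2.0 above the printed non-remitter mean 12.0,
so its squared deviation alone (4) exceeds the largest sum of squares
compatible with SD 0.5 ± 0.05 at n = 8 (7 × 0.55² ≈ 2.1). The solver
therefore proves both "printed-full" presets infeasible (0 solutions).
Dropping only the remitter/non-remitter summaries — the aggregates the
study itself prints twice under two different labels, hence the least
trustworthy — yields the feasible "default" presets: 511 IISG and 17
IIDSG solutions, every one reproducing the 46 % and 72 % remission
rates and the cohort mean/SD. The corresponding acceptance test for
the full printed set is intentionally left failing: it records a
property of the published numbers, not of this implementation.

## Synthetic cohort generator

The generator emulates the derivation cohort's structure: each score
component is an independent Bernoulli draw of its unfavourable state;
raw fields are then drawn from truncated normals whose location/scale
come from the published baseline profile (age 51.7 ± 13.3 / 57.6 ±
11.5 years, BMI 23.4 ± 4.5 / 25.6 ± 4.5 kg/m², duration 9.9 ± 4.8 /
10.1 ± 5.0 years, HbA1c 8.1 ± 0.59 / 9.0 ± 0.78 % for IISG / IIDSG),
truncated to the intersection of the eligibility window and the drawn
component state — so every generated record passes the eligibility
screen by construction, a property asserted across seeds. Stimulated
C-peptide, which has no published marginal, uses 3.0 ± 1.2 ng/mL, a
plausible range for insulin-treated T2DM. Remission is assigned either
by the outcome bands (`band_model`, the default — band rules then hold
by construction) or by a logistic model in the total DRS, used for
directional parameter-recovery checks.

The default unfavourable probabilities were calibrated once and
frozen: the sums are anchored analytically (E[DRS] = 7 + Σp, so
Σp = 2.2 / 3.4 gives exactly 9.2 / 10.4) and the apportionment across
components follows the published profile — retinopathy 21/46 vs 13/29
for the microvascular flag, the large insulin-dose gap (28 vs 76 U/day)
for insulin use, the BMI and age means for their components. They are a
synthetic emulation, not an estimate of the true prevalences, which
were never published.

Known limitation: with seven independent Bernoulli components the
per-cohort DRS variance is at most 7 × 0.25, i.e. SD ≤ 1.32, slightly
below the published 1.4; matching it would require positive
between-component correlation (a shared severity factor) that nothing
published constrains. Replicate means are unaffected (the calibration
check uses 200 replicate cohorts of n = 46, sized to keep the whole
suite fast while leaving the Monte Carlo error of the grand mean near
0.01). Passing tests on these cohorts show the pipeline's arithmetic
and rules are right under the published marginal structure; they say
nothing about correlated real-world risk factors, secular trends, or
other surgical procedures, for which the score itself claims no
validity.

## Pipeline and reproducibility

Every pipeline report embeds package version, seed and a hash of the
analysis-relevant configuration; outputs are computed fully before
anything is written, so validation failures leave no partial bundles.
Identical config and seed reproduce byte-identical outputs.
`drs reproduce` re-derives every in-scope published aggregate next to
its printed value and carries the documented irreproducible values
verbatim, labelled as such.
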