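# Methods

## The analysis model

`pvsignal` implements the case/non-case design used for signal detection in
spontaneous-report pharmacovigilance databases such as FAERS. The counting
unit everywhere is the deduplicated individual case safety report (ICSR): a
report counts once per contingency cell no matter how many matching drug or
event mentions it lists. Exposure is defined as the presence of any index
drug with a counted role (primary suspect, secondary suspect, and
concomitant by default; the rare "interacting" code is folded into
concomitant), optionally restricted to reports carrying a required
therapeutic indication on any drug mention. The comparator arm is either
the whole rest of the database or the subset of remaining reports listing a
named comparator drug; a report listing both an index and a comparator drug
counts as exposed only. The indication restriction applies to the exposed
arm alone by default, because published screens of this kind restrict the
exposed margin to the indication of interest while comparing against the
unrestricted database margin; a flag extends the restriction to a named
comparator arm for users who want symmetric restriction.

### Reporting odds ratio

For the report-count table (n11, n10, n01, n00),

    ROR = (n11 · n00) / (n10 · n01),
    CI95 = exp(ln ROR ± 1.96 · sqrt(1/n11 + 1/n10 + 1/n01 + 1/n00)).

No Haldane–Anscombe continuity correction is applied: with any zero cell
the ROR and its interval are reported as undefined (NaN) and never signal.
This choice is validated by the bundled published screen margins, whose
printed lower bounds are reproduced to the printed precision only without
a correction. A signal is flagged when ROR_025 > 1.

### Shrinkage information component

With E = drug_total · event_total / N,

    IC     = log2((n + 0.5) / (E + 0.5)),
    IC_025 = IC − 3.3 (n+0.5)^(−1/2) − 2 (n+0.5)^(−3/2),
    IC_975 = IC + 2.4 (n+0.5)^(−1/2) + 0.5 (n+0.5)^(−3/2).

The +0.5 terms shrink small-count signals toward the null and the analytic
credibility-bound constants are the standard approximation for the
shrunken observed-to-expected log-ratio. These constants reproduce all ten
published IC_025 values of the bundled SMQ screen to the printed
precision, which is the package's primary exactness gate. A signal is
flagged when IC_025 > 0. The shrinkage vanishes as counts grow
(|IC − log2(n/E)| < 0.01 already at E = 10^4), and the interval width is
monotone decreasing in n — both asserted as properties.

Screens over many PTs report every row; rows with n not exceeding the
minimum-count rule (strictly more than 5 by default) are flagged rather
than dropped. No multiple-testing adjustment is applied anywhere, matching
standard disproportionality practice; every interval is unadjusted.

### Between-stratum IC delta

The subgroup contrast is an observed-to-expected ratio between two
disjoint strata of the same drug–event pair. With the index stratum's
exposed total d_i and the reference stratum's event rate n_r / d_r,

    E_index  = d_i · n_r / d_r,
    IC_delta = log2((n_i + 0.5) / (E_index + 0.5)),

bounded with the same credibility constants on (n_i + 0.5). A
significantly negative delta (upper bound below zero) marks
under-reporting in the index stratum. The published description names the
method without printing a formula; this reconstruction follows the quoted
observed-to-expected definition and is flagged as such.

### Omega interaction statistic

For the 2×2×2 table over (drug A) × (drug B) × (event), with observed
event proportions f_ab in the four exposure cells, the no-interaction
expectation for the co-exposed cell solves

    1/(1 − g11) = 1/(1 − f10) + 1/(1 − f01) − 1/(1 − f00),

and Ω = log2((n111 + 0.5)/(g11 · n11· + 0.5)) with the same credibility
constants on (n111 + 0.5); an interaction signal is Ω_025 > 0. The
harmonic combination is additive in excess risk for small risks
(g11 ≈ f10 + f01 − f00), so it always meets or exceeds each single-drug
risk alone while staying below the multiplicative expectation
f10·f01/f00 whenever the background risk is below both single-drug risks
— the sense in which the additive-excess null is the conservative choice
for detecting super-multiplicative interactions. Two documented
degeneracies: any empty exposure cell or any f_ab = 1 is an error, and a
background risk so far above both single-drug risks that g11 ≤ 0 is an
error as well. g11 is deliberately not floored at max(f10, f01); pass
`floor_g11=True` for the stricter clamped variant used by some
implementations. The statistic is symmetric in the two drugs (asserted as
a property).

### Sensitivity arms and consistency grading

Three arms probe a drug–event signal for confounding:

* **competition_bias** — drop reports co-medicated (any role) with any
  drug on the supplied event-inducing list; the broad any-role exclusion
  is the conservative reading.
* **pre_existing** — drop reports carrying any PT from the pre-existing
  disease list. Curated lists of this kind routinely include the index
  event itself (prior disease as history); because this data model only
  carries event PTs, the index event terms are removed from the exclusion
  set before filtering — otherwise the arm would empty the case series by
  construction.
* **suspect_hcp** — one combined arm: healthcare-professional reporters
  only AND suspect-only (PS/SS) exposure roles.

The consistency grade is a pure function of the number of arms with
IC_025 > 0 (an arm with zero observed cases contributes no signal):
3/3 Strong, 2/3 Intermediate, 1/3 Weak, 0/3 No signal. Each arm only
removes reports, so every arm's exposed total is bounded by the primary
analysis; arms are mutually independent and order-free.

### Time trend and time to onset

The trend series recomputes the IC per window of receipt quarters;
cumulative mode (all reports received up to each window end) is the
default, matching the conventional signal-stability view, with
non-cumulative per-window mode available since the published trace
convention is not stated. Calendar-year windows at quarterly granularity
are the default grid. Time to onset is days from the earliest start date
of a matching drug mention to the earliest onset of a matching event;
negative onsets (event precedes drug) are tallied separately and excluded
from the median/IQR, since they usually flag an event that cannot be
drug-induced.

## The synthetic report generator

The generator draws reports independently. Per report: each catalog drug
enters by an independent Bernoulli draw of its marginal probability; each
catalog event enters with probability

    baseline × ∏ association(drug, pt) × subgroup(drug, pt, stratum)
             × interaction(drugA, drugB, pt),

multiplied over the applicable planted effects and capped at 1 (capping is
counted and warned about). Demographics, reporter type, roles, per-drug
indications, receipt quarter, dates, and outcome flags come from
configured mixes, independent of the event draws.

A report whose Bernoulli draws select no drug receives a designated
*background drug* rather than a forced catalog drug — forcing or rejection
sampling would inflate the catalog marginals, and the generator's marginal
calibration (binomial 99% CI at n = 100,000) is a tested invariant.

Default demographic and reporting mixes emulate the descriptive profile of
spontaneous-report case series in this indication: 70% female among known
sex with 12% sex missingness, age ≈ N(47, 12²) years with 40% missingness,
34% healthcare-professional reporters, receipt years skewed 88% into
2019–2022, fatal-outcome flag at 11.3%, and a role mix dominated by
secondary-suspect coding. `make_aslike_fixture` packages these defaults
with seven bDMARD-like drugs, a comparator panel, the ten SMQ PTs plus
common co-reported events, a ×4 female subgroup effect on every
bDMARD–pericarditis pair, and one planted drug-pair interaction; it
returns the generating configuration as the ground-truth record.

Reproducibility: one root seed keys a counter-based Philox stream, and
report *i* consumes row *i* of a fixed-width uniform matrix, so enlarging
`n_reports` extends a collection without reshuffling earlier reports (with
catalogs held fixed). Categorical mixes are consumed in sorted key order,
so equal configurations generate identical collections regardless of how
their dictionaries were ordered on disk.

What the generator does **not** model — and what passing tests therefore
do not show about real data: duplicate submissions and versioned case
histories (the simulator emits one version per case; deduplication is
exercised by hand-built fixtures), report-level event correlation beyond
shared drugs, free-text drug-name noise beyond case/whitespace
normalization, outcome flags correlated with events, indication
misclassification, and secular reporting artifacts such as lawyer-driven
report waves.

## Validation problem sizes and numerical choices

Simulation-based checks use 200,000-report collections: planted
reporting-rate ratios ρ ∈ {1, 2, 8} are recovered as the mean 2^IC over
five replicate collections to within ±20% (drug marginal 0.01, event
baseline 0.05, chosen so the expected exposed case count ≈ 100·ρ makes
that band several standard errors wide); null calibration uses 40
(drug, event) pairs with all multipliers at 1 and requires the IC_025 > 0
rate to stay within the nominal one-sided 2.5% plus sampling slack; the
omega screen must detect a planted ×5 interaction and stay quiet on at
least 37 of 40 null drug pairs; and a ×4 female subgroup effect must drive
the male-index IC-delta upper bound below zero. Table builders are checked
against literal brute-force re-counts on 100 random collections.

Other numerical conventions: deduplication keeps the latest version date
with ties broken by the lexicographically greatest version marker, and
returns reports sorted by case identifier so repeated runs are
deterministic; receipt quarters use the canonical `YYYYQn` token whose
lexicographic order is chronological; drug names are case-folded, trimmed,
and whitespace-collapsed with no ingredient dictionary (a synonym-map hook
is provided instead, since term dictionaries are licensed); age bands are
0–24, 25–65 (inclusive), >65; missing sex/age stay in primary analyses and
drop out of the corresponding strata only.

## Known limitations

The pipeline measures reporting disproportionality, not risk or incidence
— there is no person-time denominator in spontaneous-report data, and
neither the ROR nor the IC is a causal effect estimate. SMQ term sets are
flat PT lists with no MedDRA hierarchy traversal. The IC-delta and omega
formulas are reconstructions validated by their mathematical properties
and by the exactly reproduced screen bounds, not by access to the original
analysis software.
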