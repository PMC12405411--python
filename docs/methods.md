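# Methods

## Problem and pipeline

Spontaneous-report databases such as FAERS accumulate voluntary reports of
suspected adverse drug reactions. Whether a drug–event pair is reported
*disproportionately* often, relative to the database background, is the
basic screening question of pharmacovigilance. `faersig` implements that
screen end-to-end for one target drug:

1. **Ingest** the five raw quarterly tables (DEMO, DRUG, REAC, THER, OUTC)
   in the `$`-delimited ASCII or CSV dialect; all quarters are concatenated
   before cleaning, so a case resubmitted across quarters deduplicates
   globally.
2. **Deduplicate** report versions per the FDA-recommended rule: within
   each CASEID keep the version with the largest FDA_DT, ties broken by the
   largest PRIMARYID (compared numerically when all PRIMARYIDs parse as
   integers, which is the FAERS convention; versions with an unparseable
   FDA_DT lose any tie). Child-table rows of discarded versions are
   dropped.
3. **Select** the target series: reports with at least one DRUG row whose
   role code is PS and whose drug name or active ingredient matches a
   synonym as an exact string or whole token of the uppercased text.
   Substring-anywhere matching is deliberately rejected to avoid false
   positives from unrelated names containing a synonym.
4. **Aggregate terms**: reaction PTs are uppercased, deduplicated within a
   report (a report contributes at most once per term), and mapped to SOCs
   through a user-supplied two-column table; unmapped PTs are bucketed
   under the sentinel SOC `UNMAPPED` and counted.
5. **Tabulate and test**: per term, the 2×2 cells are counted over the
   report×term incidence at the chosen level (PT or SOC), and the four
   statistics with their criteria are evaluated.
6. **Screen**: final signals are the intersection of the four flag sets;
   exclusive Venn-region counts describe algorithm disagreement; top-N
   tables rank estimable terms by case count, ties broken lexicographically.
7. **Describe**: characteristics of the target series (sex, age group,
   reporter, country, outcome, reporting year), an unknown-age sensitivity
   re-analysis, and time-to-onset binning.

## Counting conventions

**Denominator scope.** The cells derive from the report×term incidence at
one level: `a` = target reports containing the term, `b` = remaining
target-report incidences, `c`/`d` likewise for all other reports, so
N = total incidences at that level and is constant across terms. Published
FAERS analyses rarely state their N; this convention is declared here and
in the output metadata so alternatives (report-level N) can be compared.
At SOC level a report counts once per SOC regardless of how many of its
PTs map there.

**Zero cells.** No Haldane/continuity correction is applied anywhere. A
table with a zero in any required denominator is marked non-estimable, its
statistics are NaN, all four flags are false, and it is excluded from
signal lists and top-N rankings (with a logged count). χ² is the plain
(uncorrected) Pearson statistic of the 2×2 table.

**EBGM as printed.** The EBGM implemented is the observed/expected ratio
aN/[(a+b)(a+c)] with a one-sided lower bound at z = 1.64 (the one-sided 95%
and two-sided 90% lower bounds coincide) — *not* the full Gamma–Poisson
mixture (MGPS) empirical-Bayes fit. This O/E form is what many published
FAERS analyses tabulate under the EBGM heading; consequently
IC = log₂(EBGM) holds identically, which the tests assert to 1e-12.

**BCPNN.** The information component uses the standard Bayesian posterior
with all elementary hyperparameters set to 1 (α = β = 2):
γ = γ₁₁(N+α)(N+β)/[(a+b+α₁)(a+c+β₁)],
E(IC) = log₂[(a+γ₁₁)(N+α)(N+β)/((N+γ)(a+b+α₁)(a+c+β₁))], and
V(IC) = (1/ln²2)·[(N−a+γ−γ₁₁)/((a+γ₁₁)(N+1+γ)) +
(N−a−b+α−α₁)/((a+b+α₁)(N+1+α)) + (N−a−c+β−β₁)/((a+c+β₁)(N+1+β))].
E(IC) and V(IC) remain defined at a = 0 (the posterior shrinks toward
independence); the point IC does not.

**A non-obvious property.** Because N grows with `a`, the O/E ratio is not
monotone in `a` with b, c, d held fixed: aN/[(a+b)(a+c)] rises and then
decays toward 1 (e.g. b=c=d=1 gives 1.125 at a=3 but 130/121 at a=10).
ROR and PRR are strictly increasing in `a`. The test suite pins both
behaviors. On any all-positive table, ROR ≥ PRR ≥ EBGM when ad > bc, with
equality iff ad = bc.

## Synthetic corpus generator

The generator emulates the structure a FAERS extract presents to this
pipeline, with known ground truth. Per logical case: one primary-suspect
drug (target with probability `p_target`, else a weighted comparator);
each PT j included independently with probability min(1, q_j·RR_j) on
target reports and q_j otherwise; at least one PT forced by redrawing
(every real report has a reaction). A `duplicate_rate` fraction of cases
is emitted in two versions differing only in FDA_DT (strictly later) and
PRIMARYID (strictly larger), so the dedup rule is observable but
ground-truth counts stay unambiguous. Roughly 30% of reports carry a
concomitant comparator row and ~1% of non-target reports list the target
drug as concomitant — rows the PS-only selection must ignore. Dates are
YYYYMMDD integers.

Defaults are the package's study conditions: n = 20,000 reports,
p_target = 0.01, five planted PTs at RR = 8 on a 2% baseline among 200
null PTs at 2%, duplicate_rate = 0.2 (two-version duplication at rate r
discards r/(1+r) ≈ 16.7% of raw rows, the magnitude seen in real cleaned
corpora). Demographic and administrative marginals mirror the published
laronidase series: 38.6% unknown age (known ages split 25.9/46.6/27.5%
across <5, 5–18, >18 years, with under-2s reported in months to exercise
unit conversion), 27.7% unknown sex, reporter-country mass 73.7% US and
3.2% Brazil, reporter-type mass 65.5% consumer / 22.0% physician / 6.1%
other health professional, single most-serious outcome codes at the
published outcome shares, reporting years 2004–2024 at the published
yearly shares, therapy-start dates present for 32.4% of reports, and an
onset-day mixture placing 64.06% of known onsets beyond 360 days (other
bin weights 0.12/0.04/0.03/0.06/0.1094 over 0–30/31–60/61–90/91–180/
181–360 days — only the >360 share is externally anchored; the rest is a
plausible spread, configurable).

What the generator does *not* emulate: reporting-delay dynamics,
drug–drug interactions, dose/indication records, correlated PTs within a
report, age- or sex-dependent reaction profiles, and real MedDRA
vocabulary beyond a synthetic PT→SOC map. Passing recovery tests therefore
demonstrates that the pipeline's plumbing and decision rules are correct
under the independence assumptions disproportionality statistics already
make — not that those assumptions hold in real FAERS data.

## Test design and problem sizes

Planted-signal recovery runs 100 independent corpora under the default
conditions; the four-algorithm intersection must contain all five planted
PTs in ≥95 seeds, with on average ≤5% of null PTs flagged (observed: all
seeds recover all five; null false positives are essentially absent,
because four criteria intersected at a ≈ 32 are conservative).

The unknown-age sensitivity property — excluding unknown-age reports
leaves the top-3 PT identity unchanged in ≥95 of 100 corpora — is tested
on a variant whose planted PTs carry baseline probabilities in the
frequency ratios of the real series (q = 0.055/0.026/0.0198/0.0135/0.0125)
with p_target = 0.05, giving a target series of ~1000 reports. Under the
default config all five planted PTs are exchangeable, so their frequency
ranking is a tie and "top-3 identity" is undefined — rank stability is
only a meaningful property when the ranking is identifiable, as it is in
the real series (case counts 465/223/167/114/106).

Statistical correctness is established against an independent
exact-rational oracle (`fractions.Fraction` ratios, floats only at the
final log/exp step) on 1,000 log-uniform random tables with cells in
[1, 10⁶], to a combined tolerance of 1e-10 relative or 1e-12 absolute —
the absolute floor exists because IC-type quantities can sit arbitrarily
close to 0, where a pure relative criterion is ill-posed in double
precision. Analytic nulls (a=b=c=d=k) must hit independence exactly
(≤1e-12) for k up to 10⁶.

## Numerical and formatting choices

* Percentages round half-up (`decimal`-based) at the printed precision:
  one decimal for characteristics categories, two for reporting-year rows
  and the onset fraction.
* Age conversion to years: YR×1, DEC×10, MON÷12, WK÷52, DY÷365.25,
  HR÷8766; a value with an unknown unit is treated as years and counted in
  the run log.
* Age groups: <5; ≥5 and ≤18; >18; Unknown.
* Onset = event date − earliest therapy start date, in days; negative or
  unparseable onsets are excluded and counted. Default bins 0–30, 31–60,
  61–90, 91–180, 181–360, >360 days (configurable).
* A report with several outcome codes is characterized by its most serious
  (DE > LT > DS > CA > HO > OT).
* All randomness flows from a single integer seed through numpy's
  `default_rng`; fixed seed ⇒ byte-identical output files.

## Known limitations

The pipeline inherits every limitation of spontaneous-report
disproportionality: no denominators of exposure, reporting bias,
duplicate reports only partially removable, and signal ≠ causation. No
multiple-testing control is applied (none is conventional in this
four-criteria screening design). Stratified or regression-adjusted
disproportionality, the full MGPS mixture fit, FAERS XML ingestion and
pre-2004 legacy formats are out of scope.
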