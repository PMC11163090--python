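# Methods

This note records the models, conventions and design choices behind
`faers-signals`, in the spirit of a statistical software methods appendix.

## Data model and file handling

FAERS quarters are bundles of "$"-delimited ASCII tables with one header
row and no quoting or escape convention. The reader types the mandatory
columns (identifiers as strings, `caseversion`/`drug_seq` as nullable
integers, `YYYYMMDD` dates parsed strictly — impossible calendar dates
become missing with one aggregated warning per file), preserves unknown
columns verbatim, and treats an empty field as missing. Files are decoded
as UTF-8 with a latin-1 fallback (latin-1 accepts any byte sequence, so the
fallback can never fail). The writer emits the same dialect; because the
dialect cannot represent an embedded "$", offending characters are replaced
by a configurable substitute (default: removed) with a warning. Reading a
written bundle reproduces the typed representation field-for-field.

Deletion lists (the DELETED table) are applied on load: any `primaryid` on
the list is dropped from every table, idempotently. Case versioning is kept
intact at the I/O layer; collapsing versions is a cohort decision, which
keeps I/O lossless.

## Cohort construction

Cleaning runs in a fixed order, and every step's exclusion count is
recorded so `input = output + Σ exclusions` always holds:

1. **Deduplication** (two-stage, the default): within each `caseid` keep
   only the highest `caseversion`; then collapse reports identical on
   (caseid, event date, reaction PT set), keeping the largest `primaryid`;
   a residual same-case collapse guarantees one record per case even when
   duplicate copies disagree on a date. A `literal` mode is provided
   for sensitivity analysis: it drops only exact
   (primaryid, event date, PT set) duplicates and keeps all case versions
   (in that mode the cohort is keyed by `primaryid`, not `caseid`). The
   result is independent of the order in which quarters are supplied.
2. **Study window**: the report year is the event-date year when present,
   else the submission (FDA receipt) year; which source was used is kept
   per record. Records with neither date are excluded and tallied — the
   window is an inclusion criterion, so undatable reports cannot satisfy
   it. Default window: 2019–2021.
3. **Exposure**: only primary-suspect (PS) drug rows define exposure. Drug
   names and active ingredients are matched against the class dictionary
   after trimming, whitespace-collapsing and casefolding; matching is exact
   on the full name. The shipped dictionary covers the GLP-1 receptor
   agonist, DPP-4 inhibitor and SGLT2 inhibitor classes with US brand
   names (exenatide marked as the GLP-1 RA reference drug) and is
   user-overridable via a three-column TSV. A report whose PS drugs map to
   two classes counts for each class independently, mirroring the usual
   one-row-per-drug-event convention; such reports are tallied in the
   audit.
4. **Event flag**: exact normalized match of the target preferred term
   (substring matches such as "pancreatitis acute" for target
   "pancreatitis" do not count). An explicit term-list mode exists for
   users who want a broader definition; single-PT matching is deliberately
   the default because it is the most reproducible and its narrowness is a
   known, documented limitation of PT-level searches.

Ages are converted to years (MON/12, WK/52, DY/365.25, HR/8766); values
above 120 years are treated as unit errors and set missing. Age groups use
0–18, 19–30, 31–40, 41–50, 51–60, 61–70, >70.

## Disproportionality indices

**Comparator.** "All other reports" means every cohort report whose PS set
lacks the studied exposure — the full cleaned window, not just the studied
classes. Within-class drug comparisons restrict the 2×2 to reports exposed
to the studied drug or to the class reference drug.

**ROR and PRR** use the formulas in the README with z = 1.96 (95%
intervals throughout). When any cell is zero, 0.5 is added to all four
cells for both the estimate and the interval (Haldane–Anscombe), and the
result is flagged `correction_applied`. An all-zero table raises rather
than returning a number. The signal rule tests the ROR point estimate, as
the rule is conventionally stated; a switch applies it to the CI lower
bound instead for users who prefer that variant.

**EBGM.** The prior is DuMouchel's two-component gamma mixture
(shape/rate), fitted by maximizing the exact marginal log-likelihood — a
two-component negative-binomial mixture — summed over the whole drug×event
grid. The optimizer is L-BFGS-B on log-transformed shapes/rates and a
logit-transformed weight (clipped to (10⁻⁶, 1−10⁻⁶), so boundary starts
cannot crash), started from DuMouchel's published values
(α₁=0.2, β₁=0.1, α₂=2, β₂=4, p=1/3), tolerance 10⁻⁶, at most 500
iterations; non-convergence warns and is flagged, never silent. The
posterior for a pair is again a two-gamma mixture with components
Gamma(αₖ+n, βₖ+e), giving EBGM in closed form via digamma functions.
EB05/EB95 solve the mixture CDF with Brent's method inside a bracket formed
by the component quantiles, with a scale-aware absolute tolerance
(tol × the bracket scale) because lower quantiles at n = 0 can sit many
orders of magnitude below 1. An optional exact-weight aggregation of
identical (n, e-bin) pairs ("squashing") is available for very large grids
and is off by default.

**IC** uses the closed form log₂((n+0.5)/(e+0.5)) with credibility bounds
log₂ of the 2.5th/97.5th Gamma(n+0.5, e+0.5) percentiles — the standard
smoothed formulation. Expected counts are unstratified by default;
stratification by sex, age group and report year is available and sums
stratum-wise expectations.

**Signal rule.** ROR > 1 with n ≥ 2, PRR > 2 with n ≥ 3, EBGM ≥ 2 and
IC > 0 each with n ≥ 1; a pair is a signal only when all four hold. All
thresholds and minimum counts are configurable; the defaults are the
conventional ones. Raising any threshold can only remove signals.

**Reporting.** Percentages are rounded to one decimal and indices to two in
the report tables. Sex percentages use the sex-recorded denominator. A case
is "serious" if it carries at least one outcome code in
{DE, DS, HO, LT, RI, CA}; OT is excluded, and the seriousness definition is
echoed in the run manifest because published seriousness percentages are
notoriously sensitive to the denominator chosen.

## Synthetic data generator

The generator emulates exactly the statistical structure the analysis
assumes: pair counts are Poisson with mean N·w_drug·w_event·rr, where rr = 1
off the injected list, so the null grid satisfies row/column independence by
construction and each injected pair has a known multiplicative signal. Each
count becomes a case with one PS drug and one reaction PT (a multi-drug /
multi-PT mode exists to exercise multi-class logic), demographics
(sex ≈ 50/50, ages ≈ N(58, 15) years with a 5% share expressed in months,
US-heavy reporting countries), event dates uniform over the configured
years with a geometric submission lag, and outcome codes drawn
hospitalization-heavy. FAERS warts are layered on at configurable rates:
duplicate copies (same case, date and PTs under a new `primaryid`),
version re-submissions (incremented `caseversion`), and missing
sex/age/event-date fields. Everything derives from one mandatory seed, and
identical configurations produce byte-identical files.

Default margins are uniform with the injected pair's drug weight doubled,
which pins that pair's null expected count at ≈ 20 on the default
200×100 / N=200,000 grid (uniform margins would give ≈ 10); a seeded
symmetric Dirichlet draw is available for irregular margins. The default
scenario's years lie entirely inside the 2019–2021 window so the analyzed
grid size is the nominal N; the `stress` preset spans 2018–2022 with higher
duplicate/missingness rates to exercise the window filter and the audit.

What the generator does **not** emulate — and hence what green tests do not
establish about real FAERS: free-text drug-name noise (misspellings,
compounded products) beyond an optional case jitter, reporting-rate trends
over time, correlated missingness, true MedDRA hierarchies, or
polypharmacy exposure correlation. Recovery results on synthetic data
validate the estimators and the plumbing, not the epidemiology.

## Problem sizes used in the validation suite

The headline recovery study uses the default scenario above (≈ 200,000
cases, 20,000 grid pairs); hyperparameter recovery uses 50,000 simulated
pairs with expected counts log-uniform on [0.1, 100]; estimator calibration
averages the shrinkage estimate at the injected pair over 20 seeds at the
grid level; confidence-interval coverage uses 2,000 null multinomial
tables. These sizes make the stochastic checks stable at the tolerances
tested while keeping the whole suite's runtime modest.

## Known limitations

- Published class-level index values for the pancreatitis question are
  reproducible only from the real FAERS 2019–2021 quarters and are carried
  as frozen external reference rows; desk-scale runs validate the
  machinery, not those numbers, which are additionally sensitive to
  dictionary and deduplication choices.
- PT matching is literal; no MedDRA SMQ expansion.
- The EBGM here is the single-item (pairwise) shrinker; multi-item
  interaction scores and regression-adjusted IC are out of scope.
- Exact (Fisher-type) intervals, stratified/adjusted ROR and time-scan
  statistics are not implemented.
- Reports exposed to both the studied and the reference drug contribute to
  both arms of a within-class comparison.
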