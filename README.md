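# faers-signals

Disproportionality signal detection for spontaneous adverse-event reports in
the FAERS (FDA Adverse Event Reporting System) quarterly file format.

The package is written for pharmacovigilance analysts and biostatisticians
who want a tested, reproducible version of the standard signal-mining
workflow: read the "$"-delimited quarterly DEMO/DRUG/REAC/OUTC (+ DELETED)
tables, build a cleaned analysis cohort, score drug–event pairs with the
four canonical disproportionality indices, and apply a conservative
all-indices signal rule. A synthetic FAERS-like generator with known ground
truth makes the whole pipeline testable without downloading any data.

## The statistics

For one exposure (a drug or drug class) and one adverse-event preferred
term, reports are cross-classified into the 2×2 table with cells *a* (event
reports for the exposure), *b* (non-event reports for the exposure), *c*
(event reports for everything else) and *d* (the rest). The frequentist
indices are

- **ROR** = (a·d)/(b·c), with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)),
- **PRR** = [a/(a+b)] / [c/(c+d)], with the analogous log-normal CI,

with the Haldane–Anscombe +0.5 correction applied to all four cells when any
cell is zero. The Bayesian indices operate on the full drug×event grid with
expected counts e = (row total × column total)/grand total:

- **EBGM**: under DuMouchel's gamma–Poisson model, n | λ ~ Poisson(λe) with a
  two-component gamma mixture prior on λ whose five hyperparameters are
  fitted by maximizing the negative-binomial-mixture marginal likelihood
  over the grid; EBGM = 2^E[log₂ λ | n, e] with posterior quantiles
  EB05/EB95,
- **IC**: log₂((n+0.5)/(e+0.5)) with credibility bounds from the
  Gamma(n+0.5, e+0.5) posterior.

A pair is a **signal** only if ROR > 1 (n ≥ 2), PRR > 2 (n ≥ 3), EBGM ≥ 2
and IC > 0 (n ≥ 1) hold simultaneously.

## Worked example

Generate a small synthetic database with one planted signal (relative risk
10 for drug `DRUG_001` and event `EVENT_001`), build the cohort, fit the
shrinkage prior, and score every pair:

```python
import faers_signals as fs
from faers_signals.bayes import GammaPoissonShrinkage

config = fs.SyntheticConfig(seed=1, n_drugs=50, n_events=20, n_reports=20_000,
                            injected_signals=(("DRUG_001", "EVENT_001", 10.0),))
bundles, truth = fs.generate_database(config)
cohort, audit = fs.build_cohort(bundles, fs.FilterConfig(target_pt="EVENT_001"),
                                fs.default_class_map())
print("audit:", audit)

pairs = fs.pair_grid_from_cohort(cohort)
est = GammaPoissonShrinkage().fit(pairs["n"].to_numpy(), pairs["e"].to_numpy())
scores = fs.score_pair_grid(pairs, est.prior_)
top = scores.sort_values("ebgm", ascending=False).head(3)
print(top[["drug", "event", "n", "e", "ror", "prr", "ebgm", "ic", "is_signal"]]
      .round(2).to_string(index=False))
```

This prints:

```
audit: {'input_reports': 21102, 'version_collapsed': 406, 'duplicate_collapsed': 406,
 'missing_year_excluded': 0, 'out_of_window_excluded': 29, 'multi_class_reports': 0,
 'final_cohort': 20261}
    drug     event   n     e  ror  prr  ebgm   ic  is_signal
drug_001 event_001 392 79.06 9.37 6.48  4.96 2.30       True
drug_007 event_011  40 18.94 2.29 2.16  1.14 1.06      False
drug_009 event_009  34 19.62 1.83 1.76  1.09 0.78      False
```

The audit shows the cleaning arithmetic (21,102 raw report rows; 406
superseded case versions and 406 duplicate copies collapsed; 29 reports
outside the 2019–2021 window). The planted pair is the only one clearing all
four indices; the next-ranked pairs are ordinary Poisson noise and are
(correctly) not flagged. Note the indices at the planted pair understate the
true relative risk of 10 — a strong signal inflates its own drug and event
margins, so the margin-based expected count is biased upward; this is
intrinsic to disproportionality statistics, not an implementation artifact.

There is also a CLI for shell use — `faers-signals simulate | ingest |
cohort | signals | report` — each a thin wrapper over the functions above.

## Layout

| module | role |
|---|---|
| `faers_signals.io` | read/validate/write "$"-delimited quarterly tables, DELETED handling |
| `faers_signals.cohort` | deduplication, study-window filter, drug-class mapping, event flagging |
| `faers_signals.contingency` | 2×2 tables, ROR and PRR with CIs, within-class reference comparisons |
| `faers_signals.bayes` | expected counts, gamma–Poisson shrinkage (EBGM), information component |
| `faers_signals.triage` | four-index signal rule, report tables, end-to-end pipeline |
| `faers_signals.synthetic` | FAERS-schema generator with injected signals and ground truth |

See `docs/methods.md` for the modeling details, parameter defaults and known
limitations.
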