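# aquaqc

Quality control, analysis, and submission formatting for **discrete
surface-water monitoring data**.

Community and agency monitoring programs collect seasons of water-quality
measurements — dissolved oxygen, nutrients, bacteria, conductance — that are
only usable for regulatory assessment if they demonstrably meet a set of
*data-quality objectives* (DQOs): duplicate samples must agree, blanks must
read below detection thresholds, spiked samples must recover known
quantities, QC samples must be collected at a required frequency, and enough
of the data must remain usable (completeness). Preparing these QC reports by
hand is slow and error-prone. `aquaqc` automates the whole loop for small
monitoring programs: strict validation of tabular inputs, outlier screening,
DQO evaluation, summary views, and export of a submission workbook for the
USEPA Water Quality Exchange (WQX) — the pathway into the largest public
water-quality database in the United States.

## What it computes

* **Input validation** — the results table passes a fixed suite of fifteen
  named checks (column names, controlled activity-type and depth
  vocabularies, date formats, censoring tokens, one unit per parameter, ...).
  The first failing check aborts with the offending values and 1-based data
  row numbers, e.g. `Incorrect Activity Type found: Sample, Field in
  row(s) 4, 135`, so the spreadsheet can be fixed and re-imported.
* **Outlier screening** — within each month/week/year/site group, a value is
  a potential outlier when it falls outside
  `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, with quartiles interpolated between order
  statistics and log10 screening for parameters whose DQOs carry a `log`
  hint. Censored values substitute MDL/2 (below detection) or the UQL
  (above quantification). Flags are reported, never removed.
* **Accuracy QC** — each QC record gets a hit/miss verdict against its
  criterion: blanks compare the reading to a threshold (`BDL` is a hit; for
  a strict `<` threshold a value *equal* to it is a miss), duplicate pairs
  use the relative percent difference `RPD = 100·|a−b| / mean(a,b)` (or an
  absolute difference for non-percent DQOs), spikes and instrument checks
  use the percent deviation from the known quantity. Per-parameter
  acceptance is `round(100·(n − misses)/n)` with halves away from zero, or
  `-` where no QC records exist.
* **Frequency & completeness** — observed QC frequency per check type
  (`100·n_qc / n_regular`) against the required percent, and completeness
  `100·(n − n_qualified)/n` where qualified records carry a paired value in
  the *QC Reference Value* column.
* **WQX export** — a three-sheet workbook (`Project`, `Locations`,
  `Results`) with censored results exported as detection-condition text and
  same-row duplicate pairs expanded into paired activity rows.

## Worked example

The package ships a deterministic synthetic-bundle generator that emulates a
May–September monitoring season (six stations, eight parameters, QC
activities interleaved, censored values, and injected anomalies recorded in
a ground-truth sidecar):

```python
import aquaqc as aq

bundle, truth = aq.generate_bundle(aq.FixtureSpec(seed=42))
table, outcomes = aq.read_results(bundle.results, verbose=True)
```

```
Running checks on results data...
Checking column names... OK
Checking all required columns are present... OK
Checking valid Activity Types... OK
...
Checking acceptable units for each entry in Characteristic Name... OK
All checks passed!
```

```python
summary = aq.tab_accuracy(bundle, "summary")
print(summary[summary["Parameter"].isin(["Ammonia", "TP"])].to_string(index=False))
```

```
                          Type Parameter  Number of QC Checks  Number of Misses % Acceptance
              Field Duplicates   Ammonia                    8                 1          88%
              Field Duplicates        TP                    8                 0         100%
                Lab Duplicates   Ammonia                   11                 0         100%
                Lab Duplicates        TP                   11                 0         100%
                  Field Blanks   Ammonia                   11                 0         100%
                  Field Blanks        TP                   11                 1          91%
                    Lab Blanks   Ammonia                   11                 1          91%
                    Lab Blanks        TP                   11                 0         100%
Lab Spikes / Instrument Checks   Ammonia                   11                 0         100%
Lab Spikes / Instrument Checks        TP                   11                 0         100%
```

Each row tallies one QC check type for one parameter: eleven TP field blanks
were evaluated, one missed its 0.01 mg/l threshold, so TP field blanks sit
at 91% acceptance. The three misses in this dataset are exactly the
anomalies the generator injected (`truth["qc_misses"]`).

```python
print(aq.detect_outliers(bundle, "DO", group="month").to_string(index=False))
```

```
Monitoring Location ID Activity Start Date Activity Start Time Characteristic Name Result Value Result Unit
               SYN-005          2022-05-29               06:30                  DO         27.6        mg/l
               SYN-005          2022-09-18               06:30                  DO         27.6        mg/l
```

Both flagged observations are the two extreme dissolved-oxygen values the
generator planted (`truth["outliers"]`), recovered exactly by the month-wise
1.5×IQR rule.

The same operations are available from the shell:

```sh
aquaqc fixture -o fx --seed 42
aquaqc validate fx/results.csv --acc fx/accuracy.csv --frecom fx/frecom.csv
aquaqc outliers fx/results.csv --acc fx/accuracy.csv --param DO --group month
aquaqc qc-report fx/results.csv --acc fx/accuracy.csv --frecom fx/frecom.csv -o report
aquaqc wqx fx/results.csv --acc fx/accuracy.csv --sites fx/sites.csv --wqx fx/wqx.csv -o .
```

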