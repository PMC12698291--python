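# sarclink

Signature-based **indirect record linkage** between a clinical registry (the
*source*) and a large administrative claims database (the *target*) when no
shared patient identifier exists — the situation of a national sarcoma
registry being enriched with reimbursement data to reconstruct complete care
pathways. The package is aimed at epidemiologists and data engineers who
need a deterministic, auditable linkage with explicit confidence metrics,
plus a synthetic-data simulator with planted ground truth so the whole
pipeline can be validated end to end.

## The method

Each record carries a set of *chaining variables* — non-directly-identifying
attributes present in both systems, at several granularities: `S` (sex +
birth month/year) and its coarsening `s` (sex + birth year), `D` (death
date), `L` (town of residency) and `l` (department), `C` (tumor type
anchored at the surgery date), `F` (surgery facility), `R` (resection date),
`M` (micro-biopsy date), `O` (surgery date vs hospital-stay start). Date
comparisons use per-variable tolerance windows, directional where the
systems are known to differ (the stay start precedes the surgery date).

For a candidate (source, target) pair, the *signature* S is the set of
chaining variables defined on both sides that agree, rendered as a ten-slot
string such as `Ss.LlC.R..`. The pipeline has three steps:

1. **Chaining.** For every source record, candidates are targets with no
   disagreeing co-defined variable and at least one agreeing event date;
   they are ranked by signature size |S|. Exactly one maximal candidate →
   a *unique* pair; ties → *ambiguous*; otherwise *no candidate*.
2. **Disambiguation.** Ambiguities whose signature has |S| ≥ 5 and at most
   2 source-side missing variables are re-examined with *checking
   variables* (`d` diagnosis-code mapping, `e`/`c`/`r` treatment
   indications followed through within a window); the ambiguity resolves
   iff exactly one candidate scores a hit.
3. **Elimination.** Whole signature groups judged unsafe (no demographics,
   no residency, or small signatures with heavy missingness) are removed
   together; the definitive matching rate = retained pairs / source records.

Two metrics grade every retained pair:

* **Robustness** R — the largest k such that removing *any* k variables
  from the signature leaves the pair uniquely linked (exact subset
  enumeration; R = 0 means one variable is indispensable).
* **Quality** Q ∈ [0, 7] — folds R, |S| and the number of checking hits
  into one scale comparable across signature classes (base 1–5 from R and
  |S|, exclusive bonus +1/+2 for 2 / ≥3 checking hits; pairs resolved only
  by checking variables keep Q = 0).

## Worked example

```python
import sarclink as sl

cfg = sl.SimulationConfig(n_source=500, n_target=10_000, seed=42)
source, target, truth = sl.generate(cfg)

result = sl.run_linkage(source, target)
print(result.definitive_matching_rate)        # 86.8
report = sl.evaluate(result, truth)
print(report.precision, round(report.recall, 3))   # 1.0 0.868

print(sl.signature_frequency_table(result.pairs, result.book).head())
```

```
 signature   n  r_min  r_median  r_max  cumulative_share
Ss.LlC.RMO 128      1       3.0      3          0.294931
SsDLlC.RMO  46      1       3.0      4          0.400922
Ss.LlC..MO  44      0       2.0      2          0.502304
Ss.LlC.R.O  35      0       2.0      2          0.582949
Ss.Ll..RM.  33      1       1.0      1          0.658986
```

Of 500 source records, 434 end up in retained pairs (definitive matching
rate 86.8%), 1 has no candidate, 1 stays ambiguous and 64 are removed by
the safety rules; every retained pair is correct (precision 1.0) and the
ones lost to elimination or left unresolved account for the 13.2% recall
gap. The most frequent signature, `Ss.LlC.RMO`, pairs on demographics,
residency and three event dates and is robust to dropping three variables.

The same pipeline is available from the shell:

```bash
sarclink simulate --out sim --seed 42
sarclink link --source sim/source.csv --target sim/target.csv --out run
sarclink evaluate --run-dir run --source sim/source.csv \
         --target sim/target.csv --truth sim/truth.csv --out eval
```

## Layout

- `src/sarclink/book.py` — linkage management book (variables, tolerances,
  thresholds) as validated YAML configuration
- `records.py`, `index.py` — normalized record stores, missingness reports,
  inverted candidate index
- `signatures.py`, `engine.py`, `checking.py`, `elimination.py` — the three
  pipeline steps
- `metrics.py` — robustness and quality
- `simulate.py` — synthetic registry generator with planted truth
- `evaluate.py` — truth-based scoring and report tables
- `cli.py` — `sarclink simulate | link | evaluate | report`

See `docs/methods.md` for the modelling choices, defaults and limitations.
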