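# Methods

## The linkage model

The engine performs deterministic, signature-based indirect record linkage.
Conceptually it explores the Cartesian product of the source registry and
the target database: for each source record it looks for the target record
with the same combination of chaining variables, or the closest defined
sub-combination. The inverted candidate index is purely an engineering
device — retrieval through it is provably equivalent to the exhaustive scan
(tested against a brute-force reference), because a target can only be a
candidate if at least one of its event-date postings falls inside one of
the source record's tolerance windows.

Candidacy requires three things, all configurable:

* **zero conflicts** (default): no chaining variable defined on both sides
  may disagree. The `max_conflicts` knob relaxes this; deterministic
  linkage convention keeps it at 0.
* **at least one agreeing event-date variable** (`D`, `C`, `F`, `R`, `M`,
  `O`). Dates are the workhorse discriminators: demographic variables split
  the population into large groups, while an event date narrows candidates
  to a handful. Requiring one prevents pairs built on demographics alone.
* **maximal signature cardinality**: candidates are ranked by the number of
  agreeing variables, with no per-variable weighting. Weighting schemes
  (Fellegi–Sunter style) are deliberately out of scope; cardinality plus
  the event-date requirement operationalizes "closest subpart", and ties
  are never broken arbitrarily — they are genuine ambiguity.

### Date semantics

Dates are handled at day precision; the birth date is compared as
(year, month) for `S` and year for `s`. Each date-bearing variable has a
tolerance window and direction:

| variable | window | direction | reason |
|---|---|---|---|
| `O`, `C`, `F` | 30 d | target ≤ source | the claims side stores the stay start, which precedes the surgery |
| `D` | 90 d | symmetric | death reaches either system with delay (last-contact + vital status on the registry side) |
| `R`, `M` | 14 d | symmetric | sampling act vs result-production dates |

The magnitudes are engineering defaults (the direction is dictated by how
the systems record events, the widths are not); all are overridable in the
linkage book.

### Granularity hierarchy

`s` is a projection of `S` and `l` of `L`. At load time the department is
always derived from the town prefix when the town is defined (overwriting
an inconsistent department column), so `L` agreement implies `l` agreement
on every record pair — a structural invariant the elimination rules rely
on. Whether a real system would trust the recorded department over the
derived one is an open question; deriving is the conservative choice.

### Step 2 — checking variables

Checking variables are too noisy for primary chaining (planned treatments
are not always carried out; diagnosis coding of rare tumors is unreliable)
but informative enough to separate two tied candidates. The eligibility
rule — signature of at least 5 variables and at most 2 missing — is read
with missingness counted on the **source side only**: counting both sides
against a 10-slot alphabet would make "≥ 5 present and ≤ 2 missing"
near-contradictory, while the source-side reading keeps both constraints
active. Event-window comparators accept the target event from 0 to
`window_days` (default 180) **after** the indication date. Resolution
requires exactly one candidate with ≥ 1 hit and all others with none; a
single pass, no re-chaining afterwards.

### Step 3 — elimination

Five shipped rules remove whole signature groups: no `S` and no `s`; no
`L` and no `l`; one of `S`/`s` absent with ≥ 2 missing and size < 6; `L`
absent with ≥ 2 missing and size < 8; one of `L`/`l` absent with ≥ 2
missing and size < 6. "Missing" again counts source-side undefined
variables, consistent with the Step-2 rule. The group key is (present set,
source-missing count): elimination never looks at an individual pair's
attributes, so pairs with identical signatures share fate and the filter is
idempotent. Rules are data and can be replaced wholesale.

### Robustness

R is computed by exact subset enumeration: for k = 1, 2, … every k-subset
of the signature is removed and uniqueness re-tested; R is the largest k
for which *every* k-subset survives (equivalently, one less than the size
of the smallest breaking set). Removing a source variable erases both its
agreements and its conflicts, so previously conflicting targets can re-enter
the pool — the enumeration works on precomputed agreement/conflict bitmasks
over the full event-sharing pool, which makes the ≤ 2¹⁰ re-tests cheap. R
is undefined for pairs that were unique only after Step 2 (their chaining
signature alone was ambiguous); computing R conditional on the checking hit
would be a different metric and is not attempted.

### Quality

Base Q: R = 0 → 1 (size ≤ 4) or 2 (size > 4); R = 1 → 3 (size ≤ 5) or 4
(size > 5); R ≥ 2 → 5; undefined R → 0. For base Q ≥ 2 exactly one bonus
applies: +2 for ≥ 3 checking hits, else +1 for exactly 2. Making the
bonuses exclusive (rather than cumulative) keeps the scale's maximum at 7;
a cumulative reading would reach 8. "Checking variables present" is read
as *matched hits*, not merely defined fields — the checking codes only
exist as match outcomes. Assigning Q = 0 to the undefined-robustness pairs
is the package's reading of how a non-empty lowest class arises; it is an
assumption, flagged as such.

## The synthetic generator

The generator emulates a registry of three overlapping subsets (defaults
40.3% in both bases, 17.4% clinical-only, 42.3% pathological-only) inside a
target of cancer-surgery-like background records. Defaults are the study
conditions: per-variable, per-subset missingness patterned on the observed
registry rates (town 7.59% clinical / 15.45% pathological, department
4.53% / 12.13%, facility 78.9% clinical and absent pathological, surgery
date 0.88% clinical / 30% pathological-only, …), stay-start delay
geometric with mean ≈ 3 days, death/sampling dates shifted uniformly within
their windows, decoy rate 0.05.

Choices the data do not dictate, made once:

* demographics — sex Bernoulli(0.5), birth dates uniform over 80 years,
  towns Zipf-distributed over a 400-town gazetteer whose department is the
  code prefix (giving a realistic `L`/`l` hierarchy), 60 facilities;
* decoys clone the counterpart's demographic slots *and* its surgery stay
  (`S`, `s`, `L`, `l`, `C`, `O` by default) while differing on facility,
  sampling dates and death. Sharing an event anchor is what lets a decoy
  enter the candidate pool at all — a purely demographic near-duplicate is
  never a candidate (no event agreement) and would exert no pressure on the
  disambiguation step;
* checking structure: 35% of source records carry each treatment
  indication, followed through in the counterpart's pathway 80% of the
  time; the stay's diagnosis code maps consistently to the tumor type/site
  90% of the time, through a 20-row toy mapping table (the real-world
  2000-entry table is out of scope);
* department missingness is nested inside town missingness (the coarse
  level can only be unknown when the fine one is), with the conditional
  rate chosen to preserve the configured marginals; missingness is
  otherwise independent across variables and of subset membership beyond
  the per-subset marginal rates.

Every mask and every non-zero jitter applied to a planted pair is written
to a corruption log; a property test verifies that each disagreement
between a planted pair's two records is explained by a logged entry on one
of that variable's underlying columns.

What the generator does **not** emulate: real coding systems (CCAM/ICD
dictionaries beyond the toy map), correlation between missingness and
unobserved patient characteristics, duplicate source records, and target
records for source patients who were never treated (every source record has
a counterpart — so synthetic recall measures pipeline losses, not coverage
gaps). Passing tests therefore demonstrate the engine's correctness and the
metrics' behaviour under controlled corruption, not real-world match rates.

## Numerical and reporting conventions

* Percentages are rounded half-up (matching rates to 1 dp, missingness to
  2 dp); undefined ratios are reported as NA/null, never 0.
* All simulation randomness flows from a single integer seed through one
  `numpy` generator; identical seed + configuration reproduces every output
  byte for byte (summaries carry no timestamps — the run manifest does).
* Rows with invalid calendar dates are quarantined with their row number
  and linkage proceeds on clean rows; an empty string, `NA` or `UNK` is a
  missing value.
* Many-sources-to-one-target collisions are counted and reported; the
  optional strict one-to-one mode demotes all colliding pairs back to
  ambiguity instead.
* Problem sizes used by the shipped checks: the default synthetic scenario
  links 2 000 source records against 50 000 targets (a scaled-down version
  of the registry-vs-claims size ratio that keeps a full run in seconds);
  oracle-equivalence suites use 100 high-collision instances of up to
  20×160 records where exhaustive Cartesian scans are cheap.

## Known limitations

* Slot semantics for `F`, `R`, `M`, `O` (which care-pathway date attaches
  to which letter) follow the package's default book and are configurable;
  other deployments may bind them differently.
* The elimination rule thresholds (notably "size < 8" for the `L`-absent
  rule) are taken as given; they originate from expert review of doubtful
  care pathways, not from an optimization the package could reproduce.
* Robustness enumeration is exact but exponential in signature size; it is
  intended for alphabets of ~10–20 slots, not hundreds.
* Precision/recall are measurable only on synthetic data; on real data the
  package can report matching rates, signature tables and metric
  distributions, but no error rates.
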