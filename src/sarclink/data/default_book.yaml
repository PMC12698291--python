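# Default linkage management book.
#
# Ten chaining slots "SsDLlCFRMO" (slot order = rendering order) built from
# six base variables available in both record systems: sex, month/year of
# birth, death date, residency code (town or department), the facility where
# surgery was performed, and the event dates of the care pathway (surgery,
# tumor resection, micro-biopsy sampling).  Upper/lower case letters carry
# the same base variable at fine/coarse granularity.
#
# Date tolerances absorb known discrepancies between the systems:
#  * the administrative side stores the start of the hospital stay, which
#    precedes the surgery itself -> target_not_after_source, 30 days;
#  * the death date may be recorded with delay on either side -> symmetric
#    90 days;
#  * sampling / resection dates may refer to the act or to the production of
#    the result -> symmetric 14 days.
# All values here are overridable; this file is data, not code.
chaining:
- code: S
  description: sex with month and year of birth
  kind: categorical
  source_fields: [sex, birth_date]
  target_fields: [sex, birth_date]
  transforms:
    birth_date: year_month
- code: s
  description: sex with year of birth (coarsening of S)
  kind: categorical
  source_fields: [sex, birth_date]
  target_fields: [sex, birth_date]
  coarsening_of: S
  transforms:
    birth_date: year
- code: D
  description: death date
  kind: date
  source_fields: [death_date]
  target_fields: [death_date]
  tolerance_days: 90
  tolerance_direction: symmetric
- code: L
  description: town-of-residency code
  kind: categorical
  source_fields: [town_code]
  target_fields: [town_code]
- code: l
  description: department-of-residency code (coarsening of L; derived as town prefix)
  kind: categorical
  source_fields: [dept_code]
  target_fields: [dept_code]
  coarsening_of: L
  derive:
    field: town_code
    transform: prefix2
- code: C
  description: tumor type anchored at the surgery date
  kind: categorical_at_date
  source_fields: [tumor_type, surgery_date]
  target_fields: [tumor_type, stay_start_date]
  tolerance_days: 30
  tolerance_direction: target_not_after_source
- code: F
  description: care-facility code anchored at the surgery date
  kind: categorical_at_date
  source_fields: [facility_code, surgery_date]
  target_fields: [facility_code, stay_start_date]
  tolerance_days: 30
  tolerance_direction: target_not_after_source
- code: R
  description: tumor-resection date
  kind: date
  source_fields: [resection_date]
  target_fields: [resection_date]
  tolerance_days: 14
  tolerance_direction: symmetric
- code: M
  description: micro-biopsy / sampling date
  kind: date
  source_fields: [biopsy_date]
  target_fields: [biopsy_date]
  tolerance_days: 14
  tolerance_direction: symmetric
- code: O
  description: surgery (operation) date vs hospital-stay start
  kind: date
  source_fields: [surgery_date]
  target_fields: [stay_start_date]
  tolerance_days: 30
  tolerance_direction: target_not_after_source
# Checking variables: used only to separate candidates left ambiguous by the
# chaining step, never as chaining variables themselves (they would bring too
# many false positives as primary evidence).
checking:
- code: d
  description: diagnosis code of the surgery stay maps to the tumor type/site
  comparator: code_mapping_agreement
  source_fields: [tumor_type, tumor_site]
  target_fields: [icd10_code]
  mapping_table: packaged:icd10_toy_map.csv
- code: e
  description: tumor-reexcision indication followed by a reexcision stay
  comparator: event_within_window
  source_fields: [reexcision_indication_date]
  target_fields: [reexcision_date]
  window_days: 180
- code: c
  description: chemotherapy indication followed by a chemotherapy session
  comparator: event_within_window
  source_fields: [chemo_indication_date]
  target_fields: [chemo_date]
  window_days: 180
- code: r
  description: radiotherapy indication followed by a radiotherapy session
  comparator: event_within_window
  source_fields: [radio_indication_date]
  target_fields: [radio_date]
  window_days: 180
# Eligibility thresholds for the disambiguation step: the chaining signature
# must contain at least five variables and have no more than two variables
# missing on the source side.
step2:
  min_signature: 5
  max_missing: 2
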