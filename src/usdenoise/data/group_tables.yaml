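# Printed summary tables of the two nursing groups (50 patients each):
# per-complication patient counts, nursing-satisfaction percentages and
# (mean, sd) pairs for the continuous perioperative outcomes.
#
# Note on operation_time_min: the source abstract prints "55.45 +/- 6.13
# days" for the experimental group while the results section prints
# "55.45 +/- 16.13 minutes"; this fixture transcribes the results
# section.  Satisfaction is ingested as percentages (the printed form;
# some values imply non-integer counts at n = 50).
groups:
  control:
    label: control
    n: 50
    complication_counts:
      bleeding: 2
      subcutaneous_emphysema: 0
      pain: 1
      nausea_vomiting: 1
      infection: 1
      high_fever: 2
      abdominal_distension: 1
      back_soreness: 0
    satisfaction:
      very_satisfied: 69
      satisfied: 24
      dissatisfied: 7
    satisfaction_as_percent: true
    continuous_outcomes:
      operation_time_min: [60.83, 17.62]
      intraoperative_blood_loss_ml: [78.54, 10.02]
      postoperative_exhaust_time_days: [2.3, 0.84]
      time_out_of_bed_days: [1.7, 0.91]
      hospital_stay_days: [9.5, 2.8]
      age_years: [29.56, 3.78]
      weight_kg: [63.82, 8.03]
      height_cm: [162.88, 5.06]
      cyst_diameter_mm: [68.731, 6.76]
      disease_course_months: [9.2, 1.5]
  experimental:
    label: experimental
    n: 50
    complication_counts:
      bleeding: 1
      subcutaneous_emphysema: 0
      pain: 1
      nausea_vomiting: 0
      infection: 0
      high_fever: 1
      abdominal_distension: 0
      back_soreness: 1
    satisfaction:
      very_satisfied: 76
      satisfied: 22
      dissatisfied: 2
    satisfaction_as_percent: true
    continuous_outcomes:
      operation_time_min: [55.45, 16.13]
      intraoperative_blood_loss_ml: [71.52, 9.87]
      postoperative_exhaust_time_days: [1.9, 0.73]
      time_out_of_bed_days: [1.2, 0.85]
      hospital_stay_days: [7.3, 2.6]
      age_years: [29.37, 4.12]
      weight_kg: [62.57, 7.45]
      height_cm: [161.33, 5.41]
      cyst_diameter_mm: [69.34, 7.28]
      disease_course_months: [9.3, 1.7]
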