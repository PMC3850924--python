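"""Train a kNN model and assess one query subject individually.

The model represents each training subject by the average 30-bin amplitude
histogram of its reflex-window EMG (sites 9 and 10, four repetitions each).
A query subject's signals are classified one by one against the k = 5
nearest training profiles; the mean per-signal patient probability l_q^p
is the individual assessment, with >= 50% classifying as patient.
"""

from nwrpredict import (
    ClassSignalParams,
    CohortSpec,
    generate_cohort,
    predict_subject,
    train_model,
)

cohort = generate_cohort(
    CohortSpec(n_per_cell=6, sites=(9, 10), seed=1),  # 48 subjects
    ClassSignalParams(informative_sites=(9, 10), effect_size=2.5),
)
subjects = list(cohort)
healthy = [s for s in subjects if s.group == "h"]
patients = [s for s in subjects if s.group == "p"]

model = train_model(healthy[:20] + patients[:20], site_ids=(9, 10), k=5)
print(f"trained on {len(model.profiles)} subjects, sites {model.site_ids}, "
      f"k={model.k}, {model.n_bins} bins over "
      f"rg=({model.range_spec.restricted_range[0]:.3f}, "
      f"{model.range_spec.restricted_range[1]:.3f})")

query = patients[20]  # held out
pred = predict_subject(query, model)
print(f"\nquery {query.subject_id} (true group: {query.group}):")
for a in pred.signal_assessments:
    print(f"  site {a.site_id} rep {a.repetition}: l_qj^p = {a.prob_patient:5.1f}%"
          f"  -> {a.label}")
print(f"individual assessment l_q^p = {pred.prob_patient:.1f}% "
      f"-> classified {'patient' if pred.predicted_label == 'p' else 'healthy'}")
print("(l_q^p is the mean of the per-signal kNN vote percentages; it doubles "
      "as the confidence of the call)")
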