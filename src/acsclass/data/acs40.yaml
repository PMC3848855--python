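# Default 40-feature acute coronary syndrome admission schema.
# Categorical features carry their integer coding; continuous ("ratio")
# features are min-max rescaled to [-1, 1] before modelling.
n_classes: 4
class_names: [STEMI, NSTEMI, UA, Other]
features:
  - {label: 1, name: Sex, scale: nominal, codes: [1, 2]}
  - {label: 2, name: Age, scale: ratio, range: [-1, 1]}
  - {label: 3, name: Living place, scale: nominal, codes: [1, 2]}
  - {label: 4, name: Body Mass Index, scale: ratio, range: [-1, 1]}
  - {label: 5, name: History of prior myocardial infarction, scale: nominal, codes: [1, 2]}
  - {label: 6, name: History of prior angina pectoris, scale: nominal, codes: [1, 2]}
  - {label: 7, name: History of congestive heart failure, scale: nominal, codes: [1, 2]}
  - {label: 8, name: History of stroke, scale: nominal, codes: [1, 2]}
  - {label: 9, name: History of chronic renal failure, scale: nominal, codes: [1, 2]}
  - {label: 10, name: History of chronic lung disease, scale: nominal, codes: [1, 2]}
  - {label: 11, name: Prior PCI, scale: nominal, codes: [1, 2]}
  - {label: 12, name: Prior CABG, scale: nominal, codes: [1, 2]}
  - {label: 13, name: Smoking status, scale: ordinal, codes: [1, 2, 3]}
  - {label: 14, name: Diabetes mellitus, scale: ordinal, codes: [1, 2, 3, 4, 5, 6]}
  - {label: 15, name: History of hypertension, scale: nominal, codes: [1, 2]}
  - {label: 16, name: History of hypercholesterolemia, scale: nominal, codes: [1, 2]}
  - {label: 17, name: Family history of CAD, scale: nominal, codes: [1, 2]}
  - {label: 18, name: "Chronic Home MEDs: Aspirin", scale: nominal, codes: [1, 2]}
  - {label: 19, name: "Chronic Home MEDs: Other antiplatelet", scale: ordinal, codes: [1, 2, 3, 4]}
  - {label: 20, name: "Chronic Home MEDs: Anticoagulants", scale: nominal, codes: [1, 2]}
  - {label: 21, name: "Chronic Home MEDs: Beta-blockers", scale: nominal, codes: [1, 2]}
  - {label: 22, name: "Chronic Home MEDs: ACE inhibitors", scale: nominal, codes: [1, 2]}
  - {label: 23, name: "Chronic Home MEDs: Angiotensin II RB", scale: nominal, codes: [1, 2]}
  - {label: 24, name: "Chronic Home MEDs: Statins", scale: nominal, codes: [1, 2]}
  - {label: 25, name: "Chronic Home MEDs: Non-statin lipid low. Agents", scale: ordinal, codes: [1, 2, 3, 4]}
  - {label: 26, name: "Chronic Home MEDs: Calcium channel blockers", scale: nominal, codes: [1, 2]}
  # The source registry form lists two identically named calcium-channel-blocker
  # entries; the second keeps its own label with a disambiguating suffix.
  - {label: 27, name: "Chronic Home MEDs: Calcium channel blockers (2)", scale: nominal, codes: [1, 2]}
  - {label: 28, name: Predominantly presenting symptom, scale: ordinal, codes: [1, 2, 3, 4, 5, 6, 7]}
  - {label: 29, name: Heart rate, scale: ratio, range: [-1, 1]}
  - {label: 30, name: Systolic blood pressure, scale: ratio, range: [-1, 1]}
  - {label: 31, name: Troponin I elevated, scale: nominal, codes: [-1, 1]}
  - {label: 32, name: CKMB mass elevated, scale: nominal, codes: [-1, 1]}
  - {label: 33, name: Total Cholesterol value, scale: ratio, range: [-1, 1]}
  - {label: 34, name: Serum creatinine value, scale: ratio, range: [-1, 1]}
  - {label: 35, name: Glucose value, scale: ratio, range: [-1, 1]}
  - {label: 36, name: Hemoglobin value, scale: ratio, range: [-1, 1]}
  - {label: 37, name: Killip class, scale: ordinal, codes: [1, 2, 3, 4]}
  - {label: 38, name: ECG rhythm, scale: ordinal, codes: [1, 2, 3, 4]}
  - {label: 39, name: ECG QRS annotation, scale: ordinal, codes: [1, 2, 3, 4]}
  - {label: 40, name: ECG STT changes, scale: ordinal, codes: [1, 2, 3, 4]}
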