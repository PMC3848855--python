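"""The full study pipeline end to end, at smoke scale.

Generates a small registry, selects features, evaluates a roster of
classifiers and prints the plain-text report. Equivalent to
``acsclass run-all --profile smoke`` on the command line.
"""

from acsclass import default_schema, format_report, run_pipeline, smoke_config

report = run_pipeline(smoke_config(seed=0, n=250, reps=15))
print(format_report(report, default_schema().class_names))
# The per-classifier accuracy table is the headline; the APM/CPM blocks
# below it break accuracy down per class and per call.
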