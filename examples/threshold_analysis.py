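"""Full dose-response threshold analysis of three simulated environments.

Simulates urban-park (UP), remnant-forest (RF) and wetland-park (WP) cohorts
whose ground-truth recovery midpoints are ordered UP < WP < RF, runs the
complete chain (filtering, blink removal, amplitude rejection, 30-s band
powers, group aggregation, spline fit, threshold detection, AUC) and prints
the report in the index-by-environment layout.
"""

import warnings

from greendose import results_wide_table
from greendose.pipeline import PipelineConfig, analyze_specs, three_environment_specs

warnings.filterwarnings("ignore")

specs = three_environment_specs(n_participants=6, seed=1)
out = analyze_specs(specs, PipelineConfig(seed=1))

print(results_wide_table(out["results"]).round(2).to_string())
print()
print("ET_min/BT_min are minutes of exposure; AUC is the signed area of the "
      "baseline-subtracted index (negative when the index stays below its "
      "stressed level, as for relative beta). The urban park, whose simulated "
      "recovery midpoint is earliest, reaches both thresholds first.")
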