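"""Score a simulated 10-day IVT-mRNA degradation time course.

Generates triplicate synthetic gels (ladder + blank lane + control + four
incubation time points), calibrates molecular weight from the ladder, and
prints the per-lane quantification: peak-zone and degradation-zone AUCs,
the dominant product size, and raw/normalized preservation scores. The
preservation score falls from 1 (control, by definition) toward 0 as
signal mass moves from the product band into the low-molecular-weight
smear.
"""

import numpy as np

from gelflq import (
    ExperimentSpec,
    ScoringOptions,
    background_from_lanes,
    detect_ladder_bands,
    fit_exponential_calibration,
    score_run,
    subtract_background,
    synth_experiment,
)
from gelflq.synthetic import DEFAULT_LADDER_SIZES

spec = ExperimentSpec(base_seed=1)
runs, truth = synth_experiment(spec)

print(f"{'gel':16s} {'lane':8s} {'peak AUC':>10s} {'deg AUC':>10s} "
      f"{'size (nt)':>10s} {'P raw':>7s} {'P norm':>7s}")
for run in runs:
    background = background_from_lanes(run.background_lanes)
    ladder = subtract_background(run.ladder, background)
    bands = detect_ladder_bands(ladder, n_bands=len(DEFAULT_LADDER_SIZES))
    cal = fit_exponential_calibration(bands, DEFAULT_LADDER_SIZES)
    for r in score_run(run, cal=cal, options=ScoringOptions(background=background)):
        print(f"{run.gel_id:16s} {r.condition:8s} {r.peak_aucs[0]:10.0f} "
              f"{r.degradation_aucs[0]:10.0f} {r.mw_max:10.1f} "
              f"{r.preservation_raw:7.3f} {r.preservation_norm:7.3f}")

print("\nPeak AUC shrinks and the degradation AUC grows with incubation time;")
print("the dominant product size collapses from ~2.1 knt to ~0.6 knt by day 7.")
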