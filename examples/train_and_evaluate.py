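"""Train the three heads on one cohort and compare censoring-aware metrics.

Runs a scaled-down early-event scenario end to end: binary classifier (BC),
discrete-time network (DTNN) and deep Cox model (DCPH) share one encoder
architecture and one test split; the script prints time-indexed AUC,
regular AUC, Harrell's C and the censoring concordance with bootstrap CIs.
Time-indexed AUC excludes patients censored before the evaluation age;
regular AUC calls every non-diagnosed patient a negative, which is the
construction that rewards models for tracking follow-up length.
"""
import dataclasses

import censorbench as cb
from censorbench.config import FilterSpec
from censorbench.pipeline import ModelSetup

sc = cb.rom_like_scenario(n_patients=3000, seed=0)
sc = dataclasses.replace(sc, eval_times=(1.0,), n_boot=50)
base = FilterSpec(prediction_age_cutoff=sc.prediction_age_cutoff, yob_max=sc.yob_max)
setups = [
    ModelSetup("BC", base, "BC"),
    ModelSetup("DTNN", base, "DTNN"),
    ModelSetup("DCPH", base, "DCPH"),
]
report = cb.run_scenario(sc, setups=setups)

m = report.metrics
for metric in ("auc_t", "regular_auc", "harrell_c", "censoring_concordance"):
    print(f"\n{metric}:")
    for _, row in m[m.metric == metric].iterrows():
        t = "" if row.eval_time != row.eval_time else f" @ t={row.eval_time:g}"
        print(
            f"  {row.model:5s}{t}: {row.point:.3f} "
            f"(95% CI {row.ci_low:.3f}-{row.ci_high:.3f})"
        )
print(
    "\ncensoring_concordance ~0.5 means predictions carry no information\n"
    "about follow-up length; values above 0.5 flag the dependence that\n"
    "makes a classifier unsafe under heavier censoring."
)
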