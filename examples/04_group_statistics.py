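"""Run the full two-arm experiment and print the recovered effect sizes.

Executes simulate -> segment -> quantify -> stats on 8 control + 8 cKO
synthetic animals and shows the per-region percent reductions with their
delta-method SEMs, the two-way ANOVA, and the replicated ELISA comparison.
"""

from lamplaq import RunConfig
from lamplaq.pipeline import run_pipeline

cfg = RunConfig(master_seed=1)
res = run_pipeline(cfg, write_outputs=False)

print("Percent reduction of plaque area fraction (cKO vs control):")
print(res.reductions.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print("\nPlanted values: 75 % in CA1-SP, 50 % in each DG lamina; aggregates "
      "calibrated to ~31 % (hippocampus), ~24 % (CA1), ~50 % (DG).")

print("\nTwo-way ANOVA (arm x region) on the lamina table:")
print(res.anova.to_string(index=False))

print("\nSoluble Ab42 comparison (12 vs 12, one draw):")
print(res.elisa_reduction.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nEstimates sit within about two SEM of the planted effects; the arm "
      "main effect and the arm-by-region interaction are both clearly "
      "detected at this cohort size.")
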