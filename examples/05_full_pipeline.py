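"""End-to-end run: simulate a cohort, process both sessions, write artifacts.

Produces the per-group/session laterality table (both the two-group and the
three-group views), the cohort statistics, grand-average time courses and a
reproducibility manifest in an output directory.
"""

from pathlib import Path

from nirstress import PipelineConfig, run_pipeline
from nirstress.laterality import lis_table

out = Path("scratch/pipeline_run")
cfg = PipelineConfig(n_per_group=11, seed=42)
res = run_pipeline(cfg, out)

print("three-group laterality:")
print(lis_table(res.lis_three_group).to_string(index=False,
                                               float_format=lambda v: f"{v:.4f}"))
print("\ntwo-group laterality:")
print(lis_table(res.lis_two_group).to_string(index=False,
                                             float_format=lambda v: f"{v:.4f}"))
print(f"\nartifacts written to {out}/:",
      ", ".join(sorted(p.name for p in out.iterdir())))
# LIS > 0 is right-hemisphere dominance. The eustress group carries the
# strongest right lateralization, distress nearly none -- the separation
# that sAA alone anticipates and the questionnaires cannot resolve.
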