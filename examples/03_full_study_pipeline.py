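"""Run the full analysis on a synthetic height-threat study with a planted
frontal condition effect.

The generator emulates the 2 (condition: neutral / negative) x 2 (task:
elevator / plank walking) fully within-subject design: every subject
contributes one epoch per cell, frontal within-region coupling is raised
in the negative condition, and the pipeline should find exactly that —
a significant condition effect on frontal efficiency with
negative > neutral, and little else.
"""

from neurowalk import PipelineConfig, run_pipeline

config = PipelineConfig(mode="synthetic", design="frontal", n_subjects=20,
                        effect_delta=0.3, epoch_length=10.0, sfreq=250.0,
                        seed=7, out_dir="scratch/example_run")
result = run_pipeline(config)

frontal = result.anova[(result.anova.scope == "frontal")
                       & (result.anova.metric == "efficiency")]
print("frontal efficiency ANOVA:")
print(frontal.to_string(index=False))

sub = result.metrics[(result.metrics.scope == "frontal")
                     & (result.metrics.metric == "efficiency")]
for cond in ("neutral", "negative"):
    vals = sub[sub.condition == cond].value
    print(f"frontal efficiency, {cond:8s}: "
          f"{vals.mean():.3f} +- {vals.std(ddof=1):.3f}")

n_sig = (result.anova.p < 0.05).sum()
print(f"\n{n_sig} of {len(result.anova)} tested effects significant at 0.05.")
print("The planted condition effect dominates: eta_p_sq near the top of")
print("the table, with negative > neutral as planted. Artifacts "
      "(metrics/ANOVA/posthoc CSVs) are in scratch/example_run/.")
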