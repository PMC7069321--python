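"""The full reinforcement-signature analysis on a synthetic dataset.

Generates the study-condition dataset (4 populations x 2 contexts x
2 sexes, ~18 fish per cell; 3 stream replicates per population), then
runs: group preference summaries, the nested linear model with backward
selection, pooled-context nonparametric comparisons with effect sizes,
isolation tables, and the heteroskedastic GLS on total isolation with a
solicitation-drop sensitivity refit.
"""

from reinfiso.report import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(simulate_seed=7, out_dir="pipeline_out"))

print("Final model terms:", ", ".join(report.final_terms))
print("\nPooled strength of preference by context x sex:")
print(report.pooled_sop.round(2).to_string(index=False))
print("\nSex-specific sympatry-allopatry comparisons:")
print(report.sex_specific.round(3).to_string(index=False))

ctx = report.gls_full["coefficients"]["context[sympatric]"]
ctx_red = report.gls_reduced["coefficients"]["context[sympatric]"]
print(f"\nGLS context effect on total isolation: "
      f"t = {ctx['t']:.2f}, p = {ctx['p']:.3f}")
print(f"after dropping solicitation behaviors:  "
      f"t = {ctx_red['t']:.2f}, p = {ctx_red['p']:.3f}")
print("\nA significant context effect that disappears without male "
      "solicitation shows the sympatry-allopatry contrast is carried by "
      "courtship, not chases — the generator builds in exactly that "
      "structure. Full tables in pipeline_out/.")
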