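"""End-to-end analysis: growth patterns -> adiposity, with imputation.

Runs the full pipeline on a simulated cohort: SDS, 9-level patterns,
conditional variables, trajectory summaries, adiposity indices, multiple
imputation of missing covariates (m = 5 chained-equation datasets) and
Rubin-pooled, confounder-adjusted linear models.
"""
from earlygrowth import PipelineConfig, run_pipeline
from earlygrowth.association import results_frame

config = PipelineConfig(
    outdir="example_out",
    seed=6,
    simulate={"n_children": 2000, "seed": 6},
    chart_source="generating",  # external-style reference charts
)
result = run_pipeline(config)

pat = results_frame(result.results["patterns"])
print("combined-pattern contrasts vs normal fetal / normal infant growth")
print("(liver fat fraction SDS, Rubin-pooled over 5 imputations):")
rows = pat[pat.outcome == "liver_fat_fraction_sds"]
for _, r in rows.iterrows():
    print(f"  {r.exposure.removeprefix('pat:'):30s} {r.estimate:+.2f} "
          f"({r.ci_low:+.2f} to {r.ci_high:+.2f})")
print(f"\nfetal x infant interaction p: "
      f"{result.results['interaction_p']['liver_fat_fraction_sds']:.3f}")
print(f"report bundle written to {config.outdir}/")
# The generator injects a 0.34-SDS liver-fat effect for fetal deceleration
# followed by infant acceleration; the pooled contrast recovers it within
# sampling error.
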