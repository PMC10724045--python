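"""Run the full pipeline on a synthetic cohort and read the report.

The pipeline chains: generation -> log transform -> group t-tests with BH
correction -> bootstrapped top-k region selection -> age/sex residualization
-> event-based model with bootstrap uncertainty -> randomness test ->
cross-sectional staging. All artifacts (report.json, selection.tsv,
sequence.json, positional_variance.tsv) land in the output directory, and a
second run with the same config + seed reproduces them byte for byte.
"""

from disconseq import GeneratorConfig, RunConfig, run_pipeline

config = RunConfig(
    mode="synthetic",
    generator=GeneratorConfig(n_subjects=300, n_regions=20),
    n_boot=25,
    top_k=10,
    seed=11,
    outdir="scratch/examples/pipeline",
    make_plots=True,  # writes the positional-variance and event-centre figures
)
report = run_pipeline(config)

print("selected regions:", ", ".join(report.selection.selected_regions))
print("estimated order: ", " -> ".join(report.sequence_result.sequence_ids))
print(f"randomness test:  t = {report.randomness.t:.2f}, "
      f"one-sided p = {report.randomness.p_one_sided:.2g}")
print(f"Kendall tau vs planted truth (selected regions): {report.recovery_tau:.3f}")
print("subjects per modal stage:", report.stage_counts)
print(f"\nartifacts written to {config.outdir} (config hash "
      f"{report.provenance['config_hash']})")
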