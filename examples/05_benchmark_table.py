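"""Run a miniature benchmark protocol and print the comparison table.

For one parameter-spread level the protocol optimizes a design with each
estimator (linearization and sigma points), Monte Carlo-verifies both
winners, and tabulates estimated vs verified overlap plus the relative
MSEs of the moment estimates.  This is a heavily scaled-down version of
the full benchmark (use the `roed benchmark` CLI with larger budgets for
a serious run); expect a few minutes.
"""

from roed.benchmarks import BenchmarkConfig, run_benchmark

cfg = BenchmarkConfig(
    system="schlogl",
    eta_levels=(0.1,),
    estimators=("linearization", "sigma-point"),
    n_opt_repeats=4,
    n_mc_verify=2000,
    seed=0,
    budget=120,
)
table = run_benchmark(cfg)
cols = ["estimator", "est_overlap", "mc_overlap",
        "rel_mse_mean", "rel_mse_var"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print("Watch the est_overlap vs mc_overlap columns: the linearization-based")
print("design typically reports a far smaller overlap than Monte Carlo")
print("reveals, while the sigma-point design's estimate is honest.")
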