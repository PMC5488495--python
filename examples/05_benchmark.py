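"""A small slice of the benchmark grid: does unlabeled data help?

Compares the supervised-only and semisupervised arms at one labeled
subimage, averaged over seeded repeats (kept small here; see
scripts/acceptance.py for the full five-repeat protocol).
"""
from cellforest import BenchmarkConfig, benchmark_run

cfg = BenchmarkConfig(k_values=(1,), arms=("supervised", "ss"),
                      n_repeats=2, seed=0)
report = benchmark_run(cfg)
print(report.to_string(index=False))
print("\nf_mean is the detection F-score averaged over repeats;")
print("the two rows differ only in whether the unsupervised path loss is used.")
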