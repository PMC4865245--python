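"""QC cascade and cohort merging.

Simulates three drift-differentiated cohorts with injected missingness,
applies the sample/marker QC cascade per cohort, merges them, and repeats
QC on the merged panel — the standard chip-analysis preamble.
"""

import numpy as np

from capripop import QCConfig, merge_datasets, run_qc
from capripop.qc import TABLE_HEADER
from capripop.simulate import inject_missingness, simulate_structured

cohorts = []
for i, pop in enumerate(["AR", "FR", "SA"]):
    ds, _ = simulate_structured(1, 0.5, 20, 600, seed=10 + i)
    ds.samples = [s.__class__(f"{pop}{j}", pop) for j, s in enumerate(ds.samples)]
    ds = inject_missingness(ds, np.full(20, 0.1), 0.3, seed=i)
    cohorts.append(ds)

print(TABLE_HEADER)
cleaned = []
for pop, ds in zip(["AR", "FR", "SA"], cohorts):
    out, report = run_qc(ds, QCConfig())
    cleaned.append(out)
    print(report.to_table_row(pop))

merged = merge_datasets(cleaned)
merged, report = run_qc(merged, QCConfig())
print(report.to_table_row("Merged"))
print(f"\nMerged panel: {merged.n_samples} samples x {merged.n_snps} SNPs.")
print("Each row counts SNPs removed by the first criterion they fail "
      "(call rate, MAF, then exact HWE); 'remaining' is the analysis panel.")
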