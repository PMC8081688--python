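"""Marker quality control: missingness and MAF filters, redundancy removal
and mean imputation, with the counts each step removed."""

import numpy as np

import famblup as fb

gmap = fb.generate_genetic_map(3, 60, 100.0, seed=1)
markers = fb.generate_founders(40, gmap, seed=2)

# degrade the matrix: 20% missing calls in the first three loci, one
# duplicated column
calls = markers.calls.copy()
calls.iloc[:8, :3] = np.nan
calls["dup_of_m4"] = calls.iloc[:, 4]
dirty = fb.MarkerMatrix(calls)

filtered, report = fb.filter_markers(dirty, max_missing=0.10, min_maf=0.05)
print(report.summary())
dedup, dd_report = fb.deduplicate_markers(filtered, seed=3)
print(f"redundancy: removed {dd_report.n_removed_redundant} duplicate column(s)")
complete = fb.impute_missing(dedup)
print(f"after imputation: complete = {complete.is_complete()}, "
      f"mode = {complete.mode}")
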