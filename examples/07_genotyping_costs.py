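"""Genotyping-sample accounting for a typical small line-breeding program:
100 advanced lines phenotyped per year, 1000 candidates from 50 crosses."""

import famblup as fb

shape = fb.ProgramShape(n_training_lines_per_year=100, n_candidates=1000,
                        n_crosses=50)
print(f"program: {shape.n_training_lines_per_year} training lines/year, "
      f"{shape.n_candidates} candidates from {shape.n_crosses} crosses\n")
print(f"{'strategy':<12}{'assays':>8}{'% of full':>12}")
for strategy in ("full", "midparent", "familybulk"):
    n = fb.genotyping_samples(shape, strategy)
    pct = fb.genotyping_cost_ratio(shape, strategy)
    print(f"{strategy:<12}{n:>8}{pct:>11.0f}%")
print("\nmid-parent genotyping fingerprints only the crossing parents; the "
      "family-bulk strategy adds one pooled sample per cross.")
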