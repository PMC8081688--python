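"""Genotyping-sample accounting for alternative breeding strategies.

A full genomic strategy fingerprints every selection candidate each year.
The mid-parent strategy only genotypes the advanced-generation lines that
serve as training material and crossing parents; the family-bulk strategy
additionally runs one pooled sample per cross.  Pooled and individual
samples are priced as one genotyping assay each.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ProgramShape", "genotyping_samples", "genotyping_cost_ratio"]

STRATEGIES = ("full", "midparent", "familybulk")


@dataclass
class ProgramShape:
    """Annual shape of a line breeding program."""

    n_training_lines_per_year: int = 100
    n_candidates: int = 1000
    n_crosses: int = 50

    def __post_init__(self) -> None:
        if min(self.n_training_lines_per_year, self.n_candidates, self.n_crosses) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_crosses > self.n_candidates:
            raise ValueError("cannot have more crosses than candidates")


def genotyping_samples(shape: ProgramShape, strategy: str) -> int:
    """Number of genotyping assays per year under a strategy."""
    if strategy == "full":
        return shape.n_candidates
    if strategy == "midparent":
        return shape.n_training_lines_per_year
    if strategy == "familybulk":
        return shape.n_training_lines_per_year + shape.n_crosses
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def genotyping_cost_ratio(shape: ProgramShape, strategy: str) -> float:
    """Genotyping cost of a strategy as a percentage of the full genomic
    strategy (which fingerprints every candidate)."""
    if shape.n_candidates == 0:
        raise ValueError("zero candidates: ratio undefined")
    return 100.0 * genotyping_samples(shape, strategy) / genotyping_samples(shape, "full")
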