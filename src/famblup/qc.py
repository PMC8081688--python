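"""Marker quality control: missingness and MAF filters, redundancy removal,
mean imputation.

Filters use strict boundaries: a marker is removed iff its missing fraction
exceeds ``max_missing`` or its minor-allele frequency falls below
``min_maf``.  Heterozygous calls contribute half a copy of each allele to
the frequency computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = ["QCReport", "filter_markers", "deduplicate_markers", "impute_missing"]


@dataclass
class QCReport:
    n_input: int
    n_removed_missingness: int = 0
    n_removed_maf: int = 0
    n_removed_redundant: int = 0
    removed_missingness: list = field(default_factory=list)
    removed_maf: list = field(default_factory=list)
    removed_redundant: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_removed_missingness
            - self.n_removed_maf
            - self.n_removed_redundant
        )

    def summary(self) -> str:
        return (
            f"markers in: {self.n_input}; removed by missingness: "
            f"{self.n_removed_missingness}; by MAF: {self.n_removed_maf}; "
            f"redundant: {self.n_removed_redundant}; retained: {self.n_retained}"
        )


def allele_frequencies(markers: MarkerMatrix) -> pd.Series:
    """Frequency of the +1-coded allele per locus, from non-missing calls;
    heterozygotes count half.  p = (mean(call) + 1) / 2."""
    return (markers.calls.mean(axis=0, skipna=True) + 1.0) / 2.0


def filter_markers(
    markers: MarkerMatrix, max_missing: float = 0.10, min_maf: float = 0.05
) -> tuple[MarkerMatrix, QCReport]:
    """Drop markers with missing fraction > ``max_missing``, then markers
    with MAF < ``min_maf`` (MAF from the remaining non-missing calls)."""
    if markers.mode != "discrete":
        raise ValueError("QC filters expect a discrete-mode matrix")
    if markers.n_markers == 0 or markers.n_lines == 0:
        raise ValueError("empty marker matrix")
    report = QCReport(n_input=markers.n_markers)

    miss_frac = markers.calls.isna().mean(axis=0)
    drop_miss = miss_frac.index[miss_frac > max_missing]
    report.removed_missingness = list(drop_miss)
    report.n_removed_missingness = len(drop_miss)
    kept = markers.calls.drop(columns=drop_miss)

    p = (kept.mean(axis=0, skipna=True) + 1.0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    drop_maf = maf.index[maf < min_maf]
    report.removed_maf = list(drop_maf)
    report.n_removed_maf = len(drop_maf)
    kept = kept.drop(columns=drop_maf)

    return MarkerMatrix(kept, mode="discrete"), report


def deduplicate_markers(
    markers: MarkerMatrix, seed: int = 0
) -> tuple[MarkerMatrix, QCReport]:
    """Keep one random representative from each set of identical marker
    columns (identical including the missing pattern)."""
    if markers.mode != "discrete":
        raise ValueError("deduplication expects a discrete-mode matrix")
    rng = np.random.default_rng(seed)
    report = QCReport(n_input=markers.n_markers)

    # group columns by their exact content, NaN treated as a distinct value
    keys: dict[bytes, list] = {}
    values = markers.calls.to_numpy()
    coded = np.where(np.isnan(values), 99.0, values)
    for j, marker in enumerate(markers.calls.columns):
        keys.setdefault(coded[:, j].tobytes(), []).append(marker)

    keep = []
    removed = []
    for group in keys.values():
        pick = group[int(rng.integers(0, len(group)))]
        keep.append(pick)
        removed.extend(m for m in group if m != pick)
    keep_order = [m for m in markers.calls.columns if m in set(keep)]
    report.removed_redundant = removed
    report.n_removed_redundant = len(removed)
    return MarkerMatrix(markers.calls[keep_order], mode="discrete"), report


def impute_missing(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace missing calls by the locus mean of the non-missing calls.

    The result is continuous mode (imputed entries are generally fractional);
    non-missing calls are unchanged.
    """
    if markers.mode != "discrete":
        raise ValueError("imputation expects a discrete-mode matrix")
    all_missing = markers.calls.isna().all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"locus {all_missing.index[all_missing][0]!r} is 100% missing"
        )
    filled = markers.calls.fillna(markers.calls.mean(axis=0, skipna=True))
    return MarkerMatrix(filled, mode="continuous")
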