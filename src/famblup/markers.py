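"""Core containers for genetic maps and marker-genotype matrices.

Marker calls follow the usual inbred-line coding: ``+1`` for the homozygous
major allele, ``-1`` for the homozygous minor allele and ``0`` for a
heterozygote.  Missing calls are ``NaN``.  Family-level genotypes (mid-parent
or pooled family-bulk rows) are continuous values in ``[-1, +1]`` and are
flagged by ``mode="continuous"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "MarkerMatrix"]

_DISCRETE_CALLS = (-1.0, 0.0, 1.0)


@dataclass
class GeneticMap:
    """Marker positions (centiMorgan) on one or more chromosomes.

    Backed by a DataFrame with columns ``marker``, ``chromosome`` and
    ``position_cM``, sorted by chromosome then position.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "position_cM"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"genetic map lacks columns: {sorted(missing)}")
        if self.table["marker"].duplicated().any():
            dup = self.table.loc[self.table["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id in map: {dup!r}")
        if (self.table["position_cM"] < 0).any():
            raise ValueError("map positions must be non-negative")
        self.table = (
            self.table.sort_values(["chromosome", "position_cM"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list:
        return list(self.table["chromosome"].unique())

    def chromosome_positions(self, chrom) -> pd.Series:
        """Positions (cM) of the markers on one chromosome, map order."""
        sub = self.table[self.table["chromosome"] == chrom]
        return pd.Series(
            sub["position_cM"].to_numpy(), index=sub["marker"].to_numpy()
        )


@dataclass
class MarkerMatrix:
    """Lines x markers genotype matrix.

    ``calls`` is a float DataFrame (rows = lines, columns = markers) with
    ``NaN`` for missing.  ``mode`` is ``"discrete"`` (entries in
    ``{-1, 0, +1, NaN}``) or ``"continuous"`` (entries in ``[-1, +1]``).
    """

    calls: pd.DataFrame
    mode: str = "discrete"

    def __post_init__(self) -> None:
        if self.mode not in ("discrete", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.calls.index.duplicated().any():
            raise ValueError("duplicate line ids")
        if self.calls.columns.duplicated().any():
            raise ValueError("duplicate marker ids")
        values = self.calls.to_numpy(dtype=float)
        self.calls = pd.DataFrame(
            values, index=self.calls.index, columns=self.calls.columns
        )
        if self.mode == "discrete":
            ok = np.isnan(values) | np.isin(values, _DISCRETE_CALLS)
            if not ok.all():
                i, j = np.argwhere(~ok)[0]
                raise ValueError(
                    f"invalid discrete call {values[i, j]!r} for line "
                    f"{self.calls.index[i]!r}, marker {self.calls.columns[j]!r}"
                )
        else:
            with np.errstate(invalid="ignore"):
                bad = (values < -1) | (values > 1)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"continuous call {values[i, j]} outside [-1, 1] for line "
                    f"{self.calls.index[i]!r}, marker {self.calls.columns[j]!r}"
                )

    @property
    def line_ids(self) -> list:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list:
        return list(self.calls.columns)

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset(self, line_ids=None, marker_ids=None) -> "MarkerMatrix":
        df = self.calls
        if line_ids is not None:
            df = df.loc[list(line_ids)]
        if marker_ids is not None:
            df = df[list(marker_ids)]
        return MarkerMatrix(df.copy(), mode=self.mode)

    def is_complete(self) -> bool:
        return not self.calls.isna().any().any()

    def concat(self, other: "MarkerMatrix") -> "MarkerMatrix":
        """Stack two matrices row-wise; result is continuous if either is."""
        if list(self.calls.columns) != list(other.calls.columns):
            raise ValueError("marker sets differ")
        mode = (
            "discrete"
            if self.mode == other.mode == "discrete"
            else "continuous"
        )
        return MarkerMatrix(pd.concat([self.calls, other.calls]), mode=mode)
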