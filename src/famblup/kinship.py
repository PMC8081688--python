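"""Relationship matrices for breeding-value prediction.

Implements every relationship structure a line-breeding comparison needs:

* the pedigree numerator relationship matrix **A** (Henderson's tabular
  method),
* the genomic relationship matrix **G** (VanRaden's method 1),
* family-level genotypes -- mid-parent rows (the expected F1 genotype of a
  cross) and family-bulk rows (weighted mean allele content of a pooled DNA
  sample), with the SNP-array rounding rule,
* the family-augmented genomic matrix **G_mod** = alpha*G + beta*I where
  validation lines carry their family's genotype row,
* the single-step hybrid matrix **H** that joins pedigree relationships of
  non-genotyped lines with genomic relationships of genotyped ones, together
  with its closed-form inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = [
    "Pedigree",
    "FamilyMap",
    "RelationshipMatrix",
    "BlendingConfig",
    "pedigree_numerator_matrix",
    "genomic_matrix",
    "midparent_genotypes",
    "bulk_genotypes",
    "round_bulk",
    "family_augmented_matrix",
    "adjust_genomic_to_pedigree",
    "hybrid_matrix",
]


@dataclass
class Pedigree:
    """Parent records: (individual, parent1, parent2), ``None`` = unknown."""

    records: pd.DataFrame  # columns: id, parent1, parent2

    def __post_init__(self) -> None:
        required = {"id", "parent1", "parent2"}
        if required - set(self.records.columns):
            raise ValueError("pedigree needs columns id, parent1, parent2")
        if self.records["id"].duplicated().any():
            dup = self.records.loc[self.records["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate pedigree id {dup!r}")
        self.records = self.records.where(pd.notna(self.records), None)

    def topological_ids(self) -> list:
        """All ids (recorded individuals and referenced parents), parents
        before offspring.  Raises on a cycle, naming it."""
        g = nx.DiGraph()
        for _, row in self.records.iterrows():
            g.add_node(row["id"])
            for parent in (row["parent1"], row["parent2"]):
                if parent is not None:
                    g.add_edge(parent, row["id"])
        try:
            return list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise ValueError(f"pedigree contains a cycle: {cycle}") from None

    def parents_of(self) -> dict:
        return {
            row["id"]: (row["parent1"], row["parent2"])
            for _, row in self.records.iterrows()
        }


@dataclass
class FamilyMap:
    """A bi-parental family: the cross parents and its member lines.

    ``weights`` are pooling proportions for the family bulk; ``None`` means
    equal contributions.
    """

    family_id: str
    parent1_id: str
    parent2_id: str
    member_line_ids: list
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.member_line_ids) == 0:
            raise ValueError(f"family {self.family_id!r} has no members")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(self.member_line_ids):
                raise ValueError("weights length mismatch")
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("weights must be >= 0 with a positive sum")
            self.weights = w


@dataclass
class RelationshipMatrix:
    """Dense symmetric id-indexed relationship matrix."""

    values: pd.DataFrame
    kind: str = "G"

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.values.columns):
            raise ValueError("row and column ids differ")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite relationship entry")
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError("matrix is not symmetric")

    @property
    def ids(self) -> list:
        return list(self.values.index)

    def loc(self, rows, cols) -> np.ndarray:
        return self.values.loc[list(rows), list(cols)].to_numpy()

    def subset(self, ids) -> "RelationshipMatrix":
        ids = list(ids)
        return RelationshipMatrix(self.values.loc[ids, ids].copy(), kind=self.kind)


@dataclass
class BlendingConfig:
    alpha: float = 0.95
    beta: float = 0.05
    a: float = 0.0
    b: float = 1.0


def pedigree_numerator_matrix(pedigree: Pedigree, ids=None) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    Unknown parents are treated as unrelated, non-inbred founders.  The
    returned matrix covers ``ids`` in the given order (default: all pedigree
    ids in topological order).
    """
    order = pedigree.topological_ids()
    parents = pedigree.parents_of()
    index = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for k, ind in enumerate(order):
        p1, p2 = parents.get(ind, (None, None))
        i1 = index.get(p1) if p1 is not None else None
        i2 = index.get(p2) if p2 is not None else None
        # diagonal: 1 + half the parents' relationship (inbreeding)
        if i1 is not None and i2 is not None:
            a[k, k] = 1.0 + 0.5 * a[i1, i2]
        else:
            a[k, k] = 1.0
        for j in range(k):
            val = 0.0
            if i1 is not None:
                val += 0.5 * a[j, i1]
            if i2 is not None:
                val += 0.5 * a[j, i2]
            a[k, j] = a[j, k] = val
    full = pd.DataFrame(a, index=order, columns=order)
    if ids is not None:
        ids = list(ids)
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValueError(f"ids absent from pedigree: {missing[:5]}")
        full = full.loc[ids, ids]
    return RelationshipMatrix(full, kind="A")


def _vanraden(calls: pd.DataFrame) -> pd.DataFrame:
    """VanRaden method-1 G from a complete calls matrix (entries in [-1, 1]).

    Allele frequencies are computed from this exact matrix; monomorphic loci
    drop out of both the numerator (their centered column is zero) and the
    denominator sum.
    """
    if calls.isna().any().any():
        raise ValueError("G requires a complete (imputed) marker matrix")
    z = calls.to_numpy(dtype=float)
    p = (z.mean(axis=0) + 1.0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all loci monomorphic: G denominator is zero")
    w = z + 1.0 - 2.0 * p
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    g = (w @ w.T) / denom
    g = (g + g.T) / 2.0
    return pd.DataFrame(g, index=calls.index, columns=calls.index)


def genomic_matrix(markers: MarkerMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix G = WW'/(2*sum p(1-p)) with W the
    frequency-centered marker matrix."""
    return RelationshipMatrix(_vanraden(markers.calls), kind="G")


def midparent_genotypes(
    families: list[FamilyMap], parent_markers: MarkerMatrix
) -> MarkerMatrix:
    """Expected family genotypes: the mean of the two parents' calls per
    locus -- the genotype of the F1 of the cross."""
    rows = {}
    for fam in families:
        for pid in (fam.parent1_id, fam.parent2_id):
            if pid not in parent_markers.calls.index:
                raise ValueError(f"parent {pid!r} not genotyped")
        p1 = parent_markers.calls.loc[fam.parent1_id]
        p2 = parent_markers.calls.loc[fam.parent2_id]
        if p1.isna().any() or p2.isna().any():
            raise ValueError(f"missing parent genotype in family {fam.family_id!r}")
        rows[fam.family_id] = 0.5 * (p1 + p2)
    return MarkerMatrix(pd.DataFrame(rows).T, mode="continuous")


def bulk_genotypes(
    families: list[FamilyMap], member_markers: MarkerMatrix
) -> MarkerMatrix:
    """Family-bulk genotypes: the (optionally weighted) mean allele call of
    the family members per locus, emulating a pooled DNA sample.  Weights
    are normalized internally; equal weights give the plain family mean."""
    rows = {}
    for fam in families:
        missing = [m for m in fam.member_line_ids if m not in member_markers.calls.index]
        if missing:
            raise ValueError(f"members not genotyped: {missing[:5]}")
        block = member_markers.calls.loc[fam.member_line_ids]
        if block.isna().any().any():
            raise ValueError(f"missing member genotype in family {fam.family_id!r}")
        if fam.weights is None:
            rows[fam.family_id] = block.mean(axis=0)
        else:
            w = fam.weights / fam.weights.sum()
            rows[fam.family_id] = pd.Series(
                w @ block.to_numpy(), index=block.columns
            )
    return MarkerMatrix(pd.DataFrame(rows).T, mode="continuous")


def round_bulk(bulk: MarkerMatrix) -> MarkerMatrix:
    """Round pooled allele calls to discrete SNP-array-like calls:
    +1 if > 0.5, -1 if < -0.5, else 0 (values at exactly +-0.5 map to 0)."""
    v = bulk.calls.to_numpy(dtype=float)
    if np.isnan(v).any() or (np.abs(v) > 1).any():
        raise ValueError("bulk values must be complete and within [-1, 1]")
    rounded = np.where(v > 0.5, 1.0, np.where(v < -0.5, -1.0, 0.0))
    return MarkerMatrix(
        pd.DataFrame(rounded, index=bulk.calls.index, columns=bulk.calls.columns),
        mode="discrete",
    )


def family_augmented_matrix(
    training_markers: MarkerMatrix,
    family_rows: MarkerMatrix,
    assignment: dict,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> RelationshipMatrix:
    """Genomic matrix where validation lines carry family-level genotypes.

    The marker matrix W is assembled from the individually genotyped
    training lines plus, for every validation line, the mid-parent or bulk
    row of its family (``assignment`` maps validation line id -> family id).
    Allele frequencies and G come from this combined matrix; because
    validation lines of one family have identical rows, G is singular, so
    the returned kernel is the blend alpha*G + beta*I.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("blending scalars must be non-negative")
    fam_calls = family_rows.calls
    rows = [training_markers.calls]
    index = list(training_markers.calls.index)
    val_rows = {}
    for line, fam in assignment.items():
        if fam not in fam_calls.index:
            raise ValueError(f"line {line!r} assigned to unknown family {fam!r}")
        val_rows[line] = fam_calls.loc[fam]
    if val_rows:
        rows.append(pd.DataFrame(val_rows).T[training_markers.calls.columns])
        index += list(val_rows)
    combined = pd.concat(rows)
    g = _vanraden(combined).to_numpy()
    g_mod = alpha * g + beta * np.eye(len(g))
    return RelationshipMatrix(
        pd.DataFrame(g_mod, index=combined.index, columns=combined.index),
        kind="G_mod",
    )


def adjust_genomic_to_pedigree(
    G: RelationshipMatrix, A22: RelationshipMatrix
) -> tuple[RelationshipMatrix, BlendingConfig]:
    """Rescale G to the pedigree base: find (a, b) such that the mean
    diagonal and the overall mean of a + b*G match those of A22, and return
    G_adj = a + b*G."""
    if G.ids != A22.ids:
        raise ValueError("G and A22 must share ids in the same order")
    g = G.values.to_numpy()
    a22 = A22.values.to_numpy()
    md_g, m_g = float(np.mean(np.diag(g))), float(np.mean(g))
    md_a, m_a = float(np.mean(np.diag(a22))), float(np.mean(a22))
    if abs(md_g - m_g) < 1e-12:
        raise ValueError("degenerate adjustment: mean(diag G) equals mean(G)")
    b = (md_a - m_a) / (md_g - m_g)
    a = md_a - b * md_g
    g_adj = a + b * g
    cfg = BlendingConfig(a=a, b=b)
    return (
        RelationshipMatrix(
            pd.DataFrame(g_adj, index=G.values.index, columns=G.values.columns),
            kind="G_adj",
        ),
        cfg,
    )


def hybrid_matrix(
    A: RelationshipMatrix,
    G_adj: RelationshipMatrix,
    genotyped_ids,
    alpha: float = 0.95,
    beta: float = 0.05,
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Single-step hybrid matrix H and its closed-form inverse.

    The genomic block is the blend G_w = alpha*G_adj + beta*A22.  H replaces
    the pedigree relationships among genotyped individuals by G_w and
    propagates the update to their non-genotyped relatives:

        H11 = A11 + A12 A22^-1 (G_w - A22) A22^-1 A21 ... corrected block
        H12 = A12 A22^-1 G_w,   H22 = G_w

    and H^-1 = A^-1 + [[0, 0], [0, G_w^-1 - A22^-1]].  Blocks are ordered
    (non-genotyped, genotyped).
    """
    genotyped = list(genotyped_ids)
    all_ids = A.ids
    missing = [i for i in genotyped if i not in set(all_ids)]
    if missing:
        raise ValueError(f"genotyped ids absent from A: {missing[:5]}")
    if list(G_adj.ids) != genotyped:
        G_adj = G_adj.subset(genotyped)
    nongen = [i for i in all_ids if i not in set(genotyped)]
    order = nongen + genotyped

    a22 = A.loc(genotyped, genotyped)
    g_w = alpha * G_adj.values.to_numpy() + beta * a22
    try:
        a22_inv = np.linalg.inv(a22)
    except np.linalg.LinAlgError as err:
        raise ValueError("A22 is singular") from err

    if not nongen:
        h = g_w
        h_inv = np.linalg.inv(g_w)
    else:
        a11 = A.loc(nongen, nongen)
        a12 = A.loc(nongen, genotyped)
        t = a12 @ a22_inv
        h11 = a11 + t @ (g_w - a22) @ a22_inv @ a12.T
        h12 = t @ g_w
        h = np.block([[h11, h12], [h12.T, g_w]])
        a_full = A.loc(order, order)
        correction = np.zeros_like(a_full)
        n1 = len(nongen)
        correction[n1:, n1:] = np.linalg.inv(g_w) - a22_inv
        h_inv = np.linalg.inv(a_full) + correction
    h = (h + h.T) / 2.0
    h_inv = (h_inv + h_inv.T) / 2.0
    return (
        RelationshipMatrix(pd.DataFrame(h, index=order, columns=order), kind="H"),
        RelationshipMatrix(pd.DataFrame(h_inv, index=order, columns=order), kind="H"),
    )
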