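"""Synthetic breeding-population generator.

Produces everything an in-silico line-breeding study needs: a multi-chromosome
genetic map, inbred founders with realistic relatedness and linkage
disequilibrium (mosaics of a small pool of ancestral haplotypes), bi-parental
progeny simulated by meiosis with a Poisson crossover process (Haldane,
no interference), additive QTL trait architectures, true and noisy breeding
values, and replicated multi-trial phenotypes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import GeneticMap, MarkerMatrix

__all__ = [
    "TraitArchitecture",
    "BreedingValues",
    "generate_genetic_map",
    "generate_founders",
    "simulate_progeny",
    "sample_trait_architecture",
    "true_breeding_values",
    "add_phenotyping_noise",
    "generate_trial_phenotypes",
]


@dataclass
class TraitArchitecture:
    """Additive trait architecture: QTL loci with effects, plus the disjoint
    SNP set used for relationship matrices."""

    qtl_marker_ids: list
    qtl_effects: np.ndarray
    snp_marker_ids: list

    def __post_init__(self) -> None:
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=float)
        if len(self.qtl_marker_ids) != len(self.qtl_effects):
            raise ValueError("QTL ids and effects differ in length")
        if set(self.qtl_marker_ids) & set(self.snp_marker_ids):
            raise ValueError("QTL and SNP marker sets overlap")
        if not np.all(np.isfinite(self.qtl_effects)):
            raise ValueError("non-finite QTL effect")


@dataclass
class BreedingValues:
    """True breeding values and, optionally, noisy records for a set of lines."""

    line_ids: list
    tbv: pd.Series
    ebv: pd.Series | None = None
    error_variance: float | None = None


def generate_genetic_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chrom_length_cM: float = 150.0,
    seed: int = 0,
    spacing: str = "random",
) -> GeneticMap:
    """Generate a genetic map with ``n_chromosomes`` chromosomes.

    ``spacing="even"`` places markers at equal intervals from 0 to the
    chromosome end; ``"random"`` draws uniform positions.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    if chrom_length_cM <= 0:
        raise ValueError("chromosome length must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        if spacing == "even":
            if markers_per_chromosome == 1:
                pos = np.array([0.0])
            else:
                pos = np.linspace(0.0, chrom_length_cM, markers_per_chromosome)
        elif spacing == "random":
            pos = np.sort(rng.uniform(0.0, chrom_length_cM, markers_per_chromosome))
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        for k, p in enumerate(pos, start=1):
            rows.append((f"chr{c}_m{k}", f"chr{c}", float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"]))


def generate_founders(
    n_founders: int,
    gmap: GeneticMap,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_ancestral_haplotypes: int = 20,
    segment_length_cM: float = 50.0,
    seed: int = 0,
    prefix: str = "F",
) -> MarkerMatrix:
    """Generate fully homozygous founder lines.

    Each locus gets an allele frequency whose minor side is uniform in
    ``maf_range``.  A pool of ``n_ancestral_haplotypes`` haplotypes is drawn
    at those frequencies, and every founder is an independent mosaic of pool
    haplotypes with exponentially distributed segment lengths (mean
    ``segment_length_cM``).  The mosaic construction induces relatedness
    among founders and linkage disequilibrium along chromosomes; with
    ``n_ancestral_haplotypes == n_founders`` and long segments the founders
    are close to independent draws.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n_founders < 1 or n_ancestral_haplotypes < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)

    n_loci = gmap.n_markers
    maf = rng.uniform(lo, hi, n_loci)
    # frequency of the +1 allele; the minor allele is +1 or -1 at random
    p_plus = np.where(rng.random(n_loci) < 0.5, maf, 1.0 - maf)
    # ancestral haplotype pool, alleles coded +-1
    pool = np.where(
        rng.random((n_ancestral_haplotypes, n_loci)) < p_plus, 1.0, -1.0
    )

    chrom_slices = _chromosome_slices(gmap)
    calls = np.empty((n_founders, n_loci))
    for f in range(n_founders):
        for _, sl, pos in chrom_slices:
            calls[f, sl] = _mosaic_haplotype(
                pool[:, sl], pos, segment_length_cM, rng
            )
    ids = [f"{prefix}{i + 1}" for i in range(n_founders)]
    return MarkerMatrix(
        pd.DataFrame(calls, index=ids, columns=gmap.marker_ids), mode="discrete"
    )


def _chromosome_slices(gmap: GeneticMap):
    """(chrom, column-slice, positions) per chromosome, in map order."""
    out = []
    start = 0
    table = gmap.table
    for chrom in gmap.chromosomes():
        pos = table.loc[table["chromosome"] == chrom, "position_cM"].to_numpy()
        out.append((chrom, slice(start, start + len(pos)), pos))
        start += len(pos)
    return out


def _mosaic_haplotype(pool_block, pos, segment_length_cM, rng):
    """One chromosome of a mosaic founder: switch ancestral haplotype at
    exponentially spaced breakpoints."""
    n_hap = pool_block.shape[0]
    length = pos[-1] - pos[0] if len(pos) > 1 else 0.0
    breaks = []
    x = pos[0] + rng.exponential(segment_length_cM)
    while x < pos[0] + length:
        breaks.append(x)
        x += rng.exponential(segment_length_cM)
    donors = rng.integers(0, n_hap, len(breaks) + 1)
    segment = np.searchsorted(np.asarray(breaks), pos, side="right")
    return pool_block[donors[segment], np.arange(pool_block.shape[1])]


def _gamete(hap1, hap2, chrom_slices, rng):
    """Meiotic gamete from a (possibly heterozygous) genome.

    Crossover count per chromosome is Poisson with mean = map length in
    Morgan; crossover positions are uniform (Haldane mapping, no
    interference).
    """
    out = np.empty_like(hap1)
    for _, sl, pos in chrom_slices:
        length_m = (pos[-1] - pos[0]) / 100.0 if len(pos) > 1 else 0.0
        n_xo = rng.poisson(length_m)
        xo = np.sort(rng.uniform(pos[0], pos[-1], n_xo)) if n_xo else np.empty(0)
        phase = (int(rng.integers(0, 2)) + np.searchsorted(xo, pos, side="right")) % 2
        h1, h2 = hap1[sl], hap2[sl]
        out[sl] = np.where(phase == 0, h1, h2)
    return out


def simulate_progeny(
    parent1_row: pd.Series,
    parent2_row: pd.Series,
    gmap: GeneticMap,
    n_progeny: int,
    progeny_type: str = "DH",
    selfing_generation: int = 6,
    seed: int = 0,
    prefix: str = "P",
) -> MarkerMatrix:
    """Simulate progeny of a bi-parental cross between homozygous parents.

    ``progeny_type="DH"`` doubles a single F1 gamete (fully homozygous
    lines).  ``progeny_type="selfed"`` selfs the F1 to generation
    ``selfing_generation`` (F2 = generation 2, etc.), leaving residual
    heterozygosity of about ``(1/2)**(k-1)`` per segregating locus.
    """
    if progeny_type not in ("DH", "selfed"):
        raise ValueError(f"unknown progeny_type {progeny_type!r}")
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    p1 = parent1_row.reindex(gmap.marker_ids)
    p2 = parent2_row.reindex(gmap.marker_ids)
    if p1.isna().any() or p2.isna().any():
        missing = p1.index[p1.isna() | p2.isna()][0]
        raise ValueError(f"parent genotype missing for map marker {missing!r}")
    a1 = p1.to_numpy(dtype=float)
    a2 = p2.to_numpy(dtype=float)
    if np.any(a1 == 0) or np.any(a2 == 0):
        raise ValueError("parents must be fully homozygous (calls in {-1, +1})")

    rng = np.random.default_rng(seed)
    chrom_slices = _chromosome_slices(gmap)
    calls = np.empty((n_progeny, len(a1)))
    for i in range(n_progeny):
        if progeny_type == "DH":
            g = _gamete(a1, a2, chrom_slices, rng)
            calls[i] = g  # doubled gamete: genotype call equals the allele
        else:
            h1, h2 = a1, a2  # the F1 genome
            for _ in range(selfing_generation - 1):
                h1, h2 = (
                    _gamete(h1, h2, chrom_slices, rng),
                    _gamete(h1, h2, chrom_slices, rng),
                )
            calls[i] = (h1 + h2) / 2.0
    ids = [f"{prefix}{i + 1}" for i in range(n_progeny)]
    return MarkerMatrix(
        pd.DataFrame(calls, index=ids, columns=gmap.marker_ids), mode="discrete"
    )


def sample_trait_architecture(
    marker_ids, n_qtl: int = 100, n_snp: int = 2000, seed: int = 0
) -> TraitArchitecture:
    """Sample disjoint QTL and SNP marker sets; QTL effects ~ N(0, 1)."""
    marker_ids = list(marker_ids)
    if n_qtl + n_snp > len(marker_ids):
        raise ValueError(
            f"need {n_qtl + n_snp} markers, only {len(marker_ids)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(marker_ids), size=n_qtl + n_snp, replace=False)
    qtl = [marker_ids[i] for i in chosen[:n_qtl]]
    snp = [marker_ids[i] for i in chosen[n_qtl:]]
    effects = rng.standard_normal(n_qtl)
    return TraitArchitecture(qtl, effects, snp)


def true_breeding_values(arch: TraitArchitecture, genotypes: MarkerMatrix) -> BreedingValues:
    """True breeding values: QTL genotype matrix times the effect vector."""
    missing = [m for m in arch.qtl_marker_ids if m not in genotypes.calls.columns]
    if missing:
        raise ValueError(f"QTL markers absent from genotypes: {missing[:5]}")
    q = genotypes.calls[arch.qtl_marker_ids]
    if q.isna().any().any():
        raise ValueError("missing QTL call")
    tbv = pd.Series(q.to_numpy() @ arch.qtl_effects, index=genotypes.calls.index)
    return BreedingValues(list(tbv.index), tbv)


def add_phenotyping_noise(
    tbv: pd.Series, target_h2: float, seed: int = 0
) -> BreedingValues:
    """Add Gaussian noise so records have the target entry-mean heritability.

    The error variance is ``var(tbv) * (1 - h2) / h2``, with ``var`` the
    sample variance of the supplied true breeding values -- computed on this
    subset only, so training and validation populations are noised at their
    own scales.
    """
    if not (0 < target_h2 <= 1):
        raise ValueError("target_h2 must be in (0, 1]")
    tbv = pd.Series(tbv, dtype=float)
    s2 = float(tbv.var(ddof=1))
    if not np.isfinite(s2) or s2 <= 0:
        raise ValueError("true breeding values have no variance")
    sigma2_e = s2 * (1.0 - target_h2) / target_h2
    rng = np.random.default_rng(seed)
    ebv = tbv + rng.normal(0.0, np.sqrt(sigma2_e), len(tbv))
    return BreedingValues(list(tbv.index), tbv, ebv, sigma2_e)


def generate_trial_phenotypes(
    line_effects: pd.Series,
    n_trials_per_year: int,
    years,
    sigma2_year: float = 0.0,
    sigma2_trial: float = 0.0,
    sigma2_resid: float = 1.0,
    n_replicates: int = 2,
    grand_mean: float = 0.0,
    seed: int = 0,
    trait: str = "trait",
) -> pd.DataFrame:
    """Replicated multi-trial plot phenotypes in long format.

    Each plot value is grand mean + line effect + year effect + trial offset
    + residual, with year effects N(0, sigma2_year), trial offsets
    N(0, sigma2_trial) and residuals N(0, sigma2_resid).  Columns:
    line_id, trial_id, year, replicate, trait, value.
    """
    if min(sigma2_year, sigma2_trial, sigma2_resid) < 0:
        raise ValueError("variance components must be non-negative")
    if n_trials_per_year < 1 or n_replicates < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    line_effects = pd.Series(line_effects, dtype=float)
    rows = []
    for year in years:
        j = rng.normal(0.0, np.sqrt(sigma2_year)) if sigma2_year > 0 else 0.0
        for t in range(1, n_trials_per_year + 1):
            trial_id = f"{year}_T{t}"
            t_off = rng.normal(0.0, np.sqrt(sigma2_trial)) if sigma2_trial > 0 else 0.0
            for line, g in line_effects.items():
                for rep in range(1, n_replicates + 1):
                    e = (
                        rng.normal(0.0, np.sqrt(sigma2_resid))
                        if sigma2_resid > 0
                        else 0.0
                    )
                    rows.append(
                        (line, trial_id, year, rep, trait, grand_mean + g + j + t_off + e)
                    )
    return pd.DataFrame(
        rows, columns=["line_id", "trial_id", "year", "replicate", "trait", "value"]
    )
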