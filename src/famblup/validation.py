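"""Experimental designs and metrics for comparing prediction strategies.

Covers the study designs a line-breeding comparison needs:

* an empirical-style cross-validation plan (disjoint training and
  validation families, a fixed number of lines per family, many replicates),
* a simulated breeding program (founder pool with one recorded ancestral
  generation, bi-parental candidate families of doubled-haploid progeny),
* validation scheme A (candidates pre-selected on true breeding value,
  parents in or out of the training set) and scheme B (a fixed number of
  lines sampled per family),
* `run_models`, which builds the relationship kernel for each prediction
  strategy (P-BLUP, G-BLUP, SSG-BLUP, M-BLUP, F-BLUP array/GBS, PHENO) and
  returns one estimated breeding value per candidate and model,
* evaluation metrics: prediction ability/accuracy (Pearson correlation),
  relative selection gain, co-selection percentage, and compact letter
  displays from paired tests on Fisher-z transformed abilities,
* a pooling-error stress test that overweights one member of a family bulk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .blup import fit_group_model, fit_single_kernel
from .kinship import (
    FamilyMap,
    Pedigree,
    RelationshipMatrix,
    adjust_genomic_to_pedigree,
    bulk_genotypes,
    family_augmented_matrix,
    genomic_matrix,
    hybrid_matrix,
    midparent_genotypes,
    pedigree_numerator_matrix,
    round_bulk,
)
from .markers import GeneticMap, MarkerMatrix
from .simulate import (
    add_phenotyping_noise,
    generate_founders,
    generate_genetic_map,
    sample_trait_architecture,
    simulate_progeny,
    true_breeding_values,
)

__all__ = [
    "SplitPlan",
    "SimProgram",
    "simulate_breeding_program",
    "empirical_cv_plan",
    "simulation_scheme_A",
    "simulation_scheme_B",
    "run_models",
    "prediction_ability",
    "relative_selection_gain",
    "co_selection",
    "compare_models",
    "overrepresentation_experiment",
]

ALL_MODELS = (
    "pblup",
    "gblup",
    "ssgblup",
    "mblup",
    "fblup_array",
    "fblup_gbs",
    "pheno",
)


@dataclass
class SplitPlan:
    """One replicate's training/validation split and its scenario flags."""

    replicate: int
    training_ids: list
    validation_ids: list
    family_of: dict  # validation line id -> family id
    h2_train: float = 0.5
    h2_validation: float = 0.3
    parents_in_training: bool = False
    preselection_fraction: float = 1.0
    lines_per_family: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.training_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"training and validation overlap: {sorted(overlap)[:5]}")


@dataclass
class SimProgram:
    """A simulated line-breeding program: genotyped pool lines (potential
    training material and crossing parents) plus candidate families of
    simulated progeny."""

    gmap: GeneticMap
    markers: MarkerMatrix  # pool lines + progeny, discrete calls
    pedigree: Pedigree
    arch: "object"
    tbv: pd.Series
    families: list[FamilyMap]
    pool_ids: list
    parent_ids: list
    progeny_ids: list

    @property
    def snp_marker_ids(self) -> list:
        return list(self.arch.snp_marker_ids)

    def family_of(self, ids=None) -> dict:
        out = {}
        for fam in self.families:
            for m in fam.member_line_ids:
                out[m] = fam.family_id
        if ids is not None:
            out = {i: out[i] for i in ids}
        return out


def simulate_breeding_program(
    n_families: int = 30,
    progeny_per_family: int = 90,
    n_pool: int = 300,
    n_base_founders: int = 30,
    gmap: GeneticMap | None = None,
    n_chromosomes: int = 21,
    markers_per_chromosome: int = 100,
    n_qtl: int = 100,
    n_snp: int = 2000,
    n_ancestral_haplotypes: int = 20,
    seed: int = 0,
) -> SimProgram:
    """Simulate a breeding program for in-silico validation studies.

    Base founders (unknown parents) are crossed at random to produce a pool
    of doubled-haploid lines with recorded pedigree -- the phenotyped
    material of earlier cycles.  ``2 * n_families`` pool lines become
    crossing parents of the candidate families, each with
    ``progeny_per_family`` DH progeny.  A trait architecture with ``n_qtl``
    QTL and a disjoint set of ``n_snp`` relationship markers is sampled and
    true breeding values computed for every genotyped line.
    """
    if 2 * n_families > n_pool:
        raise ValueError("pool too small to supply the crossing parents")
    rng = np.random.default_rng(seed)
    if gmap is None:
        gmap = generate_genetic_map(
            n_chromosomes, markers_per_chromosome, 150.0, seed=seed
        )
    base = generate_founders(
        n_base_founders,
        gmap,
        n_ancestral_haplotypes=n_ancestral_haplotypes,
        seed=seed + 1,
        prefix="B",
    )
    base_ids = base.line_ids

    # pool lines: one DH per random base cross, pedigree recorded
    ped_rows = []
    pool_frames = []
    for i in range(n_pool):
        b1, b2 = rng.choice(len(base_ids), size=2, replace=False)
        prog = simulate_progeny(
            base.calls.iloc[b1],
            base.calls.iloc[b2],
            gmap,
            1,
            "DH",
            seed=int(rng.integers(0, 2**31 - 1)),
            prefix=f"L{i + 1}_",
        )
        row = prog.calls.iloc[[0]].rename(index={prog.line_ids[0]: f"L{i + 1}"})
        pool_frames.append(row)
        ped_rows.append((f"L{i + 1}", base_ids[b1], base_ids[b2]))
    pool = pd.concat(pool_frames)
    pool_ids = list(pool.index)

    # candidate families from pool-line crosses
    parent_idx = rng.choice(n_pool, size=2 * n_families, replace=False)
    families: list[FamilyMap] = []
    prog_frames = []
    parent_ids: list = []
    for f in range(n_families):
        p1 = pool_ids[parent_idx[2 * f]]
        p2 = pool_ids[parent_idx[2 * f + 1]]
        parent_ids += [p1, p2]
        fam_id = f"Fam{f + 1}"
        prog = simulate_progeny(
            pool.loc[p1],
            pool.loc[p2],
            gmap,
            progeny_per_family,
            "DH",
            seed=int(rng.integers(0, 2**31 - 1)),
            prefix=f"{fam_id}_",
        )
        prog_frames.append(prog.calls)
        families.append(FamilyMap(fam_id, p1, p2, list(prog.calls.index)))
        ped_rows += [(m, p1, p2) for m in prog.calls.index]
    progeny = pd.concat(prog_frames)
    progeny_ids = list(progeny.index)

    markers = MarkerMatrix(pd.concat([pool, progeny]), mode="discrete")
    pedigree = Pedigree(
        pd.DataFrame(ped_rows, columns=["id", "parent1", "parent2"])
    )
    arch = sample_trait_architecture(gmap.marker_ids, n_qtl, n_snp, seed=seed + 2)
    tbv = true_breeding_values(arch, markers).tbv
    return SimProgram(
        gmap=gmap,
        markers=markers,
        pedigree=pedigree,
        arch=arch,
        tbv=tbv,
        families=families,
        pool_ids=pool_ids,
        parent_ids=parent_ids,
        progeny_ids=progeny_ids,
    )


def empirical_cv_plan(
    families: list[FamilyMap],
    n_train_fam: int = 45,
    n_val_fam: int = 15,
    lines_per_fam: int = 4,
    n_reps: int = 100,
    seed: int = 0,
    h2_train: float = 0.5,
    h2_validation: float = 0.3,
) -> list[SplitPlan]:
    """Across-family cross-validation: per replicate, disjoint training and
    validation family sets with a fixed number of lines sampled per family.
    Parents are excluded from both sets by construction (only family
    members are sampled)."""
    eligible = [f for f in families if len(f.member_line_ids) >= lines_per_fam]
    if len(eligible) < n_train_fam + n_val_fam:
        raise ValueError(
            f"need {n_train_fam + n_val_fam} families with >= {lines_per_fam} "
            f"lines, found {len(eligible)}"
        )
    plans = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        chosen = rng.choice(len(eligible), size=n_train_fam + n_val_fam, replace=False)
        train_ids, val_ids, fam_of = [], [], {}
        for k, fi in enumerate(chosen):
            fam = eligible[fi]
            members = list(fam.member_line_ids)
            pick = rng.choice(len(members), size=lines_per_fam, replace=False)
            lines = [members[i] for i in pick]
            if k < n_train_fam:
                train_ids += lines
            else:
                val_ids += lines
                fam_of.update({m: fam.family_id for m in lines})
        plans.append(
            SplitPlan(
                replicate=rep,
                training_ids=train_ids,
                validation_ids=val_ids,
                family_of=fam_of,
                h2_train=h2_train,
                h2_validation=h2_validation,
                seed=seed + rep,
            )
        )
    return plans


def _training_sample(program: SimProgram, n_training: int, parents_in: bool, rng):
    """Training lines from the pool: either excluding the crossing parents,
    or including all p parents plus n - p random other pool lines."""
    parents = set(program.parent_ids)
    others = [i for i in program.pool_ids if i not in parents]
    if parents_in:
        n_rest = n_training - len(parents)
        if n_rest < 0:
            raise ValueError("more parents than training slots")
        pick = rng.choice(len(others), size=n_rest, replace=False)
        return list(program.parent_ids) + [others[i] for i in pick]
    if n_training > len(others):
        raise ValueError("pool too small for the requested training size")
    pick = rng.choice(len(others), size=n_training, replace=False)
    return [others[i] for i in pick]


def simulation_scheme_A(
    program: SimProgram,
    preselect_top_fraction: float = 1.0,
    parents_in_training: bool = False,
    h2_train: float = 0.5,
    h2_validation: float = 0.3,
    n_training: int = 180,
    n_candidates: int = 300,
    n_reps: int = 50,
    seed: int = 0,
) -> list[SplitPlan]:
    """Scheme A: candidates drawn from the whole progeny pool or from its
    best fraction by true breeding value (pre-selection before genotyping).
    """
    if not (0.3 <= preselect_top_fraction <= 1.0):
        raise ValueError("preselect_top_fraction must lie in [0.3, 1.0]")
    pool = program.progeny_ids
    fam_of_all = program.family_of()
    plans = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        training = _training_sample(program, n_training, parents_in_training, rng)
        if preselect_top_fraction < 1.0:
            n_top = int(round(preselect_top_fraction * len(pool)))
            order = program.tbv.loc[pool].sort_values(ascending=False)
            eligible = list(order.index[:n_top])
        else:
            eligible = list(pool)
        if n_candidates > len(eligible):
            raise ValueError("candidate pool smaller than n_candidates")
        pick = rng.choice(len(eligible), size=n_candidates, replace=False)
        candidates = [eligible[i] for i in pick]
        plans.append(
            SplitPlan(
                replicate=rep,
                training_ids=training,
                validation_ids=candidates,
                family_of={c: fam_of_all[c] for c in candidates},
                h2_train=h2_train,
                h2_validation=h2_validation,
                parents_in_training=parents_in_training,
                preselection_fraction=preselect_top_fraction,
                seed=seed + rep,
            )
        )
    return plans


def simulation_scheme_B(
    program: SimProgram,
    lines_per_family: int = 4,
    parents_in_training: bool = False,
    h2_train: float = 0.5,
    h2_validation: float = 0.3,
    n_training: int = 180,
    n_reps: int = 50,
    seed: int = 0,
) -> list[SplitPlan]:
    """Scheme B: an equal number of lines sampled from every candidate
    family, to probe the effect of family size on each model."""
    per_family = len(program.families[0].member_line_ids)
    if lines_per_family < 1 or lines_per_family > per_family:
        raise ValueError(
            f"lines_per_family must be in [1, {per_family}]"
        )
    fam_of_all = program.family_of()
    plans = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        training = _training_sample(program, n_training, parents_in_training, rng)
        candidates = []
        for fam in program.families:
            members = list(fam.member_line_ids)
            pick = rng.choice(len(members), size=lines_per_family, replace=False)
            candidates += [members[i] for i in pick]
        plans.append(
            SplitPlan(
                replicate=rep,
                training_ids=training,
                validation_ids=candidates,
                family_of={c: fam_of_all[c] for c in candidates},
                h2_train=h2_train,
                h2_validation=h2_validation,
                parents_in_training=parents_in_training,
                lines_per_family=lines_per_family,
                seed=seed + rep,
            )
        )
    return plans


def _candidate_families(program: SimProgram, plan: SplitPlan) -> list[FamilyMap]:
    """Families restricted to the candidate members of this plan (the lines
    a bulk of the validation population would actually pool)."""
    by_fam: dict = {}
    for line, fam_id in plan.family_of.items():
        by_fam.setdefault(fam_id, []).append(line)
    lookup = {f.family_id: f for f in program.families}
    return [
        FamilyMap(fam_id, lookup[fam_id].parent1_id, lookup[fam_id].parent2_id, members)
        for fam_id, members in by_fam.items()
    ]


def build_kernel(
    model: str,
    program: SimProgram,
    plan: SplitPlan,
    families: list[FamilyMap] | None = None,
) -> RelationshipMatrix:
    """Relationship kernel over (training + candidates) for one model."""
    ids = list(plan.training_ids) + list(plan.validation_ids)
    snp = program.snp_marker_ids
    if model == "pblup":
        return pedigree_numerator_matrix(program.pedigree, ids)
    if model == "gblup":
        return genomic_matrix(program.markers.subset(ids, snp))
    if model == "ssgblup":
        a = pedigree_numerator_matrix(program.pedigree, ids)
        g = genomic_matrix(program.markers.subset(plan.training_ids, snp))
        a22 = a.subset(plan.training_ids)
        g_adj, _ = adjust_genomic_to_pedigree(g, a22)
        h, _ = hybrid_matrix(a, g_adj, plan.training_ids)
        return h
    if families is None:
        families = _candidate_families(program, plan)
    training_markers = program.markers.subset(plan.training_ids, snp)
    if model == "mblup":
        rows = midparent_genotypes(families, program.markers.subset(marker_ids=snp))
        return family_augmented_matrix(training_markers, rows, plan.family_of)
    if model in ("fblup_gbs", "fblup_array"):
        rows = bulk_genotypes(families, program.markers.subset(marker_ids=snp))
        if model == "fblup_array":
            rows = round_bulk(rows)
        return family_augmented_matrix(training_markers, rows, plan.family_of)
    raise ValueError(f"unknown model {model!r}")


def run_models(
    plan: SplitPlan,
    program: SimProgram,
    model_set=ALL_MODELS,
    with_preexisting_info: bool = False,
    seed: int | None = None,
) -> dict:
    """Fit every requested model on one plan and predict the candidates.

    Training records are the training lines' noisy breeding values at
    ``plan.h2_train``; candidate pre-existing records (used by PHENO always,
    and by the other models when ``with_preexisting_info``) are noised at
    ``plan.h2_validation``.  Returns ``{"gebv": {model: Series}, "tbv":
    Series, "records": Series, "training_records": Series}``.
    """
    seed = plan.seed if seed is None else seed
    train_bv = add_phenotyping_noise(
        program.tbv.loc[plan.training_ids], plan.h2_train, seed=seed
    )
    cand_bv = add_phenotyping_noise(
        program.tbv.loc[plan.validation_ids], plan.h2_validation, seed=seed + 1
    )
    y_train = train_bv.ebv
    y_cand = cand_bv.ebv

    gebvs: dict = {}
    for model in model_set:
        if model == "pheno":
            gebvs[model] = y_cand.copy()
            continue
        kernel = build_kernel(model, program, plan)
        if with_preexisting_info:
            y = pd.concat([y_train, y_cand])
            groups = pd.Series(
                ["train"] * len(y_train) + ["cand"] * len(y_cand), index=y.index
            )
            fit = fit_group_model(y, groups, kernel, heterogeneous=True)
            shift = fit.mu + fit.group_effects["cand"]
        else:
            fit = fit_single_kernel(y_train, kernel)
            shift = fit.mu
        gebvs[model] = shift + fit.g.loc[plan.validation_ids]
    return {
        "gebv": gebvs,
        "tbv": program.tbv.loc[plan.validation_ids],
        "records": y_cand,
        "training_records": y_train,
    }


# ---------------------------------------------------------------------------
# metrics


def prediction_ability(predicted, observed) -> float:
    """Pearson correlation of predictions with observed values (ability) or
    with true breeding values (accuracy)."""
    p = pd.Series(predicted, dtype=float)
    o = pd.Series(observed, dtype=float)
    if isinstance(predicted, pd.Series) and isinstance(observed, pd.Series):
        o = o.reindex(p.index)
    if len(p) < 3 or len(p) != len(o) or o.isna().any():
        raise ValueError("need >= 3 aligned pairs")
    if float(p.var()) <= 0 or float(o.var()) <= 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(p.to_numpy(), o.to_numpy())[0, 1])


def _top_k_ids(values: pd.Series, k: int) -> list:
    """Ids of the k largest values; ties broken by stable line-id order."""
    s = values.sort_index()
    order = np.argsort(-s.to_numpy(), kind="stable")
    return list(s.index[order[:k]])


def relative_selection_gain(predicted, observed, fraction: float) -> float:
    """Percent difference between the observed mean of the predicted-best
    fraction and the overall observed mean (denominator: |overall mean|)."""
    if not (0.2 <= fraction <= 0.8):
        raise ValueError("selection fraction must lie in [0.2, 0.8]")
    p = pd.Series(predicted, dtype=float)
    o = pd.Series(observed, dtype=float).reindex(p.index)
    overall = float(o.mean())
    if abs(overall) < 1e-12:
        raise ValueError("overall mean is zero: relative gain undefined")
    k = math.ceil(fraction * len(p))
    sel = _top_k_ids(p, k)
    return 100.0 * (float(o.loc[sel].mean()) - overall) / abs(overall)


def co_selection(predicted, observed, fraction: float) -> float:
    """Percentage of lines in the predicted top fraction that are also in
    the observed top fraction."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("selection fraction must lie in (0, 1]")
    p = pd.Series(predicted, dtype=float)
    o = pd.Series(observed, dtype=float).reindex(p.index)
    k = math.ceil(fraction * len(p))
    return 100.0 * len(set(_top_k_ids(p, k)) & set(_top_k_ids(o, k))) / k


def compare_models(
    replicate_abilities: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Compact letter display from pairwise paired t-tests on Fisher-z
    transformed abilities (rows = replicates, columns = models).

    Models that share a letter are not significantly different at ``alpha``.
    """
    df = pd.DataFrame(replicate_abilities)
    models = list(df.columns)
    if len(models) < 2:
        raise ValueError("need >= 2 models")
    if df.isna().any().any():
        raise ValueError("abilities must be paired by replicate (no missing)")
    if len(df) < 10:
        raise ValueError("need >= 10 replicates")
    z = np.arctanh(np.clip(df.to_numpy(dtype=float), -0.999999, 0.999999))
    means = df.mean().sort_values(ascending=False)
    ordered = list(means.index)
    nonsig = nx.Graph()
    nonsig.add_nodes_from(models)
    for i, mi in enumerate(models):
        for mj in models[i + 1 :]:
            d = z[:, models.index(mi)] - z[:, models.index(mj)]
            if float(np.std(d)) < 1e-12:
                # degenerate paired test: identical vectors are trivially
                # equal, a constant nonzero shift is trivially different
                p = 1.0 if abs(float(np.mean(d))) < 1e-12 else 0.0
            else:
                p = float(stats.ttest_rel(
                    z[:, models.index(mi)], z[:, models.index(mj)]
                ).pvalue)
            if p >= alpha:
                nonsig.add_edge(mi, mj)
    cliques = list(nx.find_cliques(nonsig))
    cliques.sort(key=lambda c: -max(means[m] for m in c))
    letters = {m: "" for m in models}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for m in clique:
            letters[m] += letter
    return {m: "".join(sorted(letters[m])) for m in ordered}


def overrepresentation_experiment(
    plan: SplitPlan,
    program: SimProgram,
    biased_family_counts=(0, 2, 4),
    overweight_factors=(1.0, 2.0, 4.0),
    rounded: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooling-error stress test for the family-bulk models.

    For each grid point, one random member of each of ``n`` affected
    families contributes ``factor`` times the DNA of its sibs to the bulk.
    Returns a tidy frame (overweight_factor, n_biased_families, accuracy)
    including the unbiased baseline (factor 1 or 0 biased families).
    """
    if min(overweight_factors) < 1.0:
        raise ValueError("overweight factor must be >= 1")
    base_families = _candidate_families(program, plan)
    train_bv = add_phenotyping_noise(
        program.tbv.loc[plan.training_ids], plan.h2_train, seed=plan.seed
    )
    snp = program.snp_marker_ids
    training_markers = program.markers.subset(plan.training_ids, snp)
    member_markers = program.markers.subset(marker_ids=snp)
    rng = np.random.default_rng(seed)
    rows = []
    for factor in overweight_factors:
        for n_biased in biased_family_counts:
            if n_biased > len(base_families):
                raise ValueError("more biased families than families in plan")
            fams = []
            biased_idx = set(
                rng.choice(len(base_families), size=n_biased, replace=False)
            )
            for k, fam in enumerate(base_families):
                if k in biased_idx and factor > 1.0:
                    w = np.ones(len(fam.member_line_ids))
                    w[int(rng.integers(0, len(w)))] = factor
                    fams.append(
                        FamilyMap(
                            fam.family_id, fam.parent1_id, fam.parent2_id,
                            list(fam.member_line_ids), weights=w,
                        )
                    )
                else:
                    fams.append(fam)
            bulk = bulk_genotypes(fams, member_markers)
            if rounded:
                bulk = round_bulk(bulk)
            kernel = family_augmented_matrix(training_markers, bulk, plan.family_of)
            fit = fit_single_kernel(train_bv.ebv, kernel)
            acc = prediction_ability(
                fit.mu + fit.g.loc[plan.validation_ids],
                program.tbv.loc[plan.validation_ids],
            )
            rows.append((factor, n_biased, acc))
    return pd.DataFrame(
        rows, columns=["overweight_factor", "n_biased_families", "accuracy"]
    )
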