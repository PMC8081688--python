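"""Validation designs, the model runner and the evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import famblup as fb


def synthetic_families(n=63, min_size=4, max_size=12, seed=0):
    rng = np.random.default_rng(seed)
    fams = []
    for i in range(n):
        size = int(rng.integers(min_size, max_size + 1))
        fams.append(
            fb.FamilyMap(
                f"fam{i}", f"p{i}a", f"p{i}b",
                [f"fam{i}_l{j}" for j in range(size)],
            )
        )
    return fams


class TestEmpiricalPlan:
    def test_population_counts(self):
        plans = fb.empirical_cv_plan(synthetic_families(), n_reps=5, seed=1)
        for plan in plans:
            assert len(plan.training_ids) == 180
            assert len(plan.validation_ids) == 60
            train_fams = {i.rsplit("_", 1)[0] for i in plan.training_ids}
            val_fams = {i.rsplit("_", 1)[0] for i in plan.validation_ids}
            assert not train_fams & val_fams
            assert len(val_fams) == 15

    def test_reproducible_given_seed(self):
        a = fb.empirical_cv_plan(synthetic_families(), n_reps=1, seed=7)[0]
        b = fb.empirical_cv_plan(synthetic_families(), n_reps=1, seed=7)[0]
        assert a.training_ids == b.training_ids
        assert a.validation_ids == b.validation_ids

    def test_minimum_size_family_fully_used(self):
        fams = synthetic_families(n=60, min_size=4, max_size=4, seed=2)
        plans = fb.empirical_cv_plan(fams, n_reps=3, seed=3)
        for plan in plans:
            used = plan.training_ids + plan.validation_ids
            by_fam = pd.Series([i.rsplit("_", 1)[0] for i in used]).value_counts()
            assert (by_fam == 4).all()

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError, match="families"):
            fb.empirical_cv_plan(synthetic_families(n=30), n_reps=1, seed=0)


class TestSchemeA:
    def test_counts_and_disjointness(self, small_program):
        plans = fb.simulation_scheme_A(
            small_program, n_training=60, n_candidates=50, n_reps=3, seed=5
        )
        for plan in plans:
            assert len(plan.training_ids) == 60
            assert len(plan.validation_ids) == 50
            assert not set(plan.training_ids) & set(plan.validation_ids)
            assert not set(plan.training_ids) & set(small_program.parent_ids)

    def test_full_fraction_is_simple_random_sample(self, small_program):
        plan = fb.simulation_scheme_A(
            small_program, preselect_top_fraction=1.0,
            n_training=60, n_candidates=50, n_reps=1, seed=6,
        )[0]
        assert set(plan.validation_ids) <= set(small_program.progeny_ids)

    def test_preselection_respects_quantile(self, small_program):
        frac = 0.5
        plan = fb.simulation_scheme_A(
            small_program, preselect_top_fraction=frac,
            n_training=60, n_candidates=40, n_reps=1, seed=7,
        )[0]
        pool_tbv = small_program.tbv.loc[small_program.progeny_ids]
        threshold = pool_tbv.quantile(1 - frac)
        assert (small_program.tbv.loc[plan.validation_ids] >= threshold - 1e-9).all()

    def test_candidate_mean_tbv_increases_with_preselection(self, small_program):
        means = []
        for frac in (1.0, 0.6, 0.3):
            plans = fb.simulation_scheme_A(
                small_program, preselect_top_fraction=frac,
                n_training=60, n_candidates=40, n_reps=5, seed=8,
            )
            means.append(
                np.mean([small_program.tbv.loc[p.validation_ids].mean() for p in plans])
            )
        assert means[0] < means[1] < means[2]

    def test_parents_in_training(self, small_program):
        plan = fb.simulation_scheme_A(
            small_program, parents_in_training=True,
            n_training=60, n_candidates=40, n_reps=1, seed=9,
        )[0]
        assert set(small_program.parent_ids) <= set(plan.training_ids)
        assert len(plan.training_ids) == 60

    def test_fraction_outside_grid_rejected(self, small_program):
        with pytest.raises(ValueError, match="0.3"):
            fb.simulation_scheme_A(small_program, preselect_top_fraction=0.2)


class TestSchemeB:
    @pytest.mark.parametrize("k,expected", [(1, 8), (5, 40)])
    def test_candidate_counts(self, small_program, k, expected):
        plan = fb.simulation_scheme_B(
            small_program, lines_per_family=k, n_training=60, n_reps=1, seed=10
        )[0]
        assert len(plan.validation_ids) == expected
        per_fam = pd.Series(list(plan.family_of.values())).value_counts()
        assert (per_fam == k).all()

    def test_oversized_family_request_rejected(self, small_program):
        with pytest.raises(ValueError, match="lines_per_family"):
            fb.simulation_scheme_B(small_program, lines_per_family=21)

    def test_singleton_bulk_kernel_equals_blended_individual_kernel(
        self, small_program
    ):
        # one line per family: the bulk is the line's own genotype, so the
        # family-bulk kernel is 0.5*G(individual) + 0.5*I
        plan = fb.simulation_scheme_B(
            small_program, lines_per_family=1, n_training=60, n_reps=1, seed=11
        )[0]
        from famblup.validation import build_kernel

        kernel = build_kernel("fblup_gbs", small_program, plan)
        ids = list(plan.training_ids) + list(plan.validation_ids)
        g = fb.genomic_matrix(
            small_program.markers.subset(ids, small_program.snp_marker_ids)
        )
        expected = 0.5 * g.values.to_numpy() + 0.5 * np.eye(len(ids))
        got = kernel.values.loc[ids, ids].to_numpy()
        assert np.allclose(got, expected, atol=1e-10)


class TestRunModels:
    def test_family_models_cannot_differentiate_within_family(self, small_program):
        plan = fb.simulation_scheme_B(
            small_program, lines_per_family=4, n_training=60, n_reps=1, seed=12
        )[0]
        res = fb.run_models(
            plan, small_program, model_set=("mblup", "fblup_gbs", "fblup_array"),
            with_preexisting_info=False,
        )
        fam = pd.Series(plan.family_of)
        for model, pred in res["gebv"].items():
            spread = pred.groupby(fam).std()
            assert (spread < 1e-8).all(), model

    def test_all_models_return_candidate_predictions(self, small_program):
        plan = fb.simulation_scheme_B(
            small_program, lines_per_family=3, n_training=60, n_reps=1, seed=13
        )[0]
        res = fb.run_models(plan, small_program, with_preexisting_info=False)
        for model, pred in res["gebv"].items():
            assert list(pred.index) == plan.validation_ids

    def test_preexisting_info_breaks_family_ties(self, small_program):
        plan = fb.simulation_scheme_B(
            small_program, lines_per_family=4, n_training=60, n_reps=1, seed=14
        )[0]
        res = fb.run_models(
            plan, small_program, model_set=("mblup",), with_preexisting_info=True
        )
        fam = pd.Series(plan.family_of)
        spread = res["gebv"]["mblup"].groupby(fam).std()
        assert (spread > 1e-6).any()


class TestMetrics:
    def test_prediction_ability_extremes(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert fb.prediction_ability(x, x) == pytest.approx(1.0)
        assert fb.prediction_ability(x, -x) == pytest.approx(-1.0)

    def test_prediction_ability_hand_value(self):
        # r for (1,2,3) vs (2,4,7): cov=5/2 over sqrt(1 * 57/9) ... = 0.99340
        r = fb.prediction_ability(pd.Series([1.0, 2, 3]), pd.Series([2.0, 4, 7]))
        assert r == pytest.approx(5 / np.sqrt(2 * 114 / 9), abs=1e-10)
        assert r == pytest.approx(0.9934, abs=1e-4)

    def test_prediction_ability_null(self, rng):
        a = pd.Series(rng.standard_normal(10_000))
        b = pd.Series(rng.standard_normal(10_000))
        assert abs(fb.prediction_ability(a, b)) < 0.05

    def test_prediction_ability_errors(self):
        with pytest.raises(ValueError):
            fb.prediction_ability(pd.Series([1.0, 2]), pd.Series([1.0, 2]))
        with pytest.raises(ValueError, match="zero variance"):
            fb.prediction_ability(pd.Series([1.0, 1, 1]), pd.Series([1.0, 2, 3]))

    def test_selection_gain_identity_prediction(self):
        obs = pd.Series([12.0, 12.0, 10.0, 9.0, 8.0, 9.0, 10.0, 10.0, 10.0, 10.0])
        gain = fb.relative_selection_gain(obs, obs, 0.2)
        assert gain == pytest.approx(100 * (12 - 10) / 10)

    def test_selection_gain_constant_observations(self, rng):
        pred = pd.Series(rng.standard_normal(10))
        obs = pd.Series(5.0, index=pred.index)
        assert fb.relative_selection_gain(pred, obs, 0.5) == 0.0

    def test_selection_gain_random_predictor_unbiased(self, rng):
        obs = pd.Series(rng.normal(10, 2, 50))
        gains = []
        for _ in range(400):
            pred = pd.Series(rng.standard_normal(50), index=obs.index)
            gains.append(fb.relative_selection_gain(pred, obs, 0.2))
        assert abs(np.mean(gains)) < 1.0

    def test_selection_gain_zero_mean_rejected(self):
        obs = pd.Series([-1.0, 1.0, -2.0, 2.0])
        with pytest.raises(ValueError, match="zero"):
            fb.relative_selection_gain(obs, obs, 0.5)

    def test_co_selection_extremes(self):
        x = pd.Series(np.arange(10.0))
        assert fb.co_selection(x, x, 0.2) == 100.0
        assert fb.co_selection(x, -x, 0.2) == 0.0

    def test_co_selection_hand_count(self):
        # top-2 of predicted = {l8, l9}; top-2 of observed = {l9, l0}: share 1
        pred = pd.Series(np.arange(10.0), index=[f"l{i}" for i in range(10)])
        obs = pred.copy()
        obs["l0"] = 11.0  # now observed top-2 is {l0, l9}
        assert fb.co_selection(pred, obs, 0.2) == 50.0

    def test_co_selection_random_matches_hypergeometric_mean(self, rng):
        n, k = 40, 8
        vals = []
        base = pd.Series(rng.standard_normal(n))
        for _ in range(500):
            pred = pd.Series(rng.standard_normal(n), index=base.index)
            vals.append(fb.co_selection(pred, base, k / n))
        assert np.mean(vals) == pytest.approx(100 * k / n, abs=2.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 9999), frac=st.sampled_from([0.2, 0.4, 0.6, 0.8]))
    def test_co_selection_bounds(self, seed, frac):
        rng = np.random.default_rng(seed)
        pred = pd.Series(rng.standard_normal(25))
        obs = pd.Series(rng.standard_normal(25))
        v = fb.co_selection(pred, obs, frac)
        assert 0.0 <= v <= 100.0


class TestCompareModels:
    def test_identical_vectors_share_a_letter(self, rng):
        a = rng.normal(0.3, 0.1, 30)
        letters = fb.compare_models(pd.DataFrame({"m1": a, "m2": a}))
        assert letters["m1"] == letters["m2"]

    def test_constant_shift_gets_distinct_letters(self, rng):
        a = rng.normal(0.2, 0.05, 100)
        letters = fb.compare_models(pd.DataFrame({"m1": a, "m2": a + 0.2}))
        assert letters["m1"] != letters["m2"]

    def test_overlapping_groups_pattern(self):
        rng = np.random.default_rng(41)
        n = 100
        base = rng.normal(0, 0.3, n)
        df = pd.DataFrame(
            {
                "A": base + rng.normal(0, 0.6, n),
                "B": base + 0.13 + rng.normal(0, 0.6, n),
                "C": base + 0.26 + rng.normal(0, 0.6, n),
            }
        ).clip(-0.97, 0.97)
        letters = fb.compare_models(df)
        assert letters["C"] == "a" and letters["A"] == "b" and letters["B"] == "ab"

    def test_unpaired_inputs_rejected(self, rng):
        df = pd.DataFrame({"m1": rng.normal(0, 0.1, 20), "m2": rng.normal(0, 0.1, 20)})
        df.loc[3, "m2"] = np.nan
        with pytest.raises(ValueError, match="paired"):
            fb.compare_models(df)


class TestOverrepresentation:
    def test_factor_one_identical_to_baseline(self, small_program):
        plan = fb.simulation_scheme_B(
            small_program, lines_per_family=5, n_training=60, n_reps=1, seed=15
        )[0]
        df = fb.overrepresentation_experiment(
            plan, small_program, biased_family_counts=(0, 4),
            overweight_factors=(1.0,), seed=0,
        )
        assert df["accuracy"].nunique() == 1

    def test_factor_below_one_rejected(self, small_program):
        plan = fb.simulation_scheme_B(
            small_program, lines_per_family=3, n_training=60, n_reps=1, seed=16
        )[0]
        with pytest.raises(ValueError, match=">= 1"):
            fb.overrepresentation_experiment(
                plan, small_program, overweight_factors=(0.5,), seed=0
            )

    def test_strong_bias_degrades_mean_accuracy(self):
        # large bulks, every family biased toward one member at 20x
        program = fb.simulate_breeding_program(
            n_families=10, progeny_per_family=30, n_pool=140,
            n_chromosomes=5, markers_per_chromosome=80, n_qtl=50, n_snp=300,
            seed=22,
        )
        plans = fb.simulation_scheme_B(
            program, lines_per_family=20, n_training=90, n_reps=12, seed=52
        )
        frames = []
        for plan in plans:
            frames.append(
                fb.overrepresentation_experiment(
                    plan, program, biased_family_counts=(0, 10),
                    overweight_factors=(1.0, 20.0), seed=plan.seed,
                )
            )
        out = pd.concat(frames)
        baseline = out[(out.overweight_factor == 1.0) & (out.n_biased_families == 0)]
        biased = out[(out.overweight_factor == 20.0) & (out.n_biased_families == 10)]
        assert biased["accuracy"].mean() < baseline["accuracy"].mean()
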