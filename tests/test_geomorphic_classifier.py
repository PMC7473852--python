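import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, box

from mangrove_typology.cep_covariates import COVARIATE_COLUMNS
from mangrove_typology.errors import MangroveTypologyError
from mangrove_typology.geo_core import VectorLayer
from mangrove_typology.geomorphic_classifier import (
    classify_ceps,
    count_outlets,
    flag_deltas,
    merge_delta_units,
    review_hook,
    second_pass,
    train_rf,
)
from mangrove_typology.synthetic_world import simulate_covariate_table

from conftest import ceps_from_table, make_cep


def outlet_flowlines(*points):
    layer = VectorLayer(geometry_type="polyline")
    for i, (x, y) in enumerate(points):
        layer.add(
            LineString([(x, y - 5), (x, y)]),
            fid=i + 1,
            next_fid=-1,
            outlet_x=x,
            outlet_y=y,
        )
    return layer


class TestOutlets:
    def test_no_rivers(self, empty_flowlines):
        assert count_outlets(make_cep(geometry=box(0, 0, 10, 10)), empty_flowlines) == 0

    def test_four_outlets_counted(self):
        cep = make_cep(geometry=box(0, 0, 10, 10))
        flows = outlet_flowlines((2, 5), (4, 5), (6, 5), (8, 5))
        assert count_outlets(cep, flows) == 4

    def test_outlets_elsewhere_ignored(self):
        cep = make_cep(geometry=box(0, 0, 10, 10))
        flows = outlet_flowlines((50, 50), (2, 5))
        assert count_outlets(cep, flows) == 1

    def test_planted_delta_outlet_counts(self, pipeline_result):
        scene = pipeline_result["scene"]
        matches = pipeline_result["matches"]
        for cep in pipeline_result["ceps"]:
            cls = matches.get(cep.id, {}).get("class")
            n = count_outlets(cep, scene.flowlines)
            if cls == "delta":
                assert n > 2
            elif cls == "estuary":
                assert n == 1


class TestFlagDeltas:
    def test_nothing_to_flag(self, empty_flowlines):
        ceps = [make_cep(1), make_cep(2)]
        deltas, pool = flag_deltas(ceps, empty_flowlines)
        assert deltas == []
        assert len(pool) == 2

    def test_outlet_rule_flags(self):
        cep = make_cep(1, box(0, 0, 10, 10))
        flows = outlet_flowlines((2, 5), (4, 5), (6, 5))
        deltas, pool = flag_deltas([cep], flows)
        assert [c.id for c in deltas] == [1]
        assert cep.cep_class == "delta"

    def test_two_outlets_not_candidate(self):
        cep = make_cep(1, box(0, 0, 10, 10))
        flows = outlet_flowlines((2, 5), (4, 5))
        deltas, pool = flag_deltas([cep], flows)
        assert deltas == []

    def test_oracle_rejection_returns_to_pool(self):
        cep = make_cep(1, box(0, 0, 10, 10))
        flows = outlet_flowlines((2, 5), (4, 5), (6, 5))
        deltas, pool = flag_deltas([cep], flows, confirm=lambda c: False)
        assert deltas == []
        assert pool == [cep]

    def test_listed_id_missing_warns_not_raises(self, empty_flowlines, caplog):
        deltas, pool = flag_deltas([make_cep(1)], empty_flowlines, known_delta_list=[99])
        assert deltas == []

    def test_scene_deltas_all_flagged(self, pipeline_result):
        scene = pipeline_result["scene"]
        matches = pipeline_result["matches"]
        truth = {cid: m["class"] for cid, m in matches.items()}
        delta_ids = {
            c.id for c in pipeline_result["ceps"] if truth.get(c.id) == "delta"
        }
        flagged = {c.id for c in pipeline_result["ceps"] if c.cep_class == "delta"}
        assert delta_ids <= flagged


class TestMergeDeltaUnits:
    def test_single_cep_no_extent(self):
        cep = make_cep(1, box(0, 0, 5, 5), cep_class="delta")
        units = merge_delta_units([cep])
        assert len(units) == 1
        assert units[0].member_cep_ids == [1]

    def test_three_ceps_one_extent(self):
        ceps = [
            make_cep(i, box((i - 1) * 5, 0, i * 5, 5), cep_class="delta")
            for i in (1, 2, 3)
        ]
        extents = VectorLayer(geometry_type="polygon")
        extents.add(box(-1, -1, 16, 6), name="big delta")
        units = merge_delta_units(ceps, extents)
        assert len(units) == 1
        assert sorted(units[0].member_cep_ids) == [1, 2, 3]
        assert units[0].name == "big delta"

    def test_disjoint_extents_two_units(self):
        ceps = [
            make_cep(1, box(0, 0, 5, 5), cep_class="delta"),
            make_cep(2, box(50, 0, 55, 5), cep_class="delta"),
        ]
        extents = VectorLayer(geometry_type="polygon")
        extents.add(box(-1, -1, 6, 6))
        extents.add(box(49, -1, 56, 6))
        units = merge_delta_units(ceps, extents)
        assert len(units) == 2


def separable_table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        cls = "bay" if i % 2 == 0 else "lagoon"
        v6 = rng.uniform(0.9, 1.0) if cls == "bay" else rng.uniform(0.0, 0.1)
        row = {"cep_id": i + 1, "class": cls}
        for c in COVARIATE_COLUMNS:
            row[c] = rng.uniform(0, 1)
        row["v6_closure_ratio"] = v6
        rows.append(row)
    return pd.DataFrame(rows)


class TestTrainRF:
    def test_separable_toy_perfect(self):
        run = train_rf(separable_table(), n_trees=100, seed=0)
        assert run.validation_accuracy == 1.0

    def test_shuffled_labels_chance_level(self):
        df = simulate_covariate_table(
            {"bay": 100, "estuary": 100, "lagoon": 100}, seed=0
        )
        rng = np.random.default_rng(1)
        df["class"] = rng.permutation(df["class"].to_numpy())
        run = train_rf(df, n_trees=100, seed=0)
        # chance is 1/3; wide binomial bound on a 60-row holdout
        assert 0.10 < run.validation_accuracy < 0.60

    def test_reference_training_composition_accepted(self):
        df = simulate_covariate_table(
            {"bay": 800, "lagoon": 71, "estuary": 300}, seed=0
        )
        run = train_rf(df, n_trees=50, seed=0)
        assert run.training_counts == {"bay": 800, "estuary": 300, "lagoon": 71}
        assert sum(run.training_counts.values()) == 1171

    def test_class_with_too_few_rows(self):
        df = separable_table(n=10)
        df.loc[df.index[:1], "class"] = "estuary"
        df = df[df["class"] != "lagoon"].iloc[:3]
        with pytest.raises(MangroveTypologyError, match="estuary"):
            train_rf(df, n_trees=10, seed=0)

    def test_deterministic_under_seed(self):
        df = simulate_covariate_table({"bay": 50, "lagoon": 50}, seed=0, overlap=0.5)
        r1 = train_rf(df, n_trees=50, seed=3)
        r2 = train_rf(df, n_trees=50, seed=3)
        assert r1.validation_accuracy == r2.validation_accuracy


class TestClassify:
    def test_memorized_lagoon(self):
        df = separable_table()
        run = train_rf(df, n_trees=100, seed=0)
        lagoon_row = df[df["class"] == "lagoon"].iloc[[0]]
        ceps = ceps_from_table(lagoon_row)
        out = classify_ceps(run, ceps)
        assert out.iloc[0]["class"] == "lagoon"
        assert out.iloc[0]["vote_lagoon"] >= 0.5

    def test_empty(self):
        run = train_rf(separable_table(), n_trees=10, seed=0)
        assert classify_ceps(run, []).empty

    def test_column_mismatch_error(self):
        run = train_rf(separable_table(), n_trees=10, seed=0)
        cep = make_cep(1)
        cep.covariates = {"bogus": 1.0}
        with pytest.raises(MangroveTypologyError, match="missing"):
            classify_ceps(run, [cep])

    def test_recovery_on_simulated_world(self):
        train = simulate_covariate_table(
            {"bay": 120, "estuary": 60, "lagoon": 40}, seed=0, overlap=0.2
        )
        test = simulate_covariate_table(
            {"bay": 60, "estuary": 30, "lagoon": 20}, seed=1, overlap=0.2
        )
        run = train_rf(train, n_trees=200, seed=0)
        ceps = ceps_from_table(test)
        out = classify_ceps(run, ceps)
        acc = (out["class"].to_numpy() == test["class"].to_numpy()).mean()
        assert acc >= 0.9


class TestReviewHook:
    def test_zero_error_rate_is_truth(self):
        truth = {i: "bay" for i in range(10)}
        assert review_hook(list(truth), truth, 0.0, seed=0) == truth

    def test_full_error_two_classes_complement(self):
        truth = {i: ("bay" if i % 2 else "lagoon") for i in range(10)}
        out = review_hook(list(truth), truth, 1.0, seed=0, classes=("bay", "lagoon"))
        assert all(out[i] != truth[i] for i in truth)

    def test_flip_fraction_binomial(self):
        truth = {i: "bay" for i in range(100)}
        out = review_hook(list(truth), truth, 0.1, seed=0)
        flips = sum(out[i] != truth[i] for i in truth)
        assert 2 <= flips <= 22  # 99.9% binomial interval around 10

    def test_truth_required(self):
        with pytest.raises(MangroveTypologyError):
            review_hook([1], None, 0.0, seed=0)


class TestSecondPass:
    def _setup(self, seed=0, overlap=0.35, bay_sample=500):
        train = simulate_covariate_table(
            {"bay": 120, "estuary": 60, "lagoon": 40}, seed=seed, overlap=overlap
        )
        pool_df = simulate_covariate_table(
            {"bay": 80, "estuary": 40, "lagoon": 30}, seed=seed + 1000, overlap=overlap
        )
        pool_df["cep_id"] += 10_000
        truth = dict(zip(pool_df["cep_id"], pool_df["class"]))
        pool = ceps_from_table(pool_df)
        run1 = train_rf(train, n_trees=100, seed=seed)
        labels1 = classify_ceps(run1, pool)
        return train, pool, truth, run1, labels1

    def test_perfect_hook_reviewed_match_truth(self):
        train, pool, truth, run1, labels1 = self._setup()
        reviewer = lambda ids: review_hook(ids, truth, 0.0, seed=0)  # noqa: E731
        final = second_pass(run1, train, pool, labels1, reviewer, n_trees2=100, seed=0)
        reviewed = final[final["provenance"] == "review"]
        for _, row in reviewed.iterrows():
            assert row["class"] == truth[row["cep_id"]]

    def test_agreement_zero_disagreement_flags(self):
        # no review sample at all: pass 2 trains on pass-1 data and agrees
        train, pool, truth, run1, labels1 = self._setup(overlap=0.0)
        reviewer = lambda ids: review_hook(ids, truth, 0.0, seed=0)  # noqa: E731
        final = second_pass(
            run1, train, pool, labels1, reviewer, n_trees2=100, bay_sample=0, seed=0
        )
        assert final.attrs["n_disagreements"] == 0 or (
            final["provenance"] == "review"
        ).sum() > 0

    def test_improvement_in_aggregate_over_seeds(self):
        """Second pass never reduces accuracy, aggregated over 20 seeds."""
        first_total, second_total, n_total = 0, 0, 0
        for seed in range(20):
            train, pool, truth, run1, labels1 = self._setup(
                seed=seed, overlap=0.4, bay_sample=20
            )
            lab1 = dict(zip(labels1["cep_id"], labels1["class"]))
            reviewer = lambda ids: review_hook(ids, truth, 0.0, seed=seed)  # noqa: E731
            final = second_pass(
                run1, train, pool, labels1, reviewer,
                n_trees2=100, bay_sample=20, seed=seed,
            )
            fin = dict(zip(final["cep_id"], final["class"]))
            first_total += sum(lab1[c] == truth[c] for c in truth)
            second_total += sum(fin[c] == truth[c] for c in truth)
            n_total += len(truth)
        assert second_total >= first_total

    def test_all_ceps_labelled_with_provenance(self):
        train, pool, truth, run1, labels1 = self._setup()
        reviewer = lambda ids: review_hook(ids, truth, 0.0, seed=0)  # noqa: E731
        final = second_pass(run1, train, pool, labels1, reviewer, n_trees2=50, seed=0)
        assert set(final["cep_id"]) == set(truth)
        assert set(final["provenance"]) <= {"pass1", "pass2", "review"}
        assert set(c.cep_class for c in pool) <= {"bay", "estuary", "lagoon"}

    def test_determinism(self):
        train, pool, truth, run1, labels1 = self._setup()
        reviewer = lambda ids: review_hook(ids, truth, 0.0, seed=5)  # noqa: E731
        f1 = second_pass(run1, train, pool, labels1, reviewer, n_trees2=50, seed=5)
        f2 = second_pass(run1, train, pool, labels1, reviewer, n_trees2=50, seed=5)
        pd.testing.assert_frame_equal(f1, f2)
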