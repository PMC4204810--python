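import numpy as np
import pytest
from hypothesis import given, strategies as st

from trajmix.latent_models import ModelParams, ModelSpec
from trajmix.synthetic_cohort import (
    AgeGrid,
    CohortTable,
    GenerativeTruth,
    MissingnessPlan,
    default_truth,
    derive_asthma,
    derive_sensitised,
    filter_mild_eczema,
    filter_min_timepoints,
    generate_cohort,
    structural_cells,
    with_asthma_panel,
)

from conftest import build_cohort


class TestAgeGrid:
    def test_default(self):
        grid = AgeGrid()
        assert grid.ages == (1, 3, 5, 8, 11)
        assert len(grid) == 5

    @pytest.mark.parametrize("ages", [(1,), (3, 1), (1, 1, 5)])
    def test_invalid(self, ages):
        with pytest.raises(ValueError):
            AgeGrid(ages)


def _truth(weights, emit, sizes=(100,), seed=0, plan=None):
    params = ModelParams("latent_profile", np.asarray(weights, dtype=float), emit=np.asarray(emit, dtype=float))
    return GenerativeTruth(
        model_spec=ModelSpec("latent_profile", len(weights)),
        params=params,
        cohort_sizes=sizes,
        missingness=plan or MissingnessPlan(),
        seed=seed,
    )


class TestGenerateCohort:
    def test_degenerate_all_ones(self):
        truth = _truth([1.0], np.ones((1, 3, 5)), sizes=(50,))
        cohort, _ = generate_cohort(truth)
        assert (cohort.y[cohort.y_mask] == 1).all()

    def test_mixture_prevalence_within_3_mc_se(self):
        # closed-form mixture prevalence vs empirical cell means at n=20,000
        emit = np.stack([np.full((3, 5), 0.9), np.full((3, 5), 0.2)])
        truth = _truth([0.5, 0.5], emit, sizes=(20000,), seed=7)
        cohort, _ = generate_cohort(truth)
        expected = 0.5 * 0.9 + 0.5 * 0.2
        se = np.sqrt(expected * (1 - expected) / 20000)
        observed = cohort.y.mean(axis=0)
        assert np.all(np.abs(observed - expected) < 3 * se)

    def test_structural_mask(self):
        plan = MissingnessPlan(structural={("B", "rhinitis", 1), ("B", "rhinitis", 3)})
        truth = _truth([1.0], np.full((1, 3, 5), 0.5), sizes=(30, 40), seed=3, plan=plan)
        cohort, _ = generate_cohort(truth)
        b = cohort.cohort == "B"
        r = cohort.symptoms.index("rhinitis")
        assert not cohort.y_mask[b, r, 0].any()
        assert not cohort.y_mask[b, r, 1].any()
        assert cohort.y_mask[~b, r, 0].all()

    def test_seeded_generation_reproducible(self):
        truth = default_truth(seed=5, cohort_sizes=(200, 50))
        a, la = generate_cohort(truth)
        b, lb = generate_cohort(truth)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.y_mask, b.y_mask)
        assert np.array_equal(la, lb)

    def test_invalid_probability_rejected(self):
        truth = _truth([1.0], np.full((1, 3, 5), 1.5))
        with pytest.raises(ValueError):
            generate_cohort(truth)

    def test_attrition_is_monotone(self):
        plan = MissingnessPlan(attrition=(0.0, 0.1, 0.1, 0.1, 0.1))
        truth = _truth([1.0], np.full((1, 3, 5), 0.5), sizes=(500,), seed=2, plan=plan)
        cohort, _ = generate_cohort(truth)
        seen = cohort.y_mask.any(axis=1)  # (N, T)
        for t in range(4):
            assert not (~seen[:, t] & seen[:, t + 1]).any()


class TestDeriveAsthma:
    @pytest.mark.parametrize(
        "features,expected",
        [((1, 1, 0), 1), ((0, 0, 1), 0), ((1, 1, 1), 1), ((0, 0, 0), 0)],
    )
    def test_examples(self, features, expected):
        assert derive_asthma(*features) == expected

    def test_missing_propagates(self):
        assert derive_asthma(1, 0, None) is None
        assert derive_asthma(0, 0, None) is None

    def test_two_positives_override_missing(self):
        assert derive_asthma(1, 1, None) == 1

    @given(st.permutations([1, 0, None]))
    def test_symmetric(self, perm):
        assert derive_asthma(*perm) == derive_asthma(*reversed(perm))

    @given(
        st.sampled_from([0, 1, None]),
        st.sampled_from([0, 1, None]),
        st.sampled_from([0, 1, None]),
    )
    def test_matches_definition(self, w, m, d):
        out = derive_asthma(w, m, d)
        n_pos = sum(1 for f in (w, m, d) if f == 1)
        if n_pos >= 2:
            assert out == 1
        elif None in (w, m, d):
            assert out is None
        else:
            assert out == 0


class TestDeriveSensitised:
    def test_threshold_met(self):
        assert derive_sensitised((5.0, 1.0), 2.0) == 1

    def test_below_threshold(self):
        assert derive_sensitised((4.9,), 2.0) == 0

    def test_no_reaction(self):
        assert derive_sensitised((0.0, 0.0), 0.0) == 0

    def test_empty_is_missing(self):
        assert derive_sensitised((), 1.0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            derive_sensitised((-1.0,), 0.0)


class TestFilterMinTimepoints:
    def test_single_observation_dropped(self):
        y = np.zeros((2, 3, 5), dtype=np.int8)
        mask = np.ones((2, 3, 5), dtype=bool)
        mask[0, 0, 1:] = False  # eczema observed once only for child 0
        out = filter_min_timepoints(build_cohort(y, mask), k=2)
        assert out.n_children == 1
        assert out.child_id[0] == "c0001"

    def test_fully_observed_retained(self):
        y = np.zeros((1, 3, 5), dtype=np.int8)
        out = filter_min_timepoints(build_cohort(y, np.ones_like(y, dtype=bool)), k=2)
        assert out.n_children == 1

    def test_toy_table_survivors_match_enumeration(self, rng):
        # independent re-derivation of the rule on a 10-child fixture
        y = np.zeros((10, 3, 5), dtype=np.int8)
        mask = rng.random((10, 3, 5)) < 0.5
        cohort = build_cohort(y, mask)
        expected = [i for i in range(10) if all(mask[i, s].sum() >= 2 for s in range(3))]
        out = filter_min_timepoints(cohort, k=2, exempt_structural=False)
        assert [int(c[1:]) for c in out.child_id] == expected

    def test_structural_exemption(self):
        # cohort B never observes rhinitis: exempt by default
        y = np.zeros((4, 3, 5), dtype=np.int8)
        mask = np.ones((4, 3, 5), dtype=bool)
        mask[:2, 2, :] = False  # children 0,1 in cohort B
        cohort = build_cohort(y, mask, cohort=["B", "B", "A", "A"])
        assert filter_min_timepoints(cohort, k=2).n_children == 4
        assert filter_min_timepoints(cohort, k=2, exempt_structural=False).n_children == 2

    def test_idempotent(self, rng):
        y = np.zeros((50, 3, 5), dtype=np.int8)
        mask = rng.random((50, 3, 5)) < 0.7
        once = filter_min_timepoints(build_cohort(y, mask), k=2)
        twice = filter_min_timepoints(once, k=2)
        assert np.array_equal(once.child_id, twice.child_id)

    def test_k_validation(self):
        y = np.zeros((1, 3, 5), dtype=np.int8)
        with pytest.raises(ValueError):
            filter_min_timepoints(build_cohort(y, np.ones_like(y, dtype=bool)), k=0)


def _mild_eczema_cohort(ecz_age1, rx, rx_obs, ecz_obs=True):
    y = np.zeros((1, 3, 5), dtype=np.int8)
    mask = np.ones((1, 3, 5), dtype=bool)
    y[0, 0, 0] = ecz_age1
    if not ecz_obs:
        mask[0, 0, 0] = False
        mask[0, 0, 1] = False
    return build_cohort(
        y,
        mask,
        steroid_rx_by_age3=np.array([rx], dtype=np.int8),
        steroid_rx_mask=np.array([rx_obs]),
    )


class TestFilterMildEczema:
    def test_mild_dropped(self):
        assert filter_mild_eczema(_mild_eczema_cohort(1, 0, True)).n_children == 0

    def test_treated_retained(self):
        assert filter_mild_eczema(_mild_eczema_cohort(1, 1, True)).n_children == 1

    def test_no_early_eczema_missing_rx_retained(self):
        assert filter_mild_eczema(_mild_eczema_cohort(0, 0, False)).n_children == 1

    def test_eczema_with_missing_rx_dropped(self):
        assert filter_mild_eczema(_mild_eczema_cohort(1, 0, False)).n_children == 0

    def test_unknown_early_eczema_dropped(self):
        assert filter_mild_eczema(_mild_eczema_cohort(0, 1, True, ecz_obs=False)).n_children == 0

    def test_idempotent(self, rng):
        y = (rng.random((40, 3, 5)) < 0.3).astype(np.int8)
        mask = rng.random((40, 3, 5)) < 0.8
        cohort = build_cohort(
            y,
            mask,
            steroid_rx_by_age3=(rng.random(40) < 0.5).astype(np.int8),
            steroid_rx_mask=rng.random(40) < 0.9,
        )
        once = filter_mild_eczema(cohort)
        twice = filter_mild_eczema(once)
        assert np.array_equal(once.child_id, twice.child_id)


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        truth = default_truth(seed=8, cohort_sizes=(60, 20), item_rate=0.1)
        cohort, _ = generate_cohort(truth)
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = CohortTable.from_csv(path)
        assert np.array_equal(back.y, cohort.y)
        assert np.array_equal(back.y_mask, cohort.y_mask)
        assert np.array_equal(back.cohort, cohort.cohort)
        assert np.allclose(back.wheal[back.wheal_mask], cohort.wheal[cohort.wheal_mask])

    def test_malformed_value_names_row_and_column(self, tmp_path):
        truth = default_truth(seed=8, cohort_sizes=(5,), with_sensitisation=False)
        cohort, _ = generate_cohort(truth)
        frame = cohort.to_frame()
        frame.loc[2, "eczema_3"] = 7
        with pytest.raises(ValueError, match="eczema_3.*row 2"):
            CohortTable.from_frame(frame)

    def test_missing_column_rejected(self, tmp_path):
        truth = default_truth(seed=8, cohort_sizes=(5,), with_sensitisation=False)
        cohort, _ = generate_cohort(truth)
        frame = cohort.to_frame().drop(columns=["wheeze_5"])
        with pytest.raises(ValueError, match="wheeze_5"):
            CohortTable.from_frame(frame)


class TestAsthmaPanel:
    def test_wheeze_replaced(self):
        y = np.zeros((2, 3, 5), dtype=np.int8)
        mask = np.ones((2, 3, 5), dtype=bool)
        y[0, 1, 0] = 1  # wheeze
        cohort = build_cohort(
            y,
            mask,
            med_use=np.array([[1, 0, 0, 0, 0], [0, 0, 0, 0, 0]], dtype=np.int8),
            med_use_mask=np.ones((2, 5), dtype=bool),
            dx_asthma=np.zeros((2, 5), dtype=np.int8),
            dx_asthma_mask=np.ones((2, 5), dtype=bool),
        )
        out = with_asthma_panel(cohort)
        assert out.symptoms == ("eczema", "asthma", "rhinitis")
        assert out.y[0, 1, 0] == 1  # wheeze + medication
        assert out.y[1, 1, 0] == 0

    def test_structural_cells_detected(self):
        truth = default_truth(seed=1, cohort_sizes=(100, 30), item_rate=0.0)
        cohort, _ = generate_cohort(truth)
        cells = structural_cells(cohort)
        assert ("A", "rhinitis", 1) in cells and ("A", "rhinitis", 3) in cells
        assert not any(c[0] == "B" for c in cells)
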