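"""kNN neighbour search, per-signal assessment, subject-level voting."""

import numpy as np
import pytest

from nwrpredict.classifier import (
    TrainedModel,
    assess_signal,
    histogram_distance,
    knn_neighbour_labels,
    predict_subject,
    train_model,
)
from nwrpredict.features import Histogram, histogram_edges
from nwrpredict.signal_model import ReflexWindow, Subject

from conftest import (
    CRAFT_N_BINS,
    CRAFT_RANGE,
    crafted_model,
    delta_hist,
    make_subject,
    query_trace_for_bin,
)


def random_histogram(rng) -> Histogram:
    return Histogram(
        bin_edges=histogram_edges(CRAFT_RANGE, CRAFT_N_BINS),
        probabilities=rng.dirichlet(np.ones(CRAFT_N_BINS)),
    )


def random_model(rng, n_profiles=20, k=5) -> TrainedModel:
    profiles = tuple(
        (f"T{i:03d}", ("h", "p")[int(rng.integers(2))], random_histogram(rng))
        for i in range(n_profiles)
    )
    return TrainedModel(
        profiles=profiles, range_spec=CRAFT_RANGE, k=k, n_bins=CRAFT_N_BINS,
        site_ids=(1,),
    )


class TestHistogramDistance:
    def test_identity(self, rng):
        h = random_histogram(rng)
        assert histogram_distance(h, h) == 0.0

    def test_disjoint_point_masses_are_sqrt2_apart(self):
        assert histogram_distance(delta_hist(0), delta_hist(1)) == pytest.approx(
            np.sqrt(2)
        )

    def test_metric_properties(self, rng):
        for _ in range(50):
            p, q, r = (random_histogram(rng) for _ in range(3))
            assert histogram_distance(p, q) == pytest.approx(histogram_distance(q, p))
            assert histogram_distance(p, q) <= (
                histogram_distance(p, r) + histogram_distance(r, q) + 1e-12
            )

    def test_mismatched_bins_rejected(self, rng):
        h = random_histogram(rng)
        small = Histogram(
            bin_edges=histogram_edges(CRAFT_RANGE, 10),
            probabilities=np.full(10, 0.1),
        )
        with pytest.raises(ValueError):
            histogram_distance(h, small)


class TestKnnNeighbourLabels:
    def test_identical_profile_is_nearest(self, rng):
        h = random_histogram(rng)
        model = TrainedModel(
            profiles=(("T1", "p", h),), range_spec=CRAFT_RANGE, k=1,
            n_bins=CRAFT_N_BINS,
        )
        assert knn_neighbour_labels(h, model) == [("p", 0.0, "T1")]

    def test_k_equal_to_training_size_returns_all(self, rng):
        model = random_model(rng, n_profiles=8, k=8)
        got = knn_neighbour_labels(random_histogram(rng), model)
        assert sorted(sid for _, _, sid in got) == sorted(model.training_ids)

    def test_matches_exhaustive_sort_oracle(self, rng):
        """kNN equals a full sort of all (distance, subject_id) pairs."""
        for _ in range(25):
            model = random_model(rng, n_profiles=int(rng.integers(6, 40)), k=5)
            q = random_histogram(rng)
            got = knn_neighbour_labels(q, model)
            oracle = sorted(
                (histogram_distance(q, h), sid, lab)
                for sid, lab, h in model.profiles
            )[:5]
            assert [(lab, sid) for _, sid, lab in oracle] == [
                (lab, sid) for lab, _, sid in got
            ]
            assert np.allclose(
                [d for d, _, _ in oracle], [d for _, d, _ in got], atol=1e-12
            )

    def test_matches_sklearn_nearest_neighbours(self, rng):
        """Independent library cross-check on tie-free instances."""
        from sklearn.neighbors import NearestNeighbors

        for _ in range(10):
            model = random_model(rng, n_profiles=30, k=5)
            q = random_histogram(rng)
            nn = NearestNeighbors(n_neighbors=5, metric="euclidean").fit(
                np.stack([h.probabilities for _, _, h in model.profiles])
            )
            _, idx = nn.kneighbors(q.probabilities[None, :])
            expected = {model.profiles[i][0] for i in idx[0]}
            got = {sid for _, _, sid in knn_neighbour_labels(q, model)}
            assert got == expected

    def test_storage_order_independence(self, rng):
        model = random_model(rng, n_profiles=25, k=5)
        q = random_histogram(rng)
        perm = rng.permutation(len(model.profiles))
        shuffled = TrainedModel(
            profiles=tuple(model.profiles[i] for i in perm),
            range_spec=model.range_spec, k=model.k, n_bins=model.n_bins,
            site_ids=model.site_ids,
        )
        assert knn_neighbour_labels(q, model) == knn_neighbour_labels(q, shuffled)

    def test_distance_ties_broken_by_subject_id(self):
        h = delta_hist(4)
        model = TrainedModel(
            profiles=(("TB", "h", h), ("TA", "p", h), ("TC", "h", delta_hist(9))),
            range_spec=CRAFT_RANGE, k=2, n_bins=CRAFT_N_BINS,
        )
        assert [sid for _, _, sid in knn_neighbour_labels(h, model)] == ["TA", "TB"]


class TestSignalAssessment:
    def test_three_of_five_patient_neighbours_gives_60_percent(self):
        model = crafted_model({7: (3, 2)})
        a = assess_signal(np.full(12, 7.5), model)
        assert a.prob_patient == 60.0
        assert a.prob_healthy == 40.0
        assert a.label == "p"

    def test_unanimous_patient_neighbours_give_100_percent(self):
        model = crafted_model({7: (5, 0)})
        a = assess_signal(np.full(12, 7.5), model)
        assert a.prob_patient == 100.0 and a.label == "p"

    def test_unanimous_healthy_neighbours_give_0_percent(self):
        model = crafted_model({7: (0, 5)})
        a = assess_signal(np.full(12, 7.5), model)
        assert a.prob_patient == 0.0 and a.label == "h"

    def test_probabilities_always_sum_to_100(self, rng):
        model = random_model(rng, n_profiles=30, k=5)
        for _ in range(20):
            a = assess_signal(rng.uniform(0, 30, size=12), model)
            assert a.prob_patient + a.prob_healthy == 100.0
            assert a.prob_patient in {0.0, 20.0, 40.0, 60.0, 80.0, 100.0}


class TestPredictSubject:
    def test_equal_vote_classifies_as_patient(self):
        """Signals voting p,p,h,h with l = 60,60,40,40 average to exactly 50,
        which the tie rule resolves in favour of the patient class."""
        model = crafted_model({1: (3, 2), 5: (2, 3)})
        traces = [
            query_trace_for_bin(1, "Q1", 1, 1),
            query_trace_for_bin(1, "Q1", 1, 2),
            query_trace_for_bin(5, "Q1", 1, 3),
            query_trace_for_bin(5, "Q1", 1, 4),
        ]
        pred = predict_subject(make_subject("Q1", traces=traces), model)
        assert [a.prob_patient for a in pred.signal_assessments] == [60, 60, 40, 40]
        assert pred.prob_patient == 50.0
        assert pred.predicted_label == "p"

    def test_unanimous_signals_give_full_confidence(self):
        model = crafted_model({3: (5, 0)})
        traces = [query_trace_for_bin(3, "Q1", 1, r) for r in range(1, 5)]
        pred = predict_subject(make_subject("Q1", traces=traces), model)
        assert pred.prob_patient == 100.0 and pred.predicted_label == "p"

    def test_two_site_pooled_mean(self):
        """Eight signals, six with l=20 and two with l=60: l_q^p = 30 -> healthy."""
        model = crafted_model({1: (1, 4), 8: (3, 2)}, site_ids=(1, 2))
        traces = [query_trace_for_bin(1, "Q1", 1, r) for r in range(1, 5)]
        traces += [query_trace_for_bin(1, "Q1", 2, r) for r in (1, 2)]
        traces += [query_trace_for_bin(8, "Q1", 2, r) for r in (3, 4)]
        pred = predict_subject(make_subject("Q1", traces=traces), model)
        assert sorted(a.prob_patient for a in pred.signal_assessments) == [
            20, 20, 20, 20, 20, 20, 60, 60,
        ]
        assert pred.prob_patient == pytest.approx(30.0)
        assert pred.predicted_label == "h"

    def test_missing_site_is_error(self):
        model = crafted_model({1: (3, 2)}, site_ids=(1, 2))
        traces = [query_trace_for_bin(1, "Q1", 1, r) for r in range(1, 5)]
        with pytest.raises(ValueError, match="site 2"):
            predict_subject(make_subject("Q1", traces=traces), model)

    def test_missing_repetition_warns_and_uses_rest(self):
        model = crafted_model({1: (5, 0)})
        traces = [query_trace_for_bin(1, "Q1", 1, r) for r in (1, 2, 3)]
        with pytest.warns(UserWarning, match="3 of 4"):
            pred = predict_subject(make_subject("Q1", traces=traces), model)
        assert len(pred.signal_assessments) == 3

    def test_flipping_h_to_p_never_decreases_confidence(self, rng):
        """Monotonicity of the vote in the training labels."""
        for _ in range(10):
            model = random_model(rng, n_profiles=20, k=5)
            traces = [
                query_trace_for_bin(int(rng.integers(0, 30)), "Q1", 1, r)
                for r in range(1, 5)
            ]
            query = make_subject("Q1", traces=traces)
            base = predict_subject(query, model)
            h_positions = [
                i for i, (_, lab, _) in enumerate(model.profiles) if lab == "h"
            ]
            if not h_positions:
                continue
            i = int(rng.choice(h_positions))
            sid, _, hist = model.profiles[i]
            flipped = TrainedModel(
                profiles=model.profiles[:i] + ((sid, "p", hist),) + model.profiles[i + 1:],
                range_spec=model.range_spec, k=model.k, n_bins=model.n_bins,
                site_ids=model.site_ids,
            )
            flipped_pred = predict_subject(query, flipped)
            assert flipped_pred.prob_patient >= base.prob_patient
            if base.predicted_label == "p":
                assert flipped_pred.predicted_label == "p"

    def test_prediction_deterministic_under_profile_permutation(self, rng):
        model = random_model(rng, n_profiles=25, k=5)
        traces = [query_trace_for_bin(5, "Q1", 1, r) for r in range(1, 5)]
        query = make_subject("Q1", traces=traces)
        perm = rng.permutation(len(model.profiles))
        shuffled = TrainedModel(
            profiles=tuple(model.profiles[i] for i in perm),
            range_spec=model.range_spec, k=model.k, n_bins=model.n_bins,
            site_ids=model.site_ids,
        )
        a, b = predict_subject(query, model), predict_subject(query, shuffled)
        assert a.prob_patient == b.prob_patient
        assert [s.neighbour_ids for s in a.signal_assessments] == [
            s.neighbour_ids for s in b.signal_assessments
        ]


class TestTrainModel:
    def test_profiles_average_over_selected_site_signals(self, rng):
        from nwrpredict.synthetic_data import ClassSignalParams, CohortSpec, generate_cohort

        cohort = generate_cohort(
            CohortSpec(n_per_cell=1, sites=(9, 10), seed=4), ClassSignalParams()
        )
        model = train_model(list(cohort), site_ids=(9, 10), k=3)
        assert len(model.profiles) == 8
        assert model.site_ids == (9, 10)
        for _, _, h in model.profiles:
            assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_range_is_frozen_from_training_data(self, rng):
        """Query histograms use the training range even for outlier queries."""
        model = crafted_model({7: (3, 2)})
        a = assess_signal(np.full(12, 1e6), model)  # far outside rg
        assert a.prob_patient in {0.0, 20.0, 40.0, 60.0, 80.0, 100.0}
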