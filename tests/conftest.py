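"""Shared fixtures and builders for the test suite.

Most tests run on tiny hand-built objects at a reduced sampling rate
(100 Hz) so traces stay short while respecting the 200 ms pre-stimulation
and 180 ms post-stimulation coverage invariants.
"""

from __future__ import annotations

import numpy as np
import pytest

from nwrpredict.classifier import TrainedModel
from nwrpredict.features import Histogram, RangeSpec, histogram_edges
from nwrpredict.signal_model import Cohort, EMGTrace, ReflexWindow, Subject

RATE = 100.0  # Hz; 200 ms prestim -> 20 samples, 60-180 ms window -> 12 samples
ONSET = 20
TRACE_LEN = 40


def make_trace(
    subject_id: str = "S1",
    site_id: int = 1,
    repetition: int = 1,
    fill: float = 0.0,
    samples: np.ndarray | None = None,
    rate: float = RATE,
    onset: int = ONSET,
) -> EMGTrace:
    if samples is None:
        samples = np.full(TRACE_LEN, fill, dtype=float)
    return EMGTrace(
        subject_id=subject_id,
        site_id=site_id,
        repetition=repetition,
        samples=samples,
        sampling_rate=rate,
        stim_onset_index=onset,
    )


def make_subject(
    subject_id: str,
    group: str = "h",
    gender: str = "G1",
    age: float = 30.0,
    traces: list | None = None,
) -> Subject:
    return Subject(
        subject_id=subject_id,
        group=group,
        gender=gender,
        age=age,
        traces=traces or [],
    )


def balanced_cohort(n_per_cell: int, with_traces: bool = False) -> Cohort:
    """Demographically balanced cohort; traces optional (splitting does not
    need them)."""
    subjects = []
    i = 0
    for group in ("h", "p"):
        for gender in ("G1", "G2"):
            for age in (30.0, 60.0):
                for _ in range(n_per_cell):
                    i += 1
                    traces = (
                        [make_trace(f"S{i:03d}", 1, r + 1) for r in range(4)]
                        if with_traces
                        else []
                    )
                    subjects.append(
                        make_subject(f"S{i:03d}", group, gender, age, traces)
                    )
    return Cohort(subjects=subjects)


# ---------------------------------------------------------------------------
# Crafted histogram-space models: training profiles are (near-)point masses
# in known bins, and query traces of constant amplitude land exactly on a
# chosen bin, so every signal's neighbour set — hence its vote — is known
# by construction.
# ---------------------------------------------------------------------------

CRAFT_N_BINS = 30
CRAFT_RANGE = RangeSpec(full_range=(0.0, 30.0), mu=15.0, sigma=15.0)  # rg=(0,30)


def delta_hist(bin_index: int, eps_bin: int | None = None, eps: float = 0.1) -> Histogram:
    """Point mass in ``bin_index``; optionally leak ``eps`` into ``eps_bin``
    to create a profile at a small, known distance from the pure delta."""
    probs = np.zeros(CRAFT_N_BINS)
    probs[bin_index] = 1.0
    if eps_bin is not None:
        probs[bin_index] -= eps
        probs[eps_bin] += eps
    edges = histogram_edges(CRAFT_RANGE, CRAFT_N_BINS)
    return Histogram(bin_edges=edges, probabilities=probs)


def crafted_model(votes_per_bin: dict[int, tuple[int, int]], k: int = 5,
                  site_ids: tuple[int, ...] = (1,)) -> TrainedModel:
    """Model in which a query landing in bin b sees exactly the vote
    (n_patient, n_healthy) prescribed by ``votes_per_bin[b]``.

    For each bin b, n_h healthy profiles sit exactly on the delta at b
    (distance 0) and n_p patient profiles sit at a small distance
    (0.1 * sqrt(2)); every other cluster is at distance ~sqrt(2), so with
    k = n_p + n_h the neighbour set of a bin-b query is its own cluster.
    """
    profiles = []
    counter = 0
    for b, (n_p, n_h) in votes_per_bin.items():
        for _ in range(n_h):
            counter += 1
            profiles.append((f"T{counter:03d}", "h", delta_hist(b)))
        for _ in range(n_p):
            counter += 1
            profiles.append((f"T{counter:03d}", "p", delta_hist(b, eps_bin=(b + 15) % 30)))
    return TrainedModel(
        profiles=tuple(profiles),
        range_spec=CRAFT_RANGE,
        k=k,
        n_bins=CRAFT_N_BINS,
        site_ids=site_ids,
        window=ReflexWindow(),
    )


def query_trace_for_bin(
    bin_index: int, subject_id: str, site_id: int, repetition: int
) -> EMGTrace:
    """Constant-amplitude trace whose reflex window lands wholly in one bin
    of the crafted range (bin width 1, so bin centre = index + 0.5)."""
    return make_trace(
        subject_id, site_id, repetition, fill=bin_index + 0.5
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
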