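"""kNN prediction scheme with per-signal voting and individual assessment.

Training subjects are represented by averaged amplitude-histogram profiles
P_i; a query subject's signals are assessed one at a time: each signal's
histogram P_qj is compared against every training profile by Euclidean
distance over the bin probabilities, the k nearest training subjects vote,
and the fraction of patient neighbours becomes the signal's patient
probability l_qj^p (a multiple of 100/k).  The subject-level assessment
l_q^p is the mean of the signal probabilities; l_q^p >= 50% classifies the
subject as a patient — which simultaneously implements majority voting and
the clinically motivated tie-break in favour of not missing patients.

Note the deliberate asymmetry of the comparison: query signals are used
individually (P_qj) while training subjects enter as averaged profiles
(P_i).  This is the scheme's defining structure, not an implementation
shortcut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import features
from .errors import ConfigurationError
from .features import DEFAULT_N_BINS, Histogram, RangeSpec, build_histogram, subject_profile
from .signal_model import EMGTrace, ReflexWindow, Subject, extract_reflex_window

__all__ = [
    "DEFAULT_K",
    "TrainedModel",
    "SignalAssessment",
    "SubjectPrediction",
    "histogram_distance",
    "knn_neighbour_labels",
    "assess_signal",
    "predict_subject",
    "train_model",
]

DEFAULT_K = 5


@dataclass(frozen=True)
class TrainedModel:
    """Frozen training state: profiles, amplitude range and hyperparameters.

    ``profiles`` holds one (subject_id, label, Histogram) triple per
    training subject, the label being "h" (healthy) or "p" (patient).
    ``range_spec`` is the amplitude range fitted on the training pool and
    reused verbatim for every query histogram.
    """

    profiles: tuple[tuple[str, str, Histogram], ...]
    range_spec: RangeSpec
    k: int = DEFAULT_K
    n_bins: int = DEFAULT_N_BINS
    site_ids: tuple[int, ...] = (9, 10)
    window: ReflexWindow = field(default_factory=ReflexWindow)
    #: histogram |amplitude| instead of signed amplitude (default: signed,
    #: which preserves the full distribution)
    rectify: bool = False

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("model needs at least one training profile")
        if not 1 <= self.k <= len(self.profiles):
            raise ValueError(
                f"k={self.k} must lie in [1, {len(self.profiles)}] "
                "(number of training profiles)"
            )
        labels = {lab for _, lab, _ in self.profiles}
        if not labels <= {"h", "p"}:
            raise ValueError(f"labels must be 'h'/'p', got {sorted(labels)}")
        first = self.profiles[0][2]
        for _, _, h in self.profiles[1:]:
            if not first.same_edges(h):
                raise ValueError("training profiles have mismatched bin edges")
        ids = [sid for sid, _, _ in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate training subject ids in model")
        # cached arrays for the neighbour search; _id_rank makes the
        # distance tie-break content-based (lexicographic on subject_id)
        object.__setattr__(
            self, "_matrix", np.stack([h.probabilities for _, _, h in self.profiles])
        )
        object.__setattr__(self, "_is_patient", np.array([lab == "p" for _, lab, _ in self.profiles]))
        object.__setattr__(self, "_id_rank", np.argsort(np.argsort(np.asarray(ids))))

    @property
    def training_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _, _ in self.profiles)


@dataclass(frozen=True)
class SignalAssessment:
    """kNN verdict for one query signal F_qj.

    ``prob_patient`` (l_qj^p) and ``prob_healthy`` (l_qj^h) are percentages
    that sum to 100 and are multiples of 100/k; ``label`` follows the
    neighbour majority (k odd, so no per-signal ties).
    """

    site_id: int
    repetition: int
    label: str
    prob_patient: float
    prob_healthy: float
    neighbour_ids: tuple[str, ...]
    distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(self.prob_patient + self.prob_healthy - 100.0) > 1e-9:
            raise ValueError("signal probabilities must sum to 100%")
        expected = "p" if self.prob_patient > 50.0 else "h"
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with l_qj^p = {self.prob_patient}%"
            )


@dataclass(frozen=True)
class SubjectPrediction:
    """Aggregated prediction for one query subject.

    ``prob_patient`` (l_q^p) is the mean of the per-signal patient
    probabilities and doubles as the confidence of the assessment;
    ``predicted_label`` is "p" iff l_q^p >= 50%.
    """

    subject_id: str
    signal_assessments: tuple[SignalAssessment, ...]
    prob_patient: float
    predicted_label: str

    def __post_init__(self) -> None:
        if not self.signal_assessments:
            raise ValueError("prediction needs at least one assessed signal")
        mean = float(np.mean([a.prob_patient for a in self.signal_assessments]))
        if abs(mean - self.prob_patient) > 1e-9:
            raise ValueError("l_q^p must equal the mean of per-signal l_qj^p")
        expected = "p" if self.prob_patient >= 50.0 else "h"
        if self.predicted_label != expected:
            raise ValueError(
                f"label {self.predicted_label!r} inconsistent with "
                f"l_q^p = {self.prob_patient}%"
            )

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "l_q_p": self.prob_patient,
            "predicted_label": self.predicted_label,
            "signals": [
                {
                    "site": a.site_id,
                    "repetition": a.repetition,
                    "label": a.label,
                    "l_qj_p": a.prob_patient,
                    "neighbours": list(a.neighbour_ids),
                    "distances": list(a.distances),
                }
                for a in self.signal_assessments
            ],
        }


def histogram_distance(p: Histogram, q: Histogram) -> float:
    """Euclidean distance between two histograms' bin probabilities.

    d = sqrt(sum_x (p(x) - q(x))^2) over the shared bins; symmetric, zero
    iff the probability vectors are identical.
    """
    if p.n_bins != q.n_bins or not p.same_edges(q):
        raise ValueError("histograms must share bin edges")
    return float(np.linalg.norm(p.probabilities - q.probabilities))


def knn_neighbour_labels(
    query_hist: Histogram, model: TrainedModel
) -> list[tuple[str, float, str]]:
    """The k nearest training subjects to one query histogram.

    Returns k (label, distance, subject_id) triples in ascending distance
    order.  Distance ties are broken by subject_id (lexicographic), so the
    result is independent of the storage order of the training profiles.
    """
    first = model.profiles[0][2]
    if not query_hist.same_edges(first):
        raise ValueError("query histogram does not match the model's bin edges")
    dists = np.linalg.norm(model._matrix - query_hist.probabilities, axis=1)
    order = np.lexsort((model._id_rank, dists))[: model.k]
    return [
        (model.profiles[i][1], float(dists[i]), model.profiles[i][0]) for i in order
    ]


def assess_signal(
    query_window: np.ndarray,
    model: TrainedModel,
    site_id: int = 0,
    repetition: int = 0,
) -> SignalAssessment:
    """Assess one query signal: histogram, kNN vote, patient probability.

    The query histogram is built with the model's frozen amplitude range;
    l_qj^p = (#patient neighbours) / k x 100.
    """
    query_window = np.asarray(query_window, dtype=float)
    if model.rectify:
        query_window = np.abs(query_window)
    hist = build_histogram(query_window, model.range_spec, n_bins=model.n_bins)
    neighbours = knn_neighbour_labels(hist, model)
    n_patient = sum(1 for lab, _, _ in neighbours if lab == "p")
    prob_p = 100.0 * n_patient / model.k
    return SignalAssessment(
        site_id=site_id,
        repetition=repetition,
        label="p" if prob_p > 50.0 else "h",
        prob_patient=prob_p,
        prob_healthy=100.0 - prob_p,
        neighbour_ids=tuple(sid for _, _, sid in neighbours),
        distances=tuple(d for _, d, _ in neighbours),
    )


def predict_subject(
    query: Subject, model: TrainedModel, window: ReflexWindow | None = None
) -> SubjectPrediction:
    """Classify a query subject from all its signals at the model's sites.

    Every available repetition at every selected site contributes one
    signal assessment; l_q^p is the mean of their patient probabilities
    and the subject is classified as patient iff l_q^p >= 50%.  A missing
    repetition degrades gracefully (with a warning); a site with no trace
    at all is an error.
    """
    if window is None:
        window = model.window
    tagged: list[tuple[int, int, np.ndarray]] = []
    for site in model.site_ids:
        site_traces = query.traces_for_site(site)
        if not site_traces:
            raise ValueError(
                f"subject {query.subject_id!r} has no trace for required site {site}"
            )
        if len(site_traces) < 4:
            warnings.warn(
                f"subject {query.subject_id!r}, site {site}: only "
                f"{len(site_traces)} of 4 repetitions available",
                stacklevel=2,
            )
        for tr in site_traces:
            tagged.append(
                (site, tr.repetition, extract_reflex_window(tr, window))
            )

    lengths = {w.size for _, _, w in tagged}
    assessments: list[SignalAssessment] = []
    if len(lengths) == 1:
        # vectorised path: all signals share the window length
        stacked = np.stack([w for _, _, w in tagged])
        if model.rectify:
            stacked = np.abs(stacked)
        probs = features.batch_bin_probabilities(
            stacked, model.range_spec, model.n_bins
        )
        for row, (site, rep, _) in enumerate(tagged):
            # same accumulation as knn_neighbour_labels, so distances and
            # tie-breaks agree bit-for-bit with the public single-signal path
            row_d = np.linalg.norm(model._matrix - probs[row], axis=1)
            order = np.lexsort((model._id_rank, row_d))[: model.k]
            n_patient = int(model._is_patient[order].sum())
            prob_p = 100.0 * n_patient / model.k
            assessments.append(
                SignalAssessment(
                    site_id=site,
                    repetition=rep,
                    label="p" if prob_p > 50.0 else "h",
                    prob_patient=prob_p,
                    prob_healthy=100.0 - prob_p,
                    neighbour_ids=tuple(model.profiles[i][0] for i in order),
                    distances=tuple(float(row_d[i]) for i in order),
                )
            )
    else:  # heterogeneous window lengths: per-signal fallback
        for site, rep, w in tagged:
            assessments.append(
                assess_signal(w, model, site_id=site, repetition=rep)
            )
    prob = float(np.mean([a.prob_patient for a in assessments]))
    return SubjectPrediction(
        subject_id=query.subject_id,
        signal_assessments=tuple(assessments),
        prob_patient=prob,
        predicted_label="p" if prob >= 50.0 else "h",
    )


def train_model(
    training_subjects: Sequence[Subject],
    site_ids: Sequence[int],
    window: ReflexWindow | None = None,
    k: int = DEFAULT_K,
    n_bins: int = DEFAULT_N_BINS,
    range_spec: RangeSpec | None = None,
    rectify: bool = False,
) -> TrainedModel:
    """Fit a model: pooled amplitude range, then one profile per subject.

    The range is fitted on the reflex windows of all training signals at
    the selected sites (unless an explicit ``range_spec`` is supplied) and
    each subject's profile is the bin-wise mean of its per-signal
    histograms over those sites.  With ``rectify=True`` the absolute
    amplitude is histogrammed instead of the signed value.
    """
    if window is None:
        window = ReflexWindow()
    site_ids = tuple(sorted(site_ids))
    if not site_ids:
        raise ConfigurationError("at least one stimulation site is required")
    if not training_subjects:
        raise ValueError("no training subjects")

    subject_windows: list[tuple[Subject, list[np.ndarray]]] = []
    for s in training_subjects:
        windows = [
            np.abs(extract_reflex_window(tr, window))
            if rectify
            else extract_reflex_window(tr, window)
            for site in site_ids
            for tr in s.traces_for_site(site)
        ]
        if not windows:
            raise ValueError(
                f"training subject {s.subject_id!r} has no traces at sites {site_ids}"
            )
        subject_windows.append((s, windows))

    if range_spec is None:
        range_spec = features.fit_amplitude_range(
            w for _, ws in subject_windows for w in ws
        )

    profiles = []
    lengths = {w.size for _, ws in subject_windows for w in ws}
    if len(lengths) == 1:
        # vectorised path: one binning pass over all training signals
        all_windows = np.stack([w for _, ws in subject_windows for w in ws])
        all_probs = features.batch_bin_probabilities(
            all_windows, range_spec, n_bins
        )
        edges = features.histogram_edges(range_spec, n_bins)
        row = 0
        for s, windows in subject_windows:
            block = all_probs[row : row + len(windows)]
            row += len(windows)
            profile = Histogram(
                bin_edges=edges.copy(), probabilities=block.mean(axis=0)
            )
            profiles.append((s.subject_id, s.group, profile))
    else:
        for s, windows in subject_windows:
            hists = [build_histogram(w, range_spec, n_bins=n_bins) for w in windows]
            profiles.append((s.subject_id, s.group, subject_profile(hists)))

    return TrainedModel(
        profiles=tuple(profiles),
        range_spec=range_spec,
        k=k,
        n_bins=n_bins,
        site_ids=site_ids,
        window=window,
        rectify=rectify,
    )
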