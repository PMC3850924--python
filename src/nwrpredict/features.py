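"""Amplitude-histogram classification features.

The classifier represents an EMG reflex window by a coarse probability
distribution of its amplitudes.  Because raw EMG has a wide range Rg with
only ~1/1000 of the mass near the extremes, the histogram is built on the
restricted range rg = [mu - sigma, mu + sigma], where mu and sigma are the
pooled mean and standard deviation of all training amplitudes; 30 uniform
bins over rg then suffice as a feature vector.

The range is fitted once per training configuration and frozen, so query
histograms never leak information into the feature definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RangeSpec",
    "Histogram",
    "fit_amplitude_range",
    "build_histogram",
    "subject_profile",
    "DEFAULT_N_BINS",
]

DEFAULT_N_BINS = 30

_EDGE_ATOL = 1e-9


@dataclass(frozen=True)
class RangeSpec:
    """Pooled amplitude statistics of a training configuration.

    ``full_range`` is Rg = (min, max) over all pooled training amplitudes;
    ``mu``/``sigma`` are the pooled mean and population standard deviation;
    the restricted histogram range rg = (mu - sigma, mu + sigma).
    """

    full_range: tuple[float, float]
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        lo, hi = self.full_range
        if lo > hi:
            raise ValueError(f"full_range min {lo} exceeds max {hi}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    @property
    def restricted_range(self) -> tuple[float, float]:
        return (self.mu - self.sigma, self.mu + self.sigma)

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0


@dataclass(frozen=True)
class Histogram:
    """A binned probability distribution of EMG amplitudes.

    ``bin_edges`` holds n_bins + 1 uniformly spaced amplitudes and
    ``probabilities`` the corresponding bin fractions, which sum to one.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)
        if edges.ndim != 1 or probs.ndim != 1 or edges.size != probs.size + 1:
            raise ValueError("need n_bins + 1 edges for n_bins probabilities")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.max(np.abs(widths - widths[0])) > _EDGE_ATOL * max(1.0, abs(widths[0])):
            raise ValueError("bins must be uniform")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(float(probs.sum()) - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {probs.sum()}, expected 1")

    @property
    def n_bins(self) -> int:
        return self.probabilities.size

    def same_edges(self, other: "Histogram") -> bool:
        return self.bin_edges.size == other.bin_edges.size and bool(
            np.max(np.abs(self.bin_edges - other.bin_edges)) <= _EDGE_ATOL
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Histogram):
            return NotImplemented
        return np.array_equal(self.bin_edges, other.bin_edges) and np.array_equal(
            self.probabilities, other.probabilities
        )

    __hash__ = None  # type: ignore[assignment]


def fit_amplitude_range(
    training_windows: Iterable[np.ndarray],
) -> RangeSpec:
    """Pool reflex-window amplitudes from training signals and fit the range.

    Rg is the min/max of the pooled samples; mu and sigma are the pooled
    mean and population standard deviation (ddof=0).  Must be computed from
    training data only — the result is frozen into the trained model.
    """
    arrays = [np.asarray(w, dtype=float).ravel() for w in training_windows]
    arrays = [a for a in arrays if a.size]
    if not arrays:
        raise ValueError("cannot fit an amplitude range from an empty pool")
    pooled = np.concatenate(arrays)
    if pooled.size < 2:
        raise ValueError("need at least two pooled samples to fit sigma")
    return RangeSpec(
        full_range=(float(pooled.min()), float(pooled.max())),
        mu=float(pooled.mean()),
        sigma=float(pooled.std(ddof=0)),
    )


def _bin_indices(
    samples: np.ndarray, lo: float, width: float, n_bins: int
) -> np.ndarray:
    """Bin index floor((x - lo)/width), clipped into [0, n_bins - 1].

    Samples exactly on an interior edge fall in the right-hand bin; samples
    below rg or at/above its upper edge are clipped into the edge bins so
    no mass is lost.
    """
    idx = np.floor((samples - lo) / width).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def batch_bin_probabilities(
    windows_matrix: np.ndarray, range_spec: RangeSpec, n_bins: int = DEFAULT_N_BINS
) -> np.ndarray:
    """Row-wise clipped bin probabilities for equally long windows.

    Equivalent to stacking ``build_histogram(row, ...).probabilities`` for
    every row of ``windows_matrix`` (shape: n_signals x n_samples); one
    vectorised pass for the training/prediction hot path.
    """
    matrix = np.asarray(windows_matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] == 0:
        raise ValueError("windows_matrix must be 2-D with non-empty rows")
    if range_spec.degenerate:
        raise ValueError(
            "restricted range is degenerate (sigma = 0); histogram undefined"
        )
    lo, hi = range_spec.restricted_range
    width = (hi - lo) / n_bins
    n_signals, n_samples = matrix.shape
    idx = _bin_indices(matrix.ravel(), lo, width, n_bins)
    idx += n_bins * np.repeat(np.arange(n_signals), n_samples)
    counts = np.bincount(idx, minlength=n_signals * n_bins).reshape(n_signals, n_bins)
    return counts / float(n_samples)


def histogram_edges(range_spec: RangeSpec, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """The uniform bin edges over the restricted range."""
    lo, hi = range_spec.restricted_range
    width = (hi - lo) / n_bins
    edges = lo + width * np.arange(n_bins + 1)
    edges[-1] = hi
    return edges


def build_histogram(
    window: np.ndarray,
    range_spec: RangeSpec,
    n_bins: int = DEFAULT_N_BINS,
    clip: bool = True,
) -> Histogram:
    """Bin one reflex window's amplitudes over the restricted range.

    With ``clip=True`` (default) out-of-range samples are counted in the
    outermost bins, conserving the sample count; with ``clip=False`` they
    are discarded and the remaining counts renormalized.

    Raises ``ValueError`` for an empty window, a degenerate range
    (sigma = 0), or ``clip=False`` when no sample falls inside rg.
    """
    samples = np.asarray(window, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("cannot build a histogram from an empty window")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if range_spec.degenerate:
        raise ValueError(
            "restricted range is degenerate (sigma = 0); histogram undefined"
        )
    lo, hi = range_spec.restricted_range
    width = (hi - lo) / n_bins
    if clip:
        idx = _bin_indices(samples, lo, width, n_bins)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
    else:
        inside = (samples >= lo) & (samples < hi)
        kept = samples[inside]
        if kept.size == 0:
            raise ValueError("no samples inside the restricted range")
        idx = np.floor((kept - lo) / width).astype(np.int64)
        idx = np.clip(idx, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
    edges = histogram_edges(range_spec, n_bins)
    return Histogram(bin_edges=edges, probabilities=counts / counts.sum())


def subject_profile(histograms: Sequence[Histogram]) -> Histogram:
    """Bin-wise mean of per-signal histograms: the subject's profile P_i.

    All inputs must share bin edges.  With the standard four repetitions
    per site this is P_i = sum_j P_ij / 4; pooling several sites simply
    averages over all of the subject's selected signals.
    """
    if not histograms:
        raise ValueError("need at least one histogram to average")
    first = histograms[0]
    for h in histograms[1:]:
        if not first.same_edges(h):
            raise ValueError("histograms have mismatched bin edges")
    mean = np.mean([h.probabilities for h in histograms], axis=0)
    return Histogram(bin_edges=first.bin_edges.copy(), probabilities=mean)
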