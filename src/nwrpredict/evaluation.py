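"""Prediction-rate metrics, misclassification demographics, and the
empirical-percentile baseline.

Model performance is summarized by three prediction rates: the overall
rate r = M+/M, and the per-group rates r_h and r_p for healthy subjects
and patients, which expose degenerate classifiers that put everyone in
one class.  Misclassified subjects are additionally broken down by gender
(G1/G2) and age class (A1/A2).

The percentile baseline mirrors the reference-value approach used with
scalar NWR biomarkers: a critical value is the empirical 75th/90th/95th
percentile of a healthy reference sample, and a query subject whose value
strictly exceeds it is flagged as a patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .data_preparation import AGE_CUT_YEARS
from .signal_model import Subject

__all__ = [
    "RateTriple",
    "DemographicRates",
    "prediction_rates",
    "misclassification_demographics",
    "percentile_baseline",
]


@dataclass(frozen=True)
class RateTriple:
    """Correct-classification counts and the derived prediction rates.

    ``m_h``/``m_p`` are the numbers of evaluated healthy subjects and
    patients, ``m_h_correct``/``m_p_correct`` the correctly classified
    ones.  Rates are exact rational percentages exposed as floats.
    """

    m_h: int
    m_h_correct: int
    m_p: int
    m_p_correct: int

    def __post_init__(self) -> None:
        if not (0 <= self.m_h_correct <= self.m_h and 0 <= self.m_p_correct <= self.m_p):
            raise ValueError("correct counts must lie within group totals")
        if self.m_h + self.m_p == 0:
            raise ValueError("empty evaluation set")

    @property
    def m(self) -> int:
        """Total number of evaluated subjects M."""
        return self.m_h + self.m_p

    @property
    def m_correct(self) -> int:
        """Correctly classified subjects M+."""
        return self.m_h_correct + self.m_p_correct

    @property
    def r_exact(self) -> Fraction:
        return Fraction(100 * self.m_correct, self.m)

    @property
    def r(self) -> float:
        """Overall prediction rate r = M+/M, in percent."""
        return float(self.r_exact)

    @property
    def r_h(self) -> float:
        """Healthy-group prediction rate, in percent."""
        if self.m_h == 0:
            raise ValueError("no healthy subjects evaluated; r_h undefined")
        return float(Fraction(100 * self.m_h_correct, self.m_h))

    @property
    def r_p(self) -> float:
        """Patient-group prediction rate, in percent."""
        if self.m_p == 0:
            raise ValueError("no patients evaluated; r_p undefined")
        return float(Fraction(100 * self.m_p_correct, self.m_p))

    @property
    def rate_gap(self) -> float:
        """|r_h - r_p|, the group-balance diagnostic."""
        return abs(self.r_h - self.r_p)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "r_h": self.r_h if self.m_h else None,
            "r_p": self.r_p if self.m_p else None,
            "M": self.m,
            "M_correct": self.m_correct,
            "M_h": self.m_h,
            "M_h_correct": self.m_h_correct,
            "M_p": self.m_p,
            "M_p_correct": self.m_p_correct,
        }

    def __str__(self) -> str:
        return (
            f"r = {self.r:.1f}%  (r_h = {self.r_h:.1f}%, r_p = {self.r_p:.1f}%; "
            f"{self.m_correct}/{self.m} correct)"
        )


@dataclass(frozen=True)
class DemographicRates:
    """Gender and age-class composition of the misclassified subjects.

    Percentages of the misclassified pool: ``v_g1``/``v_g2`` for males and
    females, ``v_a1``/``v_a2`` for the younger (< 50 y) and elder (>= 50 y)
    age classes.  When nothing was misclassified the percentages are
    undefined and ``None``.
    """

    n_misclassified: int
    v_g1: float | None
    v_g2: float | None
    v_a1: float | None
    v_a2: float | None

    @property
    def no_misclassifications(self) -> bool:
        return self.n_misclassified == 0

    def to_dict(self) -> dict:
        return {
            "n_misclassified": self.n_misclassified,
            "v_G1": self.v_g1,
            "v_G2": self.v_g2,
            "v_A1": self.v_a1,
            "v_A2": self.v_a2,
        }


def prediction_rates(
    predictions: Iterable[tuple[str, str]],
    allow_missing_group: bool = False,
) -> RateTriple:
    """Compute r, r_h and r_p from (true label, predicted label) pairs.

    Labels are "h"/"p".  By default both groups must be present, since a
    per-group rate for an absent group is undefined; pass
    ``allow_missing_group=True`` to evaluate one-group inputs (the missing
    group's rate then raises on access).
    """
    m_h = m_h_ok = m_p = m_p_ok = 0
    for true, pred in predictions:
        if true not in ("h", "p") or pred not in ("h", "p"):
            raise ValueError(f"labels must be 'h'/'p', got ({true!r}, {pred!r})")
        if true == "h":
            m_h += 1
            m_h_ok += true == pred
        else:
            m_p += 1
            m_p_ok += true == pred
    if m_h + m_p == 0:
        raise ValueError("no predictions supplied")
    if not allow_missing_group and (m_h == 0 or m_p == 0):
        missing = "healthy" if m_h == 0 else "patient"
        raise ValueError(
            f"no {missing} subjects among the predictions; per-group rate undefined"
        )
    return RateTriple(m_h=m_h, m_h_correct=m_h_ok, m_p=m_p, m_p_correct=m_p_ok)


def misclassification_demographics(
    misclassified: Sequence[Subject],
) -> DemographicRates:
    """Break the misclassified subjects down by gender and age class.

    Each percentage is 100 x (count in category) / (total misclassified);
    the age cut is 50 years (A2 includes exactly-50).  An empty input
    returns the explicit no-misclassifications marker.
    """
    n = len(misclassified)
    if n == 0:
        return DemographicRates(
            n_misclassified=0, v_g1=None, v_g2=None, v_a1=None, v_a2=None
        )
    males = sum(1 for s in misclassified if s.gender == "G1")
    young = sum(1 for s in misclassified if s.age < AGE_CUT_YEARS)
    return DemographicRates(
        n_misclassified=n,
        v_g1=100.0 * males / n,
        v_g2=100.0 * (n - males) / n,
        v_a1=100.0 * young / n,
        v_a2=100.0 * (n - young) / n,
    )


def percentile_baseline(
    healthy_reference: Sequence[float],
    queries: Sequence[tuple[float, str]],
    percentile: float = 95.0,
) -> RateTriple:
    """Reference-value baseline on a scalar biomarker.

    The critical value is the empirical ``percentile`` of the healthy
    reference sample (linear-interpolation / type-7 convention); a query
    is labelled patient iff its value strictly exceeds the critical value.
    Returns the resulting prediction rates over the queries.
    """
    if len(healthy_reference) == 0:
        raise ValueError("empty healthy reference sample")
    if len(queries) == 0:
        raise ValueError("no query values")
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    critical = float(np.percentile(np.asarray(healthy_reference, float), percentile))
    pairs = [(true, "p" if value > critical else "h") for value, true in queries]
    return prediction_rates(pairs, allow_missing_group=True)
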